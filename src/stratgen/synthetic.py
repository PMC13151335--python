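"""Synthetic admixed-cohort generator with known ground truth.

The generator emulates the study design end to end at desk scale: two
ancestral populations differentiated under a Balding-Nichols model with a
single parameter F, admixed individuals whose per-individual ancestry
proportion q is Beta-distributed, planted cis-eQTL effects expressed in
negative-binomial pseudobulk counts, a female-upregulated co-expression
gene module, and a lipid-like phenotype whose polygenic cis-region
architecture can be made sex-specific.  GWAS summary statistics come from
marginal regressions in an independently simulated base cohort, emitted in
sex-combined and sex-stratified strata.

Everything is deterministic under a seed (numpy SeedSequence substreams).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    GeneAnnotation,
    GenotypeMatrix,
    PhenotypeTable,
    SummaryStats,
    windows_from_annotation,
)
from .expression import PseudobulkMatrix


# ---------------------------------------------------------------------------
# ancestral model
# ---------------------------------------------------------------------------

@dataclass
class AncestralModel:
    """Two populations differentiated from shared ancestral frequencies.

    Population frequencies are Balding-Nichols draws,
    ``pop_freq ~ Beta(pi(1-F)/F, (1-pi)(1-F)/F)``, so each population's
    frequency has mean pi and the expected single-locus F_ST is F.
    """

    n_variants: int
    pi: np.ndarray
    F: float
    pop_freqs: np.ndarray  # 2 x n_variants

    @classmethod
    def draw(cls, n_variants: int, F: float = 0.1, seed=None,
             pi_range: tuple = (0.05, 0.95)) -> "AncestralModel":
        if not 0 < F < 1:
            raise ValueError(f"F must lie in (0, 1), got {F}")
        rng = np.random.default_rng(seed)
        pi = rng.uniform(*pi_range, size=n_variants)
        a = pi * (1 - F) / F
        b = (1 - pi) * (1 - F) / F
        pop_freqs = np.clip(rng.beta(a, b, size=(2, n_variants)), 1e-4, 1 - 1e-4)
        return cls(n_variants, pi, F, pop_freqs)


@dataclass
class TruthSet:
    """Planted ground truth carried alongside the synthetic data."""

    admixture: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    eqtl_effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "variant_id", "beta"]))
    sexde_module: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "log_fc_female"]))
    phenotype_betas: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "beta_male", "beta_female"]))


# ---------------------------------------------------------------------------
# layout helpers
# ---------------------------------------------------------------------------

def default_gene_annotation(n_genes: int, chrom: str = "1", spacing: int = 1_500_000,
                            gene_length: int = 20_000, start: int = 1_000_000) -> GeneAnnotation:
    """Evenly spaced gene bodies along one chromosome."""
    starts = start + spacing * np.arange(n_genes)
    return GeneAnnotation(pd.DataFrame({
        "gene_id": [f"GENE{i + 1}" for i in range(n_genes)],
        "chrom": chrom,
        "start": starts,
        "end": starts + gene_length - 1,
        "length": gene_length,
    }))


def _variant_metadata(n_variants: int, chrom: str, span: tuple, rng) -> pd.DataFrame:
    """Random SNP positions and non-palindromic allele pairs."""
    pos = np.sort(rng.choice(np.arange(span[0], span[1]), size=n_variants, replace=False))
    pairs = np.array([("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")])
    picks = pairs[rng.integers(0, 4, size=n_variants)]
    return pd.DataFrame({
        "id": [f"rs{j + 1}" for j in range(n_variants)],
        "chrom": chrom,
        "pos": pos.astype(int),
        "effect_allele": picks[:, 0],
        "other_allele": picks[:, 1],
    })


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_per_pop: tuple[int, int],
    model: AncestralModel,
    admixture_params: tuple[float, float] = (6.5, 3.5),
    n_admixed: int = 0,
    seed=None,
    chrom: str = "1",
    span: tuple | None = None,
    female_fraction: float = 0.5,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Draw reference-population and admixed genotypes from the model.

    ``n_per_pop`` individuals per ancestral population carry dosages
    ``Binomial(2, pop_freq)``; the ``n_admixed`` cohort individuals draw
    each locus at mixture frequency ``q_i * f_pop1 + (1 - q_i) * f_pop2``
    with ``q_i ~ Beta(*admixture_params)``.  Population labels are
    ``pop1 / pop2 / admixed``.
    """
    if not 0 < model.F < 1:
        raise ValueError("F out of range")
    rng = np.random.default_rng(seed)
    m = model.n_variants
    span = span or (1, max(10_000_000, m * 2_000))
    variants = _variant_metadata(m, chrom, span, rng)

    blocks, labels, qs = [], [], []
    for p, n in enumerate(n_per_pop):
        f = model.pop_freqs[p]
        blocks.append(rng.binomial(2, f[None, :].repeat(n, axis=0)).astype(float))
        labels += [f"pop{p + 1}"] * n
        qs += [1.0 - p] * n
    if n_admixed:
        q = rng.beta(*admixture_params, size=n_admixed)
        mix = q[:, None] * model.pop_freqs[0][None, :] + (1 - q[:, None]) * model.pop_freqs[1][None, :]
        blocks.append(rng.binomial(2, mix).astype(float))
        labels += ["admixed"] * n_admixed
        qs += q.tolist()
    dosages = np.vstack(blocks)
    n_total = dosages.shape[0]
    individuals = [f"I{i + 1}" for i in range(n_total)]
    sex = np.where(rng.random(n_total) < female_fraction, "female", "male")
    g = GenotypeMatrix(individuals, variants, dosages, sex=sex,
                       population_label=labels)
    truth = TruthSet(admixture=pd.Series(qs, index=individuals, dtype=float))
    return g, truth


# ---------------------------------------------------------------------------
# planting effects
# ---------------------------------------------------------------------------

def plant_truth(
    g: GenotypeMatrix,
    annotation: GeneAnnotation,
    truth: TruthSet,
    seed=None,
    n_eqtl_genes: int = 10,
    eqtl_beta: float = 0.8,
    min_maf: float = 0.10,
    sexde_n: int = 40,
    sexde_lfc_range: tuple = (0.3, 1.0),
    sexde_female_up_fraction: float = 1.0,
    pheno_arch: str = "male_cis",
    n_pheno_variants: int = 30,
    pheno_beta_sd: float = 0.15,
    n_coloc_genes: int = 0,
    coloc_beta: float = 0.25,
    flank: int = 500_000,
) -> TruthSet:
    """Fill the truth set with eQTL, sex-DE and phenotype architecture.

    ``pheno_arch``: ``male_cis`` concentrates male-only effects on variants
    in the cis windows of the sex-DE module genes (the study's qualitative
    headline design), ``shared`` gives both sexes the same betas on the same
    variants, ``null`` plants nothing.  ``n_coloc_genes`` planted eQTL
    variants additionally receive a sex-shared phenotype effect
    ``coloc_beta``, creating regions where the expression and phenotype
    signals share one causal variant (the colocalization ground truth).
    """
    rng = np.random.default_rng(seed)
    windows = windows_from_annotation(annotation, flank=flank)
    maf = g.maf()
    chromv = g.variants["chrom"].to_numpy()
    posv = g.variants["pos"].to_numpy(dtype=int)
    ids = g.variants["id"].to_numpy()
    genes = annotation.table["gene_id"].tolist()

    # cis-eQTLs: one common variant inside each chosen gene's window
    chosen = list(rng.choice(genes, size=min(n_eqtl_genes, len(genes)), replace=False))
    eqtl_rows = []
    for gene in chosen:
        w = windows[gene]
        ok = (chromv == w.chrom) & (posv >= w.start) & (posv <= w.end) & (maf > min_maf)
        cand = np.nonzero(ok)[0]
        if cand.size == 0:
            continue
        j = int(rng.choice(cand))
        eqtl_rows.append((gene, ids[j], eqtl_beta))
    truth.eqtl_effects = pd.DataFrame(eqtl_rows, columns=["gene_id", "variant_id", "beta"])

    # sex-DE module: female-upregulated log fold changes
    pool = [x for x in genes if x not in set(truth.eqtl_effects["gene_id"])]
    module = list(rng.choice(pool, size=min(sexde_n, len(pool)), replace=False))
    lfc = rng.uniform(*sexde_lfc_range, size=len(module))
    sign = np.where(rng.random(len(module)) < sexde_female_up_fraction, 1.0, -1.0)
    truth.sexde_module = pd.DataFrame({"gene_id": module, "log_fc_female": lfc * sign})

    # phenotype architecture
    coloc_rows = []
    if n_coloc_genes and len(truth.eqtl_effects):
        shared = truth.eqtl_effects.head(n_coloc_genes)
        coloc_rows = [(vid, coloc_beta, coloc_beta)
                      for vid in shared["variant_id"]]
    if pheno_arch == "null":
        truth.phenotype_betas = pd.DataFrame(
            coloc_rows, columns=["variant_id", "beta_male", "beta_female"])
        return truth
    module_windows = {gid: windows[gid] for gid in module}
    in_module = np.zeros(g.n_variants, dtype=bool)
    for w in module_windows.values():
        in_module |= (chromv == w.chrom) & (posv >= w.start) & (posv <= w.end)
    cand = np.nonzero(in_module & (maf > min_maf))[0]
    k = min(n_pheno_variants, cand.size)
    pick = rng.choice(cand, size=k, replace=False)
    betas = rng.normal(0.0, pheno_beta_sd, size=k)
    if pheno_arch == "male_cis":
        rows = pd.DataFrame({
            "variant_id": ids[pick], "beta_male": betas, "beta_female": 0.0})
    elif pheno_arch == "shared":
        rows = pd.DataFrame({
            "variant_id": ids[pick], "beta_male": betas, "beta_female": betas})
    else:
        raise ValueError(f"unknown phenotype architecture {pheno_arch!r}")
    if coloc_rows:
        extra = pd.DataFrame(coloc_rows,
                             columns=["variant_id", "beta_male", "beta_female"])
        rows = pd.concat([rows, extra], ignore_index=True) \
            .drop_duplicates("variant_id")
    truth.phenotype_betas = rows
    return truth


# ---------------------------------------------------------------------------
# pseudobulk counts
# ---------------------------------------------------------------------------

def simulate_pseudobulk_counts(
    g: GenotypeMatrix,
    annotation: GeneAnnotation,
    truth: TruthSet,
    nuclei_mean: float = 400.0,
    reads_per_nucleus: float = 500.0,
    dispersion: float = 0.3,
    indiv_noise_sd: float = 0.3,
    baseline_log_range: tuple = (1.0, 6.0),
    cell_type: str = "adipocyte",
    seed=None,
    flank: int = 500_000,
) -> PseudobulkMatrix:
    """Negative-binomial pseudobulk counts with planted effects.

    Per gene and individual the log relative expression is
    ``baseline + beta * dosage + log_fc_female * 1[female] + noise``;
    expected counts scale with the individual's library size, which is
    proportional to a Poisson-drawn nucleus count.
    """
    rng = np.random.default_rng(seed)
    genes = annotation.table["gene_id"].tolist()
    windows = windows_from_annotation(annotation, flank=flank)
    vmeta = g.variants.set_index("id")
    for row in truth.eqtl_effects.itertuples(index=False):
        w = windows[row.gene_id]
        if not w.contains(vmeta.at[row.variant_id, "chrom"], vmeta.at[row.variant_id, "pos"]):
            raise ValueError(
                f"truth eQTL {row.variant_id} lies outside the cis window of {row.gene_id}")
    n_genes, n_indiv = len(genes), g.n_individuals
    baseline = rng.uniform(*baseline_log_range, size=n_genes)
    mu = np.tile(baseline[:, None], (1, n_indiv))

    gene_pos = {gid: i for i, gid in enumerate(genes)}
    dos = g.dosages_imputed()
    vid_col = {vid: j for j, vid in enumerate(g.variants["id"])}
    for row in truth.eqtl_effects.itertuples(index=False):
        mu[gene_pos[row.gene_id]] += row.beta * dos[:, vid_col[row.variant_id]]
    if g.sex is None:
        raise ValueError("genotype matrix needs sex labels for the sex-DE module")
    female = (g.sex == "female").astype(float)
    for row in truth.sexde_module.itertuples(index=False):
        mu[gene_pos[row.gene_id]] += row.log_fc_female * female
    mu += rng.normal(0.0, indiv_noise_sd, size=(n_genes, n_indiv))

    n_nuclei = rng.poisson(nuclei_mean, size=n_indiv) + 1
    lib = n_nuclei * reads_per_nucleus
    rel = np.exp(mu)
    lam = rel / np.exp(baseline).sum() * lib[None, :]
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=genes, columns=g.individuals)
    return PseudobulkMatrix(cell_type, counts_df, pd.Series(n_nuclei, index=g.individuals))


def split_to_nuclei(pb: PseudobulkMatrix, seed=None):
    """Scatter each individual's pseudobulk counts across its nuclei.

    Returns ``(umi_counts, gene_ids, nucleus_meta)`` in the shape the
    aggregation stage reads, such that re-aggregating recovers ``pb``
    exactly.  Used by the end-to-end demo to exercise the UMI-level path.
    """
    rng = np.random.default_rng(seed)
    rows, meta = [], []
    genes = pb.genes
    for person in pb.individuals:
        k = int(pb.n_nuclei[person])
        col = pb.counts[person].to_numpy()
        probs = np.full(k, 1.0 / k)
        nuc = np.vstack([rng.multinomial(c, probs) for c in col]).T  # k x genes
        rows.append(nuc)
        meta += [(f"{person}_N{i + 1}", person, pb.cell_type) for i in range(k)]
    umi = np.vstack(rows)
    nucleus_meta = pd.DataFrame(meta, columns=["barcode", "individual", "cell_type"])
    return umi, genes, nucleus_meta


# ---------------------------------------------------------------------------
# phenotype and base GWAS
# ---------------------------------------------------------------------------

def _genetic_values(g: GenotypeMatrix, truth: TruthSet) -> np.ndarray:
    dos = g.dosages_imputed()
    vid_col = {vid: j for j, vid in enumerate(g.variants["id"])}
    gv = np.zeros(g.n_individuals)
    male = (g.sex == "male")
    for row in truth.phenotype_betas.itertuples(index=False):
        if row.variant_id not in vid_col:
            continue
        d = dos[:, vid_col[row.variant_id]]
        gv += np.where(male, row.beta_male, row.beta_female) * d
    return gv


def simulate_phenotype(
    g: GenotypeMatrix,
    truth: TruthSet,
    h2: float = 0.2,
    seed=None,
    age_range: tuple = (23, 70),
    bmi_mean: float = 30.0,
    bmi_sd: float = 7.6,
) -> PhenotypeTable:
    """Quantitative lipid-like phenotype for the cohort.

    ``y = genetic value + noise`` with the noise variance chosen so the
    genetic fraction of phenotypic variance equals ``h2`` (when any effects
    are planted).  With sex-specific architectures the planted betas also
    shift the *mean* genetic value of one sex; that shift acts as a sex
    main effect, so the h2 calibration uses the within-sex genetic
    variance.  Age and BMI are drawn as covariates without direct
    phenotype effects; a 10% random medication flag accompanies TC-style
    adjustment tests.
    """
    rng = np.random.default_rng(seed)
    gv = _genetic_values(g, truth)
    male = g.sex == "male"
    if 0 < male.sum() < len(gv):
        var_g = float(np.mean([np.var(gv[male]), np.var(gv[~male])]))
    else:
        var_g = float(np.var(gv))
    if var_g > 0 and 0 < h2 < 1:
        noise_sd = np.sqrt(var_g * (1 - h2) / h2)
    else:
        noise_sd = 1.0
    y = gv + rng.normal(0.0, noise_sd, size=g.n_individuals)
    table = pd.DataFrame({
        "tg": y,
        "age": rng.uniform(*age_range, size=g.n_individuals),
        "bmi": rng.normal(bmi_mean, bmi_sd, size=g.n_individuals),
        "sex": g.sex,
        "tc_medication": rng.random(g.n_individuals) < 0.10,
    }, index=pd.Index(g.individuals, name="individual"))
    return PhenotypeTable(table)


def marginal_gwas(g: GenotypeMatrix, y: np.ndarray, stratum: str = "all") -> SummaryStats:
    """Per-variant marginal regression summary statistics."""
    dos = g.dosages_imputed()
    y = np.asarray(y, dtype=float)
    n = len(y)
    yc = y - y.mean()
    dc = dos - dos.mean(axis=0)
    gss = np.sum(dc ** 2, axis=0)
    gss_safe = np.where(gss <= 0, np.nan, gss)
    beta = (dc.T @ yc) / gss_safe
    rss = np.sum(yc ** 2) - beta * (dc.T @ yc)
    df = n - 2
    se = np.sqrt(np.maximum(rss, 0) / df / gss_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    table = g.variants[["id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    table["eaf"] = g.eaf()
    table["beta"] = np.where(np.isfinite(beta), beta, 0.0)
    table["se"] = np.where(np.isfinite(se) & (se > 0), se, 1.0)
    pvals = np.where(np.isfinite(p), p, 1.0)
    table["p"] = np.clip(pvals, np.finfo(float).tiny, 1.0)
    table["n"] = n
    table["stratum"] = stratum
    return SummaryStats(table, stratum=stratum)


def simulate_phenotype_and_gwas(
    model: AncestralModel,
    variants: pd.DataFrame,
    truth: TruthSet,
    target: GenotypeMatrix,
    h2: float = 0.2,
    base_n: int = 5_000,
    admixture_params: tuple = (6.5, 3.5),
    seed=None,
) -> tuple[PhenotypeTable, dict[str, SummaryStats]]:
    """Target-cohort phenotype plus base-cohort GWAS in all three strata.

    The base cohort of ``base_n`` admixed individuals is simulated
    independently from the same ancestral model and the same planted
    phenotype architecture; marginal per-variant regressions in the
    combined, male and female strata provide the summary-statistic weights.
    """
    if base_n < target.n_individuals:
        raise ValueError("base_n must be at least the target cohort size")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_pheno, s_base, s_base_pheno = seq.spawn(3)
    pheno = simulate_phenotype(target, truth, h2=h2, seed=s_pheno)

    rng = np.random.default_rng(s_base)
    q = rng.beta(*admixture_params, size=base_n)
    mix = q[:, None] * model.pop_freqs[0][None, :] + (1 - q[:, None]) * model.pop_freqs[1][None, :]
    dosages = rng.binomial(2, mix).astype(float)
    sex = np.where(rng.random(base_n) < 0.5, "female", "male")
    base = GenotypeMatrix([f"B{i + 1}" for i in range(base_n)], variants.copy(),
                          dosages, sex=sex)
    base_pheno = simulate_phenotype(base, truth, h2=h2, seed=s_base_pheno)
    y = base_pheno.table["tg"].to_numpy()
    # sex-combined stratum adjusts for sex (standard GWAS practice);
    # without it a sex-specific architecture's mean shift inflates the
    # residual variance of every marginal regression
    male = (base.sex == "male").astype(float)
    y_adj = y.copy()
    y_adj[male == 1] -= y[male == 1].mean() - y.mean()
    y_adj[male == 0] -= y[male == 0].mean() - y.mean()
    out = {"all": marginal_gwas(base, y_adj, "all")}
    for stratum in ("male", "female"):
        mask = base.sex == stratum
        sub = base.select_individuals(mask)
        out[stratum] = marginal_gwas(sub, y[mask], stratum)
    return pheno, out
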