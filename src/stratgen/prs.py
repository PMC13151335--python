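"""Gene-set partitioned polygenic risk scoring and sex-interaction tests.

The score for an individual is the weighted sum of effect-allele dosages,
S_i = sum_v d_iv * beta_v, over a clumped, cis-window-restricted variant
set.  Its explanatory value is the incremental R^2 of adding S to the
covariate-only regression of the (inverse-normal) outcome; enrichment is
judged competitively against size-matched random variant sets drawn from a
background of clumped variants in the cis regions of all expressed genes,
with p = (1 + #{R2_perm >= R2_obs}) / (n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CisWindow, GenotypeMatrix, SummaryStats
from .regression import bh_fdr, design_matrix, incremental_r2, ols_fit

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

@dataclass
class ClumpResult:
    index_variants: list
    assignment: dict  # clumped variant -> index variant
    r2_threshold: float
    window_kb: float
    p_ceiling: float


def clump(
    gwas: SummaryStats,
    g: GenotypeMatrix,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
    p_ceiling: float = 1.0,
) -> ClumpResult:
    """Greedy LD clumping of GWAS variants against a genotype reference.

    Variants are visited in ascending p order (ties by table order); each
    retained index variant removes unretained variants within ``window_kb``
    whose squared Pearson correlation of dosage exceeds ``r2_threshold``.
    GWAS variants absent from the reference are dropped with a log entry.
    """
    t = gwas.table
    gkeys = {k: j for j, k in enumerate(g.variant_keys())}
    rows = []
    for i, key in enumerate(gwas.variant_keys()):
        if t["p"].iat[i] > p_ceiling:
            continue
        if key not in gkeys:
            continue
        rows.append((i, gkeys[key]))
    n_dropped = len(t) - len(rows)
    if n_dropped:
        log.info("clump: %d GWAS variants absent from reference or above p ceiling", n_dropped)
    if not rows:
        return ClumpResult([], {}, r2_threshold, window_kb, p_ceiling)
    order = sorted(rows, key=lambda r: (t["p"].iat[r[0]], r[0]))
    dos = g.dosages_imputed()
    dos = dos - dos.mean(axis=0)
    norms = np.sqrt(np.sum(dos ** 2, axis=0))
    chrom = g.variants["chrom"].to_numpy()
    pos = g.variants["pos"].to_numpy(dtype=int)
    ids = g.variants["id"].to_numpy()
    window_bp = window_kb * 1000.0

    alive = {j for _, j in order}
    index_variants, assignment = [], {}
    for i, j in order:
        if j not in alive:
            continue
        index_variants.append(ids[j])
        alive.discard(j)
        near = [jj for jj in alive
                if chrom[jj] == chrom[j] and abs(pos[jj] - pos[j]) <= window_bp]
        if near:
            nj = np.array(near)
            denom = norms[j] * norms[nj]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (dos[:, nj].T @ dos[:, j]) / np.where(denom == 0, np.nan, denom)
            r2 = np.nan_to_num(r ** 2)
            for jj, drop in zip(near, r2 > r2_threshold):
                if drop:
                    alive.discard(jj)
                    assignment[ids[jj]] = ids[j]
    return ClumpResult(index_variants, assignment, r2_threshold, window_kb, p_ceiling)


def assign_set_variants(clumped: ClumpResult, windows: dict[str, CisWindow],
                        g: GenotypeMatrix) -> list:
    """Clumped index variants inside the union of the set's cis windows."""
    meta = g.variants.set_index("id")
    out = []
    for vid in clumped.index_variants:
        if vid not in meta.index:
            continue
        chrom, pos = meta.at[vid, "chrom"], int(meta.at[vid, "pos"])
        if any(w.contains(chrom, pos) for w in windows.values()):
            out.append(vid)
    if not out:
        log.warning("empty PRS variant set after cis-window restriction")
    return out


# ---------------------------------------------------------------------------
# scoring and evaluation
# ---------------------------------------------------------------------------

@dataclass
class PrsResult:
    scores: pd.Series  # per individual
    r2: float  # incremental R2 of the PRS over covariates
    p: float  # p-value of the PRS term
    stratum: str = "all"
    p_comp: float | None = None
    n_perm: int | None = None
    variant_ids: list = field(default_factory=list)


def prs_scores(variant_ids: list, gwas: SummaryStats, g: GenotypeMatrix) -> pd.Series:
    """S_i = sum_v dosage_iv * beta_v with per-variant mean imputation."""
    weights = _weights_for(variant_ids, gwas, g)
    if len(weights) == 0:
        return pd.Series(np.zeros(g.n_individuals), index=g.individuals)
    cols = [g.variants.index[g.variants["id"] == vid][0] for vid in weights.index]
    dos = g.dosages_imputed()[:, cols]
    return pd.Series(dos @ weights.to_numpy(), index=g.individuals)


def _weights_for(variant_ids: list, gwas: SummaryStats, g: GenotypeMatrix) -> pd.Series:
    """Betas aligned to the genotype effect allele, indexed by variant ID."""
    from .datamodel import variant_key

    gmeta = g.variants.set_index("id")
    ref: dict[tuple, tuple] = {}
    t = gwas.table
    for key, ea, beta in zip(gwas.variant_keys(), t["effect_allele"], t["beta"]):
        ref.setdefault(key, (ea, float(beta)))
    out = {}
    for vid in variant_ids:
        if vid not in gmeta.index:
            continue
        row = gmeta.loc[vid]
        key = variant_key(row["chrom"], row["pos"], row["effect_allele"], row["other_allele"])
        if key not in ref:
            continue
        ea, beta = ref[key]
        if ea != row["effect_allele"]:
            beta = -beta
        out[vid] = beta
    return pd.Series(out, dtype=float)


def score_and_fit(
    variant_ids: list,
    gwas: SummaryStats,
    g: GenotypeMatrix,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    stratum: str = "all",
) -> PrsResult:
    """Build the PRS and evaluate its incremental R^2 over covariates.

    ``outcome`` must already be inverse-normal transformed (and
    medication-adjusted where relevant); sex-stratified runs pass the
    restricted genotype matrix and sex-stratified base weights.
    """
    s = prs_scores(variant_ids, gwas, g)
    y = np.asarray(outcome, dtype=float)
    X = design_matrix(covariates, len(y))
    sv = s.to_numpy()
    if np.var(sv) == 0:
        log.warning("zero-variance PRS; incremental R2 set to 0")
        return PrsResult(s, 0.0, 1.0, stratum, variant_ids=list(variant_ids))
    r2, p = incremental_r2(y, X, sv[:, None])
    return PrsResult(s, r2, p, stratum, variant_ids=list(variant_ids))


def competitive_p(
    observed: PrsResult,
    background: list,
    gwas: SummaryStats,
    g: GenotypeMatrix,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 10_000,
    seed=None,
) -> PrsResult:
    """Competitive permutation p for the observed incremental R^2.

    Each permutation draws a size-matched variant set without replacement
    from the background (clumped variants in cis windows of all expressed
    genes), rebuilds the score and its incremental R^2.
    """
    background = list(background)
    k = len(observed.variant_ids)
    if len(background) < k:
        raise ValueError("background smaller than the observed set")
    y = np.asarray(outcome, dtype=float)
    X = design_matrix(covariates, len(y))
    # precompute: residualize outcome and all background dosage columns once
    from .regression import residualize
    yr = residualize(y[:, None], X)[:, 0]
    tss = float(np.sum((y - y.mean()) ** 2))
    weights = _weights_for(background, gwas, g)
    usable = [v for v in background if v in weights.index]
    cols = [g.variants.index[g.variants["id"] == vid][0] for vid in usable]
    D = g.dosages_imputed()[:, cols] * weights[usable].to_numpy()[None, :]
    Dr = residualize(D, X)
    rng = np.random.default_rng(seed)
    r2_perm = np.empty(n_perm)
    for b in range(n_perm):
        pick = rng.choice(len(usable), k, replace=False)
        sr = Dr[:, pick].sum(axis=1)
        ss = float(sr @ sr)
        r2_perm[b] = (yr @ sr) ** 2 / (ss * tss) if ss > 0 else 0.0
    p_comp = (1 + int(np.sum(r2_perm >= observed.r2))) / (n_perm + 1)
    return PrsResult(observed.scores, observed.r2, observed.p, observed.stratum,
                     p_comp=p_comp, n_perm=n_perm, variant_ids=observed.variant_ids)


def adjust_tc(tc: float, on_medication: bool) -> float:
    """Rescale total cholesterol for lipid-lowering medication (TC / 0.8)."""
    if tc <= 0:
        raise ValueError(f"TC must be > 0, got {tc}")
    return tc / 0.8 if on_medication else tc


# ---------------------------------------------------------------------------
# genotype x sex and PRS x sex interactions
# ---------------------------------------------------------------------------

def gxsex_scan(
    gwas_male: SummaryStats,
    gwas_female: SummaryStats,
    g: GenotypeMatrix,
    outcome: np.ndarray,
    sex: np.ndarray,
    covariates: pd.DataFrame | None = None,
    set_windows: dict[str, CisWindow] | None = None,
    gwas_p: float = 5e-8,
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """Targeted genotype-by-sex interaction tests on candidate variants.

    Candidates are variants inside the set windows that reach genome-wide
    significance in exactly one sex stratum.  Each is tested by OLS of the
    (inverse-normal) outcome on dosage + sex + dosage*sex + covariates;
    BH-FDR is applied over the candidates.  ``sex`` is coded male=1,
    female=0 for the interaction term.
    """
    pm = {k: p for k, p in zip(gwas_male.variant_keys(), gwas_male.table["p"])}
    pf = {k: p for k, p in zip(gwas_female.variant_keys(), gwas_female.table["p"])}
    candidates = []
    for j, key in enumerate(g.variant_keys()):
        p_m, p_f = pm.get(key, 1.0), pf.get(key, 1.0)
        if (p_m < gwas_p) == (p_f < gwas_p):  # neither or both
            continue
        if set_windows is not None:
            chrom = g.variants["chrom"].iat[j]
            pos = int(g.variants["pos"].iat[j])
            if not any(w.contains(chrom, pos) for w in set_windows.values()):
                continue
        candidates.append(j)
    if not candidates:
        log.info("gxsex_scan: no candidate variants")
        return pd.DataFrame(columns=["variant_id", "beta_gxs", "se", "p", "q"])
    y = np.asarray(outcome, dtype=float)
    sex_num = np.asarray([1.0 if s == "male" else 0.0 for s in sex])
    X_cov = design_matrix(covariates, len(y))
    dos = g.dosages_imputed()
    rows = []
    for j in candidates:
        d = dos[:, j]
        X = np.column_stack([X_cov, d, sex_num, d * sex_num])
        coef, se, t, p, _, _ = ols_fit(y, X)
        rows.append((g.variants["id"].iat[j], coef[-1], se[-1], p[-1]))
    out = pd.DataFrame(rows, columns=["variant_id", "beta_gxs", "se", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr_threshold
    return out


def prs_sex_interaction(
    prs: pd.Series,
    outcome: np.ndarray,
    sex: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """PRS x sex interaction on the outcome (male coded 1).

    The PRS must be built from sex-agnostic base weights.  Returns the
    interaction coefficient, its SE, t, and p from the joint OLS fit.
    """
    sex_num = np.asarray([1.0 if s == "male" else 0.0 for s in sex])
    if len(np.unique(sex_num)) < 2:
        raise ValueError("interaction needs both sexes in the cohort")
    y = np.asarray(outcome, dtype=float)
    X_cov = design_matrix(covariates, len(y))
    s = prs.to_numpy() if hasattr(prs, "to_numpy") else np.asarray(prs, dtype=float)
    X = np.column_stack([X_cov, s, sex_num, s * sex_num])
    coef, se, t, p, _, _ = ols_fit(y, X)
    return {"beta_interaction": float(coef[-1]), "se": float(se[-1]),
            "t": float(t[-1]), "p": float(p[-1])}
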