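"""Configuration-driven orchestration of all analysis stages.

``run_pipeline`` executes the stages in dependency order on a synthetic
cohort — simulate, pseudobulk processing, differential expression, cis-eQTL
mapping, allele-frequency contrast and F_ST, colocalization, PRS and
sex-interaction tests — writing each stage's tables plus a machine-readable
``summary.json`` stamped with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import de as de_mod
from . import eqtl as eqtl_mod
from . import expression as expr_mod
from . import popdiff, prs, qc, synthetic
from .datamodel import PhenotypeTable, windows_from_annotation
from .io import write_json, write_phenotypes, write_summary_stats, write_vcf

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs with the study's default thresholds."""

    seed: int = 0
    out_dir: str = "stratgen_run"
    # synthetic cohort scale
    n_genes: int = 150
    n_variants: int = 3_000
    F: float = 0.1
    n_per_pop: int = 500
    n_admixed: int = 500
    base_n: int = 5_000
    nuclei_mean: float = 40.0
    h2: float = 0.25
    # planted architecture
    n_eqtl_genes: int = 10
    sexde_n: int = 25
    n_pheno_variants: int = 25
    pheno_beta_sd: float = 0.2
    n_coloc_genes: int = 3
    # analysis thresholds
    cis_window: int = 500_000
    maf_threshold: float = 0.10
    eqtl_fdr: float = 0.10
    gwas_p: float = 5e-8
    af_bin_edges: tuple = (0.05, 0.10)
    pph4_threshold: float = 0.5
    de_fdr: float = 0.10
    n_perm: int = 1_000
    coloc_priors: tuple = (1e-4, 1e-4, 1e-5)
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "pseudobulk": True, "de": True, "eqtl": True,
        "popdiff": True, "coloc": True, "prs": True,
    })

    def validate(self) -> None:
        if self.cis_window <= 0:
            raise ValueError(f"cis_window must be positive, got {self.cis_window}")
        if not 0 < self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must lie in (0, 0.5)")
        for name in ("eqtl_fdr", "de_fdr", "gwas_p", "pph4_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0 < self.F < 1:
            raise ValueError("F must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the summary dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq = np.random.SeedSequence(config.seed)
    subseeds = dict(zip(
        ["model", "genotypes", "truth", "pseudobulk", "gwas", "be", "fst", "prs", "nuclei"],
        seq.spawn(9)))
    summary: dict = {"seed": config.seed, "config_hash": config.content_hash(),
                     "stages": {}}

    # ---- simulate -----------------------------------------------------
    annotation = synthetic.default_gene_annotation(config.n_genes)
    model = synthetic.AncestralModel.draw(config.n_variants, F=config.F,
                                          seed=subseeds["model"])
    span = (1, int(annotation.table["end"].max() + 1_000_000))
    g_all, truth = synthetic.simulate_genotypes(
        (config.n_per_pop, config.n_per_pop), model,
        n_admixed=config.n_admixed, seed=subseeds["genotypes"], span=span)
    truth = synthetic.plant_truth(
        g_all, annotation, truth, seed=subseeds["truth"],
        n_eqtl_genes=config.n_eqtl_genes, sexde_n=config.sexde_n,
        n_pheno_variants=config.n_pheno_variants,
        pheno_beta_sd=config.pheno_beta_sd,
        n_coloc_genes=config.n_coloc_genes, flank=config.cis_window)
    cohort = g_all.select_individuals(np.asarray(g_all.population_label) == "admixed")
    pop1 = g_all.select_individuals(np.asarray(g_all.population_label) == "pop1")
    pop2 = g_all.select_individuals(np.asarray(g_all.population_label) == "pop2")
    pheno, gwas = synthetic.simulate_phenotype_and_gwas(
        model, g_all.variants, truth, cohort, h2=config.h2,
        base_n=config.base_n, seed=subseeds["gwas"])
    if config.stages.get("simulate", True):
        write_vcf(cohort, out / "cohort.vcf")
        write_phenotypes(pheno, out / "phenotypes.tsv")
        for stratum, ss in gwas.items():
            write_summary_stats(ss, out / f"gwas_{stratum}.tsv")
        annotation.table.to_csv(out / "genes.tsv", sep="\t", index=False)
        write_json({
            "eqtl_effects": truth.eqtl_effects.to_dict("records"),
            "sexde_module": truth.sexde_module.to_dict("records"),
            "phenotype_betas": truth.phenotype_betas.to_dict("records"),
            "admixture": truth.admixture.round(6).to_dict(),
        }, out / "truth.json")
        summary["stages"]["simulate"] = {
            "n_cohort": cohort.n_individuals, "n_variants": cohort.n_variants,
            "n_eqtl_effects": len(truth.eqtl_effects),
            "n_sexde_genes": len(truth.sexde_module),
        }

    cohort = qc.variant_qc(cohort, qc.QCThresholds())

    # ---- pseudobulk ---------------------------------------------------
    pb = synthetic.simulate_pseudobulk_counts(
        cohort, annotation, truth, nuclei_mean=config.nuclei_mean,
        seed=subseeds["pseudobulk"])
    umi, gene_ids, nucleus_meta = synthetic.split_to_nuclei(pb, seed=subseeds["nuclei"])
    pb = expr_mod.aggregate_pseudobulk(umi, gene_ids, nucleus_meta, pb.cell_type)
    expressed = expr_mod.filter_expressed(pb, annotation, mode="eqtl")
    pb_expr = expr_mod.PseudobulkMatrix(pb.cell_type, pb.counts.loc[expressed],
                                        pb.n_nuclei)
    logcpm = expr_mod.tmm_normalize(pb_expr)
    int_expr = expr_mod.inverse_normal_rows(logcpm)
    k = expr_mod.choose_num_pcs_be(int_expr, n_perm=30, seed=subseeds["be"])
    pcs = expr_mod.expression_pcs(int_expr, k) if k > 0 else None
    if config.stages.get("pseudobulk", True):
        pb.counts.to_csv(out / "pseudobulk_counts.tsv", sep="\t")
        int_expr.values.to_csv(out / "expression_int.tsv", sep="\t")
        summary["stages"]["pseudobulk"] = {
            "n_expressed_genes": len(expressed), "n_pcs": int(k),
            "n_individuals": pb.counts.shape[1],
        }

    ptab = pheno.aligned_to(pb_expr.individuals)
    covariates = pd.DataFrame({
        "age": ptab["age"].to_numpy(),
        "ancestry": truth.admixture[pb_expr.individuals].to_numpy(),
        "bmi": ptab["bmi"].to_numpy(),
        "n_nuclei": pb_expr.n_nuclei[pb_expr.individuals].to_numpy(),
    }, index=pb_expr.individuals)

    # ---- differential expression --------------------------------------
    if config.stages.get("de", True):
        sex_outcome = (ptab["sex"] == "male").astype(float).to_numpy()
        de_res = de_mod.de_test(int_expr.values, sex_outcome, covariates)
        de_res.to_csv(out / "de_sex.tsv", sep="\t", index=False)
        sig = de_res[de_res["q"] < config.de_fdr]
        truth_module = set(truth.sexde_module["gene_id"]) & set(de_res["gene"])
        odds, p_fisher = de_mod.fisher_overlap(
            set(sig["gene"]), truth_module, set(de_res["gene"])) \
            if len(sig) and truth_module else (float("nan"), float("nan"))
        summary["stages"]["de"] = {
            "n_tested": len(de_res), "n_significant": int(len(sig)),
            "module_overlap_odds": odds, "module_overlap_p": p_fisher,
        }

    # ---- cis-eQTL -----------------------------------------------------
    windows = windows_from_annotation(annotation, genes=expressed,
                                      flank=config.cis_window)
    cov_eqtl = covariates[["ancestry", "n_nuclei"]].copy()
    if pcs is not None:
        cov_eqtl = pd.concat([cov_eqtl, pcs], axis=1)
    sex_cov = (ptab["sex"] == "male").astype(float)
    cov_eqtl["sex"] = sex_cov.to_numpy()
    geno_expr = cohort.select_individuals(
        [cohort.individuals.index(i) for i in pb_expr.individuals])
    records = eqtl_mod.map_cis_eqtls(
        int_expr.values, geno_expr, windows, cov_eqtl,
        maf_threshold=config.maf_threshold, fdr_threshold=config.eqtl_fdr,
        cell_type=pb.cell_type)
    if config.stages.get("eqtl", True):
        records.to_csv(out / "cis_eqtl.tsv", sep="\t", index=False)
        eg = eqtl_mod.egenes(records, config.eqtl_fdr)
        planted = set(truth.eqtl_effects["gene_id"])
        summary["stages"]["eqtl"] = {
            "n_pairs": len(records), "n_egenes": len(eg),
            "planted_recovered": len(planted & set(eg)),
            "n_planted": len(planted & set(expressed)),
        }

    # ---- population differentiation ----------------------------------
    contrast = popdiff.af_contrast(pop1, pop2)
    if config.stages.get("popdiff", True):
        contrast.to_csv(out / "af_contrast.tsv", sep="\t", index=False)
        fst_all = popdiff.wc_fst(pop1, pop2)
        summary["stages"]["popdiff"] = {
            "theta_multilocus": fst_all.theta,
            "bin_counts": contrast["bin"].value_counts().to_dict(),
        }

    # ---- colocalization -----------------------------------------------
    if config.stages.get("coloc", True):
        regions = coloc_mod.select_regions(records, gwas["all"], contrast, windows,
                                           eqtl_fdr=config.eqtl_fdr,
                                           gwas_p=config.gwas_p)
        rows = []
        for gene in regions:
            e_ss = eqtl_mod.records_to_sumstats(records, geno_expr, gene)
            keys = set(e_ss.variant_keys())
            mask = [k in keys for k in gwas["all"].variant_keys()]
            g_ss = gwas["all"].subset(mask)
            if len(g_ss) < 2:
                continue
            res = coloc_mod.coloc_abf(e_ss, g_ss, priors=config.coloc_priors,
                                      gene_id=gene)
            rows.append((gene, res.n_variants, *res.pph, res.lead_shared_variant,
                         res.significant(config.pph4_threshold)))
        coloc_table = pd.DataFrame(rows, columns=[
            "gene_id", "n_variants", "PPH0", "PPH1", "PPH2", "PPH3", "PPH4",
            "lead_variant", "significant"])
        coloc_table.to_csv(out / "coloc.tsv", sep="\t", index=False)
        summary["stages"]["coloc"] = {
            "n_regions": len(regions),
            "n_colocalized": int(coloc_table["significant"].sum()) if len(coloc_table) else 0,
            "max_pph4": float(coloc_table["PPH4"].max()) if len(coloc_table) else None,
        }

    # ---- PRS / interactions -------------------------------------------
    if config.stages.get("prs", True):
        seed_fst, seed_prs = subseeds["fst"], subseeds["prs"]
        clumped = prs.clump(gwas["all"], cohort)
        module_windows = windows_from_annotation(
            annotation, genes=truth.sexde_module["gene_id"], flank=config.cis_window)
        set_variants = prs.assign_set_variants(clumped, module_windows, cohort)
        bg_windows = windows_from_annotation(annotation, genes=expressed,
                                             flank=config.cis_window)
        background = prs.assign_set_variants(clumped, bg_windows, cohort)
        pt = pheno.aligned_to(cohort.individuals)
        y = expr_mod.inverse_normal(pt["tg"].to_numpy())
        cov_prs = pd.DataFrame({
            "age": pt["age"], "age2": pt["age"] ** 2, "bmi": pt["bmi"],
            "ancestry": truth.admixture[cohort.individuals],
        })
        prs_summary = {}
        for stratum in ("all", "male", "female"):
            if stratum == "all":
                sel = np.ones(cohort.n_individuals, dtype=bool)
            else:
                sel = np.asarray(cohort.sex) == stratum
            g_s = cohort.select_individuals(sel)
            cov_s = cov_prs[sel].copy()
            if stratum == "all":
                cov_s["sex"] = (pt["sex"] == "male").astype(float).to_numpy()
            fit = prs.score_and_fit(set_variants, gwas[stratum], g_s,
                                    y[sel], cov_s, stratum=stratum)
            fit = prs.competitive_p(fit, background, gwas[stratum], g_s, y[sel],
                                    cov_s, n_perm=config.n_perm,
                                    seed=seed_prs.spawn(1)[0])
            prs_summary[stratum] = {"r2": fit.r2, "p": fit.p, "p_comp": fit.p_comp,
                                    "n_set_variants": len(set_variants),
                                    "n_individuals": int(g_s.n_individuals)}
        inter = prs.prs_sex_interaction(
            prs.prs_scores(set_variants, gwas["all"], cohort), y,
            np.asarray(cohort.sex), cov_prs)
        gxs = prs.gxsex_scan(gwas["male"], gwas["female"], cohort, y,
                             np.asarray(cohort.sex), cov_prs,
                             set_windows=module_windows, gwas_p=config.gwas_p)
        gxs.to_csv(out / "gxsex.tsv", sep="\t", index=False)
        fst_enr = popdiff.fst_enrichment(
            set_variants, background, pop1, pop2,
            n_perm=max(100, config.n_perm), seed=seed_fst) \
            if set_variants and len(background) > len(set_variants) else None
        summary["stages"]["prs"] = {
            "strata": prs_summary,
            "prs_sex_interaction": inter,
            "gxsex_candidates": int(len(gxs)),
            "gxsex_significant": int(gxs["significant"].sum()) if len(gxs) else 0,
            "fst_enrichment": None if fst_enr is None else
            {"theta_obs": fst_enr["theta_obs"], "p_perm": fst_enr["p_perm"]},
        }

    write_json(summary, out / "summary.json")
    return summary
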