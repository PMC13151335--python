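"""Cell-type level cis-eQTL mapping on pseudobulk expression.

For every gene, every variant with MAF strictly above the threshold and
position inside the gene's cis window (gene body +/- 500 kb, closed
interval) is tested by OLS of inverse-normal expression on dosage plus
covariates (global ancestry, nucleus count, expression PCs).  Per-pair t and
p come from the dosage slope via covariate residualization, which is exactly
equivalent to the joint multiple regression; FDR is Benjamini-Hochberg over
all tested pairs within the cell-type (pooling across cell-types available
by flag in the caller).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import CisWindow, GenotypeMatrix
from .regression import bh_fdr, design_matrix, marginal_slope_tests

log = logging.getLogger(__name__)

EQTL_COLUMNS = ["gene_id", "variant_id", "chrom", "pos", "effect_allele", "eaf",
                "beta", "se", "t", "p", "q", "is_lead", "cell_type"]


def map_cis_eqtls(
    expr,
    g: GenotypeMatrix,
    windows: dict[str, CisWindow],
    covariates: pd.DataFrame | None = None,
    maf_threshold: float = 0.10,
    fdr_threshold: float = 0.10,
    cell_type: str = "",
    min_extra_df: int = 5,
) -> pd.DataFrame:
    """Run the cis scan; returns one row per tested gene-variant pair.

    ``expr`` is a genes x individuals DataFrame (INT values) or a
    NormalizedExpression; its columns must match ``g.individuals`` exactly.
    """
    values = expr.values if hasattr(expr, "tmm_factors") else pd.DataFrame(expr)
    if list(values.columns) != list(g.individuals):
        raise ValueError("individual mismatch between expression and genotypes")
    n = g.n_individuals
    X = design_matrix(covariates, n)
    n_model_params = X.shape[1] + 1  # covariates + intercept + dosage
    if n < n_model_params - 1 + min_extra_df:
        raise ValueError(f"n={n} too small for {X.shape[1]} covariate columns")
    df = n - n_model_params

    maf = g.maf()
    vmeta = g.variants
    chrom = vmeta["chrom"].to_numpy()
    pos = vmeta["pos"].to_numpy(dtype=int)
    maf_ok = maf > maf_threshold  # strict inequality

    dos = g.dosages_imputed()
    records = []
    any_variant = False
    for gene, win in windows.items():
        if gene not in values.index:
            continue
        in_win = maf_ok & (chrom == win.chrom) & (pos >= win.start) & (pos <= win.end)
        idx = np.nonzero(in_win)[0]
        if idx.size == 0:
            continue
        any_variant = True
        y = values.loc[gene].to_numpy(dtype=float)[:, None]
        beta, se, t, p, _ = marginal_slope_tests(y, dos[:, idx], X, df_adjust=df)
        eaf = g.eaf()[idx]
        records.append(pd.DataFrame({
            "gene_id": gene,
            "variant_id": vmeta["id"].to_numpy()[idx],
            "chrom": chrom[idx],
            "pos": pos[idx],
            "effect_allele": vmeta["effect_allele"].to_numpy()[idx],
            "eaf": eaf,
            "beta": beta[0],
            "se": se[0],
            "t": t[0],
            "p": p[0],
        }))
    if not any_variant:
        raise ValueError("no variants pass the MAF filter inside any cis window")
    out = pd.concat(records, ignore_index=True)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["cell_type"] = cell_type
    out["is_lead"] = False
    out = _flag_leads(out)
    n_sig = int((out["q"] < fdr_threshold).sum())
    log.info("%s: %d pairs tested, %d significant at q<%.2g",
             cell_type or "cis-eQTL", len(out), n_sig, fdr_threshold)
    return out


def _flag_leads(records: pd.DataFrame) -> pd.DataFrame:
    """Mark one lead pair per gene: min p, ties by larger |t| then smaller pos."""
    records = records.copy()
    key = records.assign(abs_t=records["t"].abs())
    order = key.sort_values(["gene_id", "p", "abs_t", "pos"],
                            ascending=[True, True, False, True], kind="mergesort")
    lead_idx = order.groupby("gene_id", sort=False).head(1).index
    records.loc[lead_idx, "is_lead"] = True
    return records


def egenes(records: pd.DataFrame, fdr_threshold: float = 0.10) -> list:
    """Genes with at least one significant cis pair."""
    sig = records[records["q"] < fdr_threshold]
    return sorted(sig["gene_id"].unique().tolist())


def records_to_sumstats(records: pd.DataFrame, g: GenotypeMatrix, gene_id: str,
                        n: int | None = None):
    """Repackage one gene's cis records as summary statistics (for coloc)."""
    from .datamodel import SummaryStats

    sub = records[records["gene_id"] == gene_id]
    meta = g.variants.set_index("id")
    other = meta.loc[sub["variant_id"], "other_allele"].to_numpy()
    table = pd.DataFrame({
        "id": sub["variant_id"].to_numpy(),
        "chrom": sub["chrom"].to_numpy(),
        "pos": sub["pos"].to_numpy(),
        "effect_allele": sub["effect_allele"].to_numpy(),
        "other_allele": other,
        "eaf": sub["eaf"].to_numpy(),
        "beta": sub["beta"].to_numpy(),
        "se": sub["se"].to_numpy(),
        "p": np.clip(sub["p"].to_numpy(), np.finfo(float).tiny, 1.0),
        "n": n if n is not None else g.n_individuals,
    })
    return SummaryStats(table)


def classify_sharing(records_by_celltype: dict[str, pd.DataFrame],
                     fdr_threshold: float = 0.10) -> pd.DataFrame:
    """Classify each significant signal by how many cell-types show it.

    ``specific``: significant in exactly one cell-type, ``shared``: in all
    tested cell-types, ``partial``: otherwise.  Returns per-pair classes plus
    an ``egene_class`` table (same classes at the gene level).
    """
    if len(records_by_celltype) < 2:
        raise ValueError("sharing classification needs >= 2 cell-types")
    n_ct = len(records_by_celltype)
    pair_hits: dict[tuple, int] = {}
    gene_hits: dict[str, int] = {}
    for ct, rec in records_by_celltype.items():
        sig = rec[rec["q"] < fdr_threshold]
        for key in set(zip(sig["gene_id"], sig["variant_id"])):
            pair_hits[key] = pair_hits.get(key, 0) + 1
        for gene in set(sig["gene_id"]):
            gene_hits[gene] = gene_hits.get(gene, 0) + 1

    def label(c):
        return "specific" if c == 1 else ("shared" if c == n_ct else "partial")

    pairs = pd.DataFrame(
        [(g, v, c, label(c)) for (g, v), c in sorted(pair_hits.items())],
        columns=["gene_id", "variant_id", "n_celltypes_significant", "class"],
    )
    genes = pd.DataFrame(
        [(g, c, label(c)) for g, c in sorted(gene_hits.items())],
        columns=["gene_id", "n_celltypes_significant", "egene_class"],
    )
    return pairs, genes


def assess_replication(discovery: pd.DataFrame, replication: pd.DataFrame,
                       fdr_threshold: float = 0.10) -> pd.DataFrame:
    """Per-eGene replication decision.

    The replication FDR is recomputed over only the discovery-significant
    pairs present in the replication scan.  An eGene replicates iff at least
    one of its discovery-significant pairs reaches replication q below the
    threshold with a concordant effect sign; eGenes with no overlapping
    pairs are ``untested``.
    """
    disc_sig = discovery[discovery["q"] < fdr_threshold]
    if disc_sig.empty:
        return pd.DataFrame(columns=["gene_id", "status"])
    rep = replication.set_index(["gene_id", "variant_id"])
    keys = list(zip(disc_sig["gene_id"], disc_sig["variant_id"]))
    present = [k in rep.index for k in keys]
    overlap = disc_sig[present].copy()
    if not overlap.empty:
        rep_rows = rep.loc[list(zip(overlap["gene_id"], overlap["variant_id"]))]
        overlap["rep_p"] = rep_rows["p"].to_numpy()
        overlap["rep_beta"] = rep_rows["beta"].to_numpy()
        overlap["rep_q"] = bh_fdr(overlap["rep_p"].to_numpy())
    statuses = []
    for gene, grp in disc_sig.groupby("gene_id"):
        ov = overlap[overlap["gene_id"] == gene] if not overlap.empty else overlap
        if ov is None or len(ov) == 0:
            statuses.append((gene, "untested"))
            continue
        hit = (ov["rep_q"] < fdr_threshold) & (np.sign(ov["rep_beta"]) == np.sign(ov["beta"]))
        statuses.append((gene, "replicated" if hit.any() else "not_replicated"))
    return pd.DataFrame(statuses, columns=["gene_id", "status"])
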