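"""Pseudobulk expression processing.

Pipeline per cell-type: sum nucleus-level UMI counts into per-individual
pseudobulk, keep expressed genes (TPM and raw-count filters), compute TMM
library scale factors and log-CPM, rank-based inverse-normal transform per
gene, and choose the number of expression PCs by permutation-based parallel
analysis (Buja-Eyuboglu).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneAnnotation

log = logging.getLogger(__name__)


@dataclass
class PseudobulkMatrix:
    """Gene x individual summed UMI counts for one cell-type."""

    cell_type: str
    counts: pd.DataFrame  # genes x individuals, non-negative integers
    n_nuclei: pd.Series  # per individual
    excluded_individuals: list = field(default_factory=list)

    @property
    def lib_size(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def genes(self) -> list:
        return self.counts.index.tolist()

    @property
    def individuals(self) -> list:
        return self.counts.columns.tolist()


@dataclass
class NormalizedExpression:
    """Per-gene normalized values plus the normalization metadata."""

    values: pd.DataFrame  # genes x individuals
    tmm_factors: pd.Series
    transform: str  # "log-CPM" or "INT"
    n_pcs: int | None = None
    pcs: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_pseudobulk(
    umi_counts: np.ndarray,
    gene_ids: list,
    nucleus_meta: pd.DataFrame,
    cell_type: str,
) -> PseudobulkMatrix:
    """Sum nucleus x gene UMI counts per individual for one cell-type.

    ``nucleus_meta`` must carry ``individual`` and ``cell_type`` columns with
    one row per nucleus (row-aligned with ``umi_counts``).  Individuals with
    zero nuclei of the requested cell-type are excluded and flagged.
    """
    if not {"individual", "cell_type"}.issubset(nucleus_meta.columns):
        raise ValueError("nucleus_meta must have 'individual' and 'cell_type' columns")
    if len(nucleus_meta) != umi_counts.shape[0]:
        raise ValueError("nucleus_meta rows must match umi_counts rows")
    known = set(nucleus_meta["cell_type"].unique())
    if cell_type not in known:
        raise ValueError(f"unknown cell-type {cell_type!r}; present: {sorted(known)}")
    sel = (nucleus_meta["cell_type"] == cell_type).to_numpy()
    sub = np.asarray(umi_counts)[sel]
    indiv = nucleus_meta.loc[sel, "individual"].to_numpy()
    all_individuals = pd.unique(nucleus_meta["individual"])
    order = pd.unique(indiv)
    cols = {}
    for person in order:
        cols[person] = sub[indiv == person].sum(axis=0)
    counts = pd.DataFrame(cols, index=gene_ids).astype(int)
    n_nuclei = pd.Series({p: int((indiv == p).sum()) for p in order})
    excluded = [p for p in all_individuals if p not in set(order)]
    if excluded:
        log.info("%s: %d individuals with zero nuclei excluded", cell_type, len(excluded))
    return PseudobulkMatrix(cell_type, counts, n_nuclei, excluded_individuals=excluded)


# ---------------------------------------------------------------------------
# expressed-gene filters
# ---------------------------------------------------------------------------

def tpm(counts: pd.DataFrame, lengths: np.ndarray) -> pd.DataFrame:
    """Transcripts per million from raw counts and union-exon lengths."""
    rate = counts.div(pd.Series(lengths, index=counts.index), axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def filter_expressed(
    pb: PseudobulkMatrix,
    annotation: GeneAnnotation,
    mode: str = "eqtl",
    tpm_threshold: float = 0.1,
    min_count: int = 6,
    min_fraction: float = 0.20,
    top_read_fraction: float = 0.90,
) -> list:
    """Expressed-gene list for a cell-type.

    Keeps genes with TPM > ``tpm_threshold`` and raw count >= ``min_count``
    in more than ``min_fraction`` of individuals.  ``mode="de"`` additionally
    restricts to genes within the top ``top_read_fraction`` of cumulative
    total reads (applied after the other two filters).
    """
    if mode not in ("eqtl", "de"):
        raise ValueError(f"unknown mode {mode!r}")
    lengths = annotation.lengths_for(pb.genes)  # raises listing missing genes
    t = tpm(pb.counts, lengths)
    frac_expressed = ((t > tpm_threshold) & (pb.counts >= min_count)).mean(axis=1)
    keep = frac_expressed > min_fraction
    genes = pb.counts.index[keep]
    if mode == "de":
        totals = pb.counts.loc[genes].sum(axis=1).sort_values(ascending=False)
        cumfrac = totals.cumsum() / totals.sum()
        genes = totals.index[cumfrac <= top_read_fraction]
    return genes.tolist()


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_column: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, geometric mean 1.

    The reference column is the sample whose upper quartile of non-zero
    count fractions is closest to the mean upper quartile.  Per sample,
    the factor is ``2**(weighted trimmed mean of M)`` over genes expressed
    in both sample and reference, trimming ``trim_m`` of the M-values and
    ``trim_a`` of the A-values on each side, with inverse asymptotic
    binomial variances as weights.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 individuals")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    frac = counts.to_numpy(dtype=float) / lib
    if ref_column is None:
        uq = np.array([np.quantile(frac[:, j][frac[:, j] > 0], 0.75) for j in range(counts.shape[1])])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = counts.columns.get_loc(ref_column)
    ref = frac[:, ref_j]
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_j:
            continue
        obs = frac[:, j]
        both = (obs > 0) & (ref > 0)
        if not both.any():
            raise ValueError(
                f"library {counts.columns[j]!r} shares no expressed genes with the reference"
            )
        m = np.log2(obs[both] / ref[both])
        a = 0.5 * np.log2(obs[both] * ref[both])
        # asymptotic (delta-method) binomial variance of M
        nobs = counts.iloc[:, j].to_numpy(dtype=float)[both]
        nref = counts.iloc[:, ref_j].to_numpy(dtype=float)[both]
        w = (lib[j] - nobs) / (lib[j] * nobs) + (lib[ref_j] - nref) / (lib[ref_j] * nref)
        keep = _doubletrim(m, a, trim_m, trim_a)
        if keep.sum() == 0 or np.isclose(np.abs(m[keep]).max(), 0.0, atol=1e-10):
            factors[j] = 1.0
            continue
        factors[j] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def _doubletrim(m: np.ndarray, a: np.ndarray, trim_m: float, trim_a: float) -> np.ndarray:
    """Boolean mask keeping values inside both rank trims (edgeR convention)."""
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    return (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)


def tmm_normalize(pb: PseudobulkMatrix, prior_count: float = 0.5) -> NormalizedExpression:
    """TMM-normalized log2 counts-per-million."""
    factors = tmm_factors(pb.counts)
    eff_lib = pb.lib_size * factors
    cpm = (pb.counts + prior_count).div(eff_lib, axis=1) * 1e6
    return NormalizedExpression(np.log2(cpm), factors, transform="log-CPM")


# ---------------------------------------------------------------------------
# rank-based inverse-normal transform
# ---------------------------------------------------------------------------

def inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom-offset rank-based inverse-normal transform of a 1-D vector.

    ``out = Phi^-1((rank - offset) / (n + 1 - 2*offset))``; ties get average
    ranks, missing values are preserved.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    v = x[ok]
    if len(v) < 3:
        raise ValueError("inverse_normal needs >= 3 non-missing values")
    if np.allclose(v, v[0]):
        raise ValueError("constant vector: ranks undefined")
    ranks = stats.rankdata(v, method="average")
    out[ok] = stats.norm.ppf((ranks - offset) / (len(v) + 1 - 2 * offset))
    return out


def inverse_normal_rows(expr: NormalizedExpression) -> NormalizedExpression:
    """Apply the inverse-normal transform to each gene (row)."""
    vals = expr.values.apply(lambda row: pd.Series(inverse_normal(row.to_numpy()),
                                                   index=row.index), axis=1)
    return NormalizedExpression(vals, expr.tmm_factors, transform="INT",
                                n_pcs=expr.n_pcs, pcs=expr.pcs)


# ---------------------------------------------------------------------------
# number of expression PCs (parallel analysis)
# ---------------------------------------------------------------------------

def choose_num_pcs_be(
    expr, n_perm: int = 50, alpha: float = 0.05, seed=None
) -> int:
    """Permutation parallel analysis for the number of leading PCs.

    Each permutation shuffles the values within each gene independently,
    destroying between-gene correlation while preserving the marginals.
    Components are tested sequentially from the first: component i is
    retained while its add-one permutation p-value,
    ``(1 + #{perm eigenvalue_i >= observed_i}) / (n_perm + 1)``, is at most
    ``alpha``; K is the index of the first failure.  The add-one form keeps
    the test valid (never anti-conservative) at any permutation count.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    X = expr.values.to_numpy(dtype=float) if isinstance(expr, NormalizedExpression) else np.asarray(expr, dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    n_genes, n_indiv = X.shape
    rank = min(n_genes, n_indiv) - 1
    obs = _eigvals(X, rank)
    rng = np.random.default_rng(seed)
    perm_eigs = np.empty((n_perm, rank))
    for b in range(n_perm):
        P = _permute_within_rows(X, rng)
        perm_eigs[b] = _eigvals(P, rank)
    k = 0
    for i in range(rank):
        p_i = (1 + int(np.sum(perm_eigs[:, i] >= obs[i]))) / (n_perm + 1)
        if p_i <= alpha:
            k += 1
        else:
            break
    return k


def _permute_within_rows(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = np.argsort(rng.random(X.shape), axis=1)
    return np.take_along_axis(X, idx, axis=1)


def _eigvals(X: np.ndarray, rank: int) -> np.ndarray:
    s = np.linalg.svd(X, compute_uv=False)
    eig = (s ** 2) / (X.shape[1] - 1)
    return eig[:rank]


def expression_pcs(expr: NormalizedExpression, k: int) -> pd.DataFrame:
    """Individual x K PC scores of the gene-centred expression matrix."""
    X = expr.values.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = (vt[:k].T * s[:k])
    return pd.DataFrame(scores, index=expr.values.columns,
                        columns=[f"PC{i + 1}" for i in range(k)])
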