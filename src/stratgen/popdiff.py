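"""Allele-frequency contrasts and Weir-Cockerham F_ST.

The two-population F_ST estimator decomposes the allele-frequency variance
into among-population (a), among-individual-within-population (b) and
within-individual (c) components from sample sizes, allele frequencies and
observed heterozygote proportions.  The multi-locus estimate is the ratio
of sums, Theta = sum(a) / sum(a+b+c), not the mean of per-locus ratios.
Enrichment of a variant set's Theta against size-matched random background
sets uses the add-one permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix

log = logging.getLogger(__name__)

AF_BIN_LABELS = ["<5%", "5-10%", ">10%"]


def af_contrast(g1: GenotypeMatrix, g2: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant effect-allele frequency contrast between two cohorts.

    Both cohorts must be allele-harmonized: shared variants are matched by
    (chrom, pos, allele-pair) key and must agree on the effect allele.
    Bins partition |AF1 - AF2| at 0.05 and 0.10: [0, 0.05), [0.05, 0.10],
    (0.10, 1].
    """
    k1 = {k: i for i, k in enumerate(g1.variant_keys())}
    k2 = {k: i for i, k in enumerate(g2.variant_keys())}
    shared = [k for k in k1 if k in k2]
    if not shared:
        raise ValueError("no shared variants between cohorts")
    i1 = np.array([k1[k] for k in shared])
    i2 = np.array([k2[k] for k in shared])
    ea1 = g1.variants["effect_allele"].to_numpy()[i1]
    ea2 = g2.variants["effect_allele"].to_numpy()[i2]
    if (ea1 != ea2).any():
        bad = g1.variants["id"].to_numpy()[i1[ea1 != ea2]][:5].tolist()
        raise ValueError(f"unharmonized variants (effect alleles differ): {bad}")
    af1 = g1.eaf()[i1]
    af2 = g2.eaf()[i2]
    diff = np.abs(af1 - af2)
    # round at the 12th decimal so exact boundary frequencies bin stably
    dr = np.round(diff, 12)
    bins = np.where(dr < 0.05, "<5%", np.where(dr <= 0.10, "5-10%", ">10%"))
    return pd.DataFrame({
        "id": g1.variants["id"].to_numpy()[i1],
        "chrom": g1.variants["chrom"].to_numpy()[i1],
        "pos": g1.variants["pos"].to_numpy()[i1],
        "effect_allele": ea1,
        "af_pop1": af1,
        "af_pop2": af2,
        "diff": diff,
        "bin": bins,
    })


@dataclass
class FstComponents:
    """Per-locus variance components and the multi-locus estimate."""

    per_locus: pd.DataFrame  # id, a, b, c, theta_hat, included
    theta: float  # ratio-of-sums multi-locus estimate

    @property
    def theta_mean_of_ratios(self) -> float:
        """Naive mean of per-locus ratios (provided for comparison only)."""
        inc = self.per_locus[self.per_locus["included"]]
        return float(inc["theta_hat"].mean())


def _genotype_summaries(g: GenotypeMatrix, idx: np.ndarray):
    """Per-locus (n, p, het share) from hard calls, missing excluded."""
    calls = g.hard_calls()[:, idx]
    ok = ~np.isnan(calls)
    n = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.nansum(calls, axis=0) / (2.0 * np.where(n > 0, n, np.nan))
        h = np.nansum(calls == 1, axis=0) / np.where(n > 0, n, np.nan)
    return n, p, h


def wc_fst(g1: GenotypeMatrix, g2: GenotypeMatrix,
           variant_ids: list | None = None) -> FstComponents:
    """Weir-Cockerham (1984) two-population F_ST.

    ``variant_ids`` restricts the calculation to the named variants (matched
    by ID in ``g1``; ``g2`` is matched on the orientation-free variant key).
    Loci monomorphic in the pooled sample contribute zero components and are
    excluded from the ratio of sums.
    """
    if g1.n_individuals == 0 or g2.n_individuals == 0:
        raise ValueError("both populations must be non-empty")
    k2 = {k: i for i, k in enumerate(g2.variant_keys())}
    keys1 = g1.variant_keys()
    if variant_ids is not None:
        wanted = set(variant_ids)
        idx1 = np.array([j for j, vid in enumerate(g1.variants["id"]) if vid in wanted],
                        dtype=int)
    else:
        idx1 = np.arange(g1.n_variants)
    pairs = [(j, k2[keys1[j]]) for j in idx1 if keys1[j] in k2]
    if not pairs:
        raise ValueError("no shared variants to compute F_ST on")
    i1 = np.array([a for a, _ in pairs])
    i2 = np.array([b for _, b in pairs])
    # orientation: align pop2 allele frequency to pop1's effect allele
    flip = (g1.variants["effect_allele"].to_numpy()[i1]
            != g2.variants["effect_allele"].to_numpy()[i2])

    n1, p1, h1 = _genotype_summaries(g1, i1)
    n2, p2, h2 = _genotype_summaries(g2, i2)
    p2 = np.where(flip, 1.0 - p2, p2)

    a, b, c = wc_components(n1, p1, h1, n2, p2, h2)
    denom = a + b + c
    pooled_p = (2 * n1 * p1 + 2 * n2 * p2) / (2 * n1 + 2 * n2)
    mono = (pooled_p <= 0) | (pooled_p >= 1) | ~np.isfinite(pooled_p)
    a = np.where(mono, 0.0, a)
    b = np.where(mono, 0.0, b)
    c = np.where(mono, 0.0, c)
    denom = np.where(mono, 0.0, denom)
    included = ~mono & (denom != 0)
    if mono.any():
        log.info("F_ST: %d pooled-monomorphic loci excluded from the ratio", int(mono.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_hat = np.where(included, a / np.where(denom == 0, np.nan, denom), 0.0)
    table = pd.DataFrame({
        "id": g1.variants["id"].to_numpy()[i1],
        "a": a, "b": b, "c": c,
        "theta_hat": theta_hat,
        "included": included,
    })
    tot = denom[included].sum()
    theta = float(a[included].sum() / tot) if tot > 0 else float("nan")
    return FstComponents(table, theta)


def wc_components(n1, p1, h1, n2, p2, h2):
    """Vectorized Weir-Cockerham a, b, c for two populations.

    Inputs are per-locus sample sizes, effect-allele frequencies and observed
    heterozygote proportions for each population.
    """
    r = 2.0
    n1, p1, h1, n2, p2, h2 = map(np.asarray, (n1, p1, h1, n2, p2, h2))
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def equalize_sample_sizes(g1: GenotypeMatrix, g2: GenotypeMatrix, seed=None):
    """Randomly subsample the larger cohort to match the smaller one."""
    rng = np.random.default_rng(seed)
    if g1.n_individuals > g2.n_individuals:
        idx = rng.choice(g1.n_individuals, g2.n_individuals, replace=False)
        return g1.select_individuals(np.sort(idx)), g2
    if g2.n_individuals > g1.n_individuals:
        idx = rng.choice(g2.n_individuals, g1.n_individuals, replace=False)
        return g1, g2.select_individuals(np.sort(idx))
    return g1, g2


def fst_enrichment(observed_set: list, background: list,
                   g1: GenotypeMatrix, g2: GenotypeMatrix,
                   n_perm: int = 10_000, seed=None) -> dict:
    """Permutation p for the observed set's multi-locus Theta.

    Each permutation draws ``len(observed_set)`` variants uniformly without
    replacement from the background and recomputes Theta;
    ``p = (1 + #{Theta_perm >= Theta_obs}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    background = list(background)
    observed_set = list(observed_set)
    if not set(observed_set) <= set(background):
        raise ValueError("observed set must be contained in the background")
    if len(background) < len(observed_set):
        raise ValueError("background smaller than observed set")
    theta_obs = wc_fst(g1, g2, observed_set).theta
    rng = np.random.default_rng(seed)
    # precompute per-locus components over the whole background once
    comp = wc_fst(g1, g2, background).per_locus.set_index("id")
    a = comp["a"].to_numpy()
    denom = (comp["a"] + comp["b"] + comp["c"]).to_numpy()
    bg_ids = comp.index.to_numpy()
    k = len(observed_set)
    exceed = 0
    thetas = np.empty(n_perm)
    for b in range(n_perm):
        pick = rng.choice(len(bg_ids), k, replace=False)
        tot = denom[pick].sum()
        thetas[b] = a[pick].sum() / tot if tot > 0 else np.nan
    exceed = int(np.sum(thetas >= theta_obs))
    p_perm = (1 + exceed) / (n_perm + 1)
    return {"theta_obs": theta_obs, "p_perm": p_perm, "n_perm": n_perm,
            "perm_thetas": thetas}
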