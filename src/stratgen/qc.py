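"""Genotype QC and allele harmonization.

Harmonization aligns the effect allele of a target genotype matrix with a
reference set of summary statistics: matched variants are kept, variants
whose alleles are swapped get their dosages recoded as ``2 - d`` (which
preserves every downstream association statistic), and strand-ambiguous
(A/T, C/G) pairs are removed because their orientation cannot be resolved
from allele labels alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import GenotypeMatrix, SummaryStats, is_palindromic

log = logging.getLogger(__name__)


@dataclass
class HarmonizationReport:
    kept: int = 0
    flipped: int = 0
    dropped_palindromic: int = 0
    dropped_unmatched_target: int = 0
    dropped_unmatched_reference: int = 0
    flags: dict = field(default_factory=dict)  # variant id -> kept/flipped/...


def harmonize_alleles(
    target: GenotypeMatrix, reference: SummaryStats
) -> tuple[GenotypeMatrix, SummaryStats, HarmonizationReport]:
    """Align target dosages to the reference effect allele.

    Returns the harmonized (target, reference, report) restricted to the
    shared, unambiguous variants, in target order.
    """
    report = HarmonizationReport()
    ref_by_key: dict[tuple, int] = {}
    for i, key in enumerate(reference.variant_keys()):
        ref_by_key.setdefault(key, i)

    tv = target.variants
    keep_idx, ref_idx, flip = [], [], []
    for j, key in enumerate(target.variant_keys()):
        a1, a2 = tv["effect_allele"].iat[j], tv["other_allele"].iat[j]
        vid = tv["id"].iat[j]
        if key not in ref_by_key:
            report.dropped_unmatched_target += 1
            report.flags[vid] = "unmatched"
            continue
        if is_palindromic(a1, a2):
            report.dropped_palindromic += 1
            report.flags[vid] = "palindromic"
            continue
        i = ref_by_key[key]
        ref_ea = reference.table["effect_allele"].iat[i]
        keep_idx.append(j)
        ref_idx.append(i)
        if ref_ea == a1:
            flip.append(False)
            report.kept += 1
            report.flags[vid] = "kept"
        else:
            flip.append(True)
            report.flipped += 1
            report.flags[vid] = "flipped"
    if not keep_idx:
        raise ValueError("no overlapping variants between target and reference")
    report.dropped_unmatched_reference = len(reference) - len(set(ref_idx))

    out = target.select_variants(np.array(keep_idx))
    flip = np.array(flip)
    if flip.any():
        out.dosages[:, flip] = 2.0 - out.dosages[:, flip]
        cols = out.variants.columns
        ea = out.variants["effect_allele"].to_numpy().copy()
        oa = out.variants["other_allele"].to_numpy().copy()
        ea[flip], oa[flip] = oa[flip], ea[flip]
        out.variants = out.variants.assign(effect_allele=ea, other_allele=oa)[cols]
    ref_out = SummaryStats(
        reference.table.iloc[ref_idx].reset_index(drop=True), reference.stratum
    )
    return out, ref_out, report


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value from genotype counts.

    Sums the probabilities of all heterozygote counts (with the observed
    allele counts fixed) no more probable than the observed one, using the
    stable recurrence on adjacent heterozygote counts.
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = n_het + 2 * min(n_hom1, n_hom2)
    # probabilities over feasible het counts (same parity as n_rare)
    het_min = n_rare % 2
    hets = list(range(het_min, min(n_rare, 2 * n - n_rare) + 1, 2))
    probs = {}
    mid = hets[len(hets) // 2]
    probs[mid] = 1.0
    # P(h+2)/P(h) = 4*hom_r*hom_c / ((h+2)(h+1)) with hom_r=(n_rare-h)/2, hom_c=n-h-hom_r
    h = mid
    while h + 2 <= hets[-1]:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
    h = mid
    while h - 2 >= hets[0]:
        hom_r = (n_rare - h) // 2 + 1
        hom_c = n - h - hom_r + 2
        probs[h - 2] = probs[h] * h * (h - 1.0) / (4.0 * hom_r * hom_c)
        h -= 2
    total = sum(probs.values())
    obs = probs[n_het]
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p per variant from hard-called genotypes."""
    calls = g.hard_calls()
    out = np.ones(g.n_variants)
    for j in range(g.n_variants):
        col = calls[:, j]
        col = col[~np.isnan(col)]
        n_hom1 = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_hom2 = int((col == 2).sum())
        out[j] = hwe_exact_p(n_het, n_hom1, n_hom2)
    return out


@dataclass
class QCThresholds:
    max_missingness: float = 0.05
    hwe_p: float = 1e-12
    min_maf: float = 0.0  # stage-specific; 0 keeps all polymorphic variants
    drop_monomorphic: bool = True
    hwe_on_hard_calls: bool = True


def variant_qc(g: GenotypeMatrix, thresholds: QCThresholds | None = None) -> GenotypeMatrix:
    """Apply the variant-level filters; raises if nothing survives.

    Filters: monomorphic sites, missingness above threshold, exact-HWE
    p below threshold (on hard calls), and optionally MAF at or below the
    stage threshold (strict ``>`` comparison).
    """
    thr = thresholds or QCThresholds()
    keep = np.ones(g.n_variants, dtype=bool)
    keep &= g.missingness() <= thr.max_missingness
    eaf = g.eaf()
    if thr.drop_monomorphic:
        keep &= (eaf > 0) & (eaf < 1)
    if thr.min_maf > 0:
        keep &= g.maf() > thr.min_maf
    if thr.hwe_on_hard_calls:
        hwe = hwe_pvalues(g)
        keep &= hwe >= thr.hwe_p
    else:
        log.info("dosage-only data: HWE filter skipped")
    if not keep.any():
        raise ValueError("empty after QC: all variants removed")
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("variant QC removed %d of %d variants", n_drop, g.n_variants)
    return g.select_variants(keep)
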