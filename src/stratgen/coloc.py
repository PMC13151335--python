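"""Wakefield approximate-Bayes-factor colocalization.

Under a single-causal-variant assumption per trait, the log approximate
Bayes factor at each variant is

    lABF = 0.5 * [ln(1 - r) + r * z^2],  r = W / (W + se^2),  z = beta / se,

with W the prior variance of the true effect.  Hypothesis masses sum the
ABFs over causal-variant configurations: H0 no association, H1/H2 one
trait only, H3 two distinct causal variants, H4 one shared variant.  All
sums are evaluated in log space so z-scores in the tens remain stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .datamodel import SummaryStats

log = logging.getLogger(__name__)

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)  # p1, p2, p12


def wakefield_labf(beta, se, W) -> np.ndarray:
    """Log approximate Bayes factor for association at one or more variants."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("prior variance W must be >= 0")
    r = W / (W + se ** 2)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z ** 2)


def estimate_sdY(ss: SummaryStats) -> float:
    """Trait SD from summary statistics via the weak-effect identity.

    For a standardized-genotype regression, var(Y) ~ n * se^2 * 2*eaf*(1-eaf)
    per variant; the median over variants is used for robustness.
    """
    t = ss.table
    if "eaf" not in t.columns or "n" not in t.columns:
        raise ValueError("sdY estimation needs 'eaf' and 'n' columns")
    eaf = t["eaf"].to_numpy(dtype=float)
    var_y = t["n"].to_numpy(dtype=float) * t["se"].to_numpy(dtype=float) ** 2 \
        * 2.0 * eaf * (1.0 - eaf)
    var_y = var_y[np.isfinite(var_y) & (var_y > 0)]
    if var_y.size == 0:
        raise ValueError("cannot estimate sdY: no usable variants")
    return float(np.sqrt(np.median(var_y)))


def prior_variance(ss: SummaryStats, sd_scale: float = 0.15) -> float:
    """Quantitative-trait prior effect variance W = (sd_scale * sdY)^2."""
    return (sd_scale * estimate_sdY(ss)) ** 2


@dataclass
class ColocResult:
    gene_id: str
    n_variants: int
    pph: np.ndarray  # PPH0..PPH4
    priors: tuple
    lead_shared_variant: str | None = None

    @property
    def pph4(self) -> float:
        return float(self.pph[4])

    def significant(self, threshold: float = 0.5) -> bool:
        return self.pph4 > threshold


def coloc_abf(
    trait1: SummaryStats,
    trait2: SummaryStats,
    priors: tuple = DEFAULT_PRIORS,
    W1: float | None = None,
    W2: float | None = None,
    gene_id: str = "",
) -> ColocResult:
    """Colocalize two association signals over a shared variant list.

    Variants are intersected on the orientation-free key; W defaults to the
    quantitative-trait prior (0.15 * sdY)^2 estimated per trait from its own
    summary statistics.
    """
    p1, p2, p12 = priors
    k1 = {k: i for i, k in enumerate(trait1.variant_keys())}
    k2 = {k: i for i, k in enumerate(trait2.variant_keys())}
    shared = [k for k in k1 if k in k2]
    if len(shared) < 2:
        raise ValueError(f"need >= 2 shared variants, got {len(shared)}")
    dropped = (len(k1) - len(shared), len(k2) - len(shared))
    if any(dropped):
        log.info("coloc: dropped %d/%d single-trait variants", *dropped)
    i1 = np.array([k1[k] for k in shared])
    i2 = np.array([k2[k] for k in shared])
    t1 = trait1.table.iloc[i1]
    t2 = trait2.table.iloc[i2]
    if W1 is None:
        W1 = prior_variance(trait1)
    if W2 is None:
        W2 = prior_variance(trait2)
    l1 = wakefield_labf(t1["beta"].to_numpy(), t1["se"].to_numpy(), W1)
    l2 = wakefield_labf(t2["beta"].to_numpy(), t2["se"].to_numpy(), W2)
    pph = _posteriors_from_labf(l1, l2, p1, p2, p12)
    lead = str(t1["id"].iloc[int(np.argmax(l1 + l2))])
    return ColocResult(gene_id, len(shared), pph, (p1, p2, p12), lead)


def _posteriors_from_labf(l1, l2, p1, p2, p12) -> np.ndarray:
    lS1 = logsumexp(l1)
    lS2 = logsumexp(l2)
    lS12 = logsumexp(l1 + l2)
    lL = np.empty(5)
    lL[0] = 0.0
    lL[1] = np.log(p1) + lS1
    lL[2] = np.log(p2) + lS2
    # S1*S2 - S12 >= 0 (cross terms only); guard cancellation at 1 variant
    gap = lS12 - (lS1 + lS2)
    if gap >= 0:
        if gap > 1e-9:
            log.warning("coloc: negative H3 mass clipped to 0")
        lL[3] = -np.inf
    else:
        lL[3] = np.log(p1) + np.log(p2) + lS1 + lS2 + np.log1p(-np.exp(gap))
    lL[4] = np.log(p12) + lS12
    pph = np.exp(lL - logsumexp(lL))
    return pph / pph.sum()


def select_regions(
    eqtls: pd.DataFrame,
    gwas: SummaryStats,
    contrast: pd.DataFrame,
    windows: dict,
    eqtl_fdr: float = 0.10,
    gwas_p: float = 5e-8,
    af_bin: str = ">10%",
) -> list:
    """Population-stratified colocalization screen.

    A gene's region qualifies iff its cis window contains a significant
    eQTL (q below threshold), a genome-wide-significant GWAS variant, and at
    least one variant in the requested allele-frequency-difference bin.
    Returns the qualifying gene IDs.
    """
    gt = gwas.table
    ct = contrast
    selected = []
    for gene, win in windows.items():
        ge = eqtls[(eqtls["gene_id"] == gene) & (eqtls["q"] < eqtl_fdr)]
        if ge.empty:
            continue
        in_win_gwas = (gt["chrom"].astype(str) == win.chrom) & \
            (gt["pos"].astype(int) >= win.start) & (gt["pos"].astype(int) <= win.end)
        if not (gt.loc[in_win_gwas, "p"] < gwas_p).any():
            continue
        in_win_af = (ct["chrom"].astype(str) == win.chrom) & \
            (ct["pos"].astype(int) >= win.start) & (ct["pos"].astype(int) <= win.end)
        if not (ct.loc[in_win_af, "bin"] == af_bin).any():
            continue
        selected.append(gene)
    return selected
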