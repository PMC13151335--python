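"""Allele-frequency contrasts, Weir-Cockerham F_ST, permutation enrichment."""

import numpy as np
import pandas as pd
import pytest

from stratgen.datamodel import GenotypeMatrix
from stratgen.popdiff import (
    af_contrast,
    equalize_sample_sizes,
    fst_enrichment,
    wc_components,
    wc_fst,
)
from stratgen.synthetic import AncestralModel, simulate_genotypes
from conftest import make_genotypes


def _pop_from_counts(n_hom_ref, n_het, n_hom_alt, vid="v1", pos=100):
    dos = np.array([0.0] * n_hom_ref + [1.0] * n_het + [2.0] * n_hom_alt)
    variants = pd.DataFrame({"id": [vid], "chrom": "1", "pos": [pos],
                             "effect_allele": ["A"], "other_allele": ["G"]})
    return GenotypeMatrix([f"I{i}" for i in range(len(dos))], variants,
                          dos[:, None])


def wc_oracle(counts1, counts2):
    """Independent transcription of the two-population component formulas.

    Written scalar-by-scalar from the published definitions (sample sizes,
    allele frequencies, observed heterozygosity), deliberately not sharing
    code with the package implementation.
    """
    import math
    (aa1, ab1, bb1), (aa2, ab2, bb2) = counts1, counts2
    n1, n2 = aa1 + ab1 + bb1, aa2 + ab2 + bb2
    p1 = (2 * bb1 + ab1) / (2 * n1)
    p2 = (2 * bb2 + ab2) / (2 * n2)
    h1, h2 = ab1 / n1, ab2 / n2
    r = 2
    nbar = (n1 + n2) / 2
    CV2 = ((n1 - nbar) ** 2 + (n2 - nbar) ** 2) / (2 * nbar ** 2)
    nc = nbar * (1 - CV2 * r / (r * (r - 1) if r > 1 else 1))
    # canonical form: nc = (r*nbar - sum(ni^2)/(r*nbar)) / (r-1)
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestAfContrast:
    def test_bins_cover_reported_example(self):
        # AF 0.614 vs 0.224: |diff| = 0.390 -> ">10%" bin
        n = 500
        rng = np.random.default_rng(90)
        g1 = _pop_from_counts(0, 0, 0)
        # build from frequencies instead
        d1 = rng.binomial(2, 0.614, size=n).astype(float)
        d2 = rng.binomial(2, 0.224, size=n).astype(float)
        variants = pd.DataFrame({"id": ["rs2148489"], "chrom": "10",
                                 "pos": [100], "effect_allele": ["A"],
                                 "other_allele": ["G"]})
        g1 = GenotypeMatrix([f"M{i}" for i in range(n)], variants, d1[:, None])
        g2 = GenotypeMatrix([f"F{i}" for i in range(n)], variants, d2[:, None])
        out = af_contrast(g1, g2)
        assert out["bin"][0] == ">10%"
        assert out["diff"][0] == pytest.approx(0.39, abs=0.05)

    @pytest.mark.parametrize("af1,af2,expected", [
        (0.50, 0.43, "5-10%"),
        (0.30, 0.29, "<5%"),
        (0.50, 0.45, "5-10%"),   # boundary 0.05 belongs to the middle bin
        (0.50, 0.40, "5-10%"),   # boundary 0.10 belongs to the middle bin
        (0.50, 0.395, ">10%"),
    ])
    def test_bin_boundaries(self, af1, af2, expected):
        variants = pd.DataFrame({"id": ["v"], "chrom": "1", "pos": [1],
                                 "effect_allele": ["A"], "other_allele": ["G"]})
        # encode the frequencies exactly with 1000 allele copies
        def exact(af):
            n = 500
            n_alt = int(round(af * 2 * n))
            dos = np.zeros(n)
            dos[: n_alt // 2] = 2
            if n_alt % 2:
                dos[n_alt // 2] = 1
            return GenotypeMatrix([f"I{i}" for i in range(n)], variants,
                                  dos[:, None])
        out = af_contrast(exact(af1), exact(af2))
        assert out["bin"][0] == expected

    def test_unharmonized_effect_alleles_raise(self):
        variants1 = pd.DataFrame({"id": ["v"], "chrom": "1", "pos": [1],
                                  "effect_allele": ["A"], "other_allele": ["G"]})
        variants2 = variants1.assign(effect_allele="G", other_allele="A")
        g1 = GenotypeMatrix(["a"], variants1, np.array([[1.0]]))
        g2 = GenotypeMatrix(["b"], variants2, np.array([[1.0]]))
        with pytest.raises(ValueError, match="unharmonized"):
            af_contrast(g1, g2)


class TestWcFst:
    def test_identical_distributions_give_near_zero(self, two_pops):
        g1, _ = two_pops
        half = g1.n_individuals // 2
        a = g1.select_individuals(np.arange(half))
        b = g1.select_individuals(np.arange(half, g1.n_individuals))
        assert abs(wc_fst(a, b).theta) < 0.02

    def test_toy_counts_match_independent_oracle(self):
        """pop1 30/40/30, pop2 60/30/10 (n=100 each) to 1e-12."""
        g1 = _pop_from_counts(30, 40, 30)
        g2 = _pop_from_counts(60, 30, 10)
        res = wc_fst(g1, g2)
        a, b, c = wc_oracle((30, 40, 30), (60, 30, 10))
        assert res.per_locus["a"][0] == pytest.approx(a, abs=1e-12)
        assert res.per_locus["b"][0] == pytest.approx(b, abs=1e-12)
        assert res.per_locus["c"][0] == pytest.approx(c, abs=1e-12)
        assert res.theta == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_oracle_agreement_random_counts(self):
        rng = np.random.default_rng(91)
        for _ in range(10):
            c1 = rng.multinomial(80, [0.3, 0.45, 0.25])
            c2 = rng.multinomial(120, [0.5, 0.35, 0.15])
            g1 = _pop_from_counts(*c1)
            g2 = _pop_from_counts(*c2)
            a, b, c = wc_oracle(tuple(c1), tuple(c2))
            res = wc_fst(g1, g2)
            assert res.theta == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_recovers_balding_nichols_f(self):
        model = AncestralModel.draw(5_000, F=0.1, seed=92)
        g, _ = simulate_genotypes((500, 500), model, seed=93)
        lab = np.asarray(g.population_label)
        res = wc_fst(g.select_individuals(lab == "pop1"),
                     g.select_individuals(lab == "pop2"))
        assert 0.08 <= res.theta <= 0.12

    def test_invariant_to_allele_labeling_and_pop_order(self):
        g1 = _pop_from_counts(30, 40, 30)
        g2 = _pop_from_counts(60, 30, 10)
        base = wc_fst(g1, g2).theta
        # swap which allele is "effect" in population 2's records
        g2_swap = _pop_from_counts(10, 30, 60)
        g2_swap.variants = g2_swap.variants.assign(effect_allele="G",
                                                   other_allele="A")
        assert wc_fst(g1, g2_swap).theta == pytest.approx(base, abs=1e-12)
        assert wc_fst(g2, g1).theta == pytest.approx(base, abs=1e-12)

    def test_multilocus_is_ratio_of_sums_not_mean(self, two_pops):
        g1, g2 = two_pops
        res = wc_fst(g1, g2)
        naive = res.theta_mean_of_ratios
        inc = res.per_locus[res.per_locus["included"]]
        ratio_of_sums = inc["a"].sum() / (inc["a"] + inc["b"] + inc["c"]).sum()
        assert res.theta == pytest.approx(ratio_of_sums, abs=1e-12)
        assert res.theta != pytest.approx(naive, abs=1e-6)

    def test_monomorphic_locus_excluded(self):
        variants = pd.DataFrame({"id": ["v1", "v2"], "chrom": "1",
                                 "pos": [1, 2], "effect_allele": ["A", "A"],
                                 "other_allele": ["G", "G"]})
        d1 = np.column_stack([np.zeros(10), np.array([0., 1] * 5)])
        d2 = np.column_stack([np.zeros(10), np.array([1., 2] * 5)])
        g1 = GenotypeMatrix([f"a{i}" for i in range(10)], variants, d1)
        g2 = GenotypeMatrix([f"b{i}" for i in range(10)], variants, d2)
        res = wc_fst(g1, g2)
        assert not res.per_locus.set_index("id").at["v1", "included"]
        assert res.per_locus.set_index("id").at["v1", "a"] == 0.0

    def test_empty_population_raises(self, two_pops):
        g1, g2 = two_pops
        empty = g1.select_individuals(np.array([], dtype=int))
        with pytest.raises(ValueError, match="non-empty"):
            wc_fst(empty, g2)


class TestFstEnrichment:
    def test_rank_formula_lower_bound(self, two_pops):
        g1, g2 = two_pops
        ids = g1.variants["id"].tolist()
        res = fst_enrichment(ids[:20], ids[:200], g1, g2, n_perm=100, seed=1)
        assert res["p_perm"] >= 1 / 101

    def test_calibration_under_random_sets(self, two_pops):
        """Random observed sets give approximately uniform permutation p."""
        from scipy.stats import kstest
        g1, g2 = two_pops
        ids = g1.variants["id"].tolist()[:400]
        rng = np.random.default_rng(94)
        ps = []
        for _ in range(60):
            obs = list(rng.choice(ids, 25, replace=False))
            res = fst_enrichment(obs, ids, g1, g2, n_perm=200,
                                 seed=int(rng.integers(2 ** 31)))
            ps.append(res["p_perm"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_planted_high_f_set_detected(self):
        model_bg = AncestralModel.draw(900, F=0.05, seed=95)
        model_hi = AncestralModel.draw(100, F=0.3, seed=96)
        model = AncestralModel(1000, np.concatenate([model_bg.pi, model_hi.pi]),
                               0.05,
                               np.hstack([model_bg.pop_freqs, model_hi.pop_freqs]))
        g, _ = simulate_genotypes((200, 200), model, seed=97)
        lab = np.asarray(g.population_label)
        g1 = g.select_individuals(lab == "pop1")
        g2 = g.select_individuals(lab == "pop2")
        ids = g1.variants["id"].tolist()
        planted = ids[900:950]
        res = fst_enrichment(planted, ids, g1, g2, n_perm=500, seed=98)
        assert res["p_perm"] < 0.01

    def test_background_too_small_raises(self, two_pops):
        g1, g2 = two_pops
        ids = g1.variants["id"].tolist()
        with pytest.raises(ValueError, match="background"):
            fst_enrichment(ids[:10], ids[:5], g1, g2, n_perm=100)


def test_equalize_sample_sizes_deterministic(two_pops):
    g1, g2 = two_pops
    bigger = g1.select_individuals(np.arange(150))
    smaller = g2.select_individuals(np.arange(100))
    a1, b1 = equalize_sample_sizes(bigger, smaller, seed=5)
    a2, b2 = equalize_sample_sizes(bigger, smaller, seed=5)
    assert a1.individuals == a2.individuals
    assert a1.n_individuals == 100
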