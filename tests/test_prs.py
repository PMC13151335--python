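"""Clumping, partitioned PRS, competitive permutation, interaction tests."""

import numpy as np
import pandas as pd
import pytest

from stratgen.datamodel import CisWindow, GenotypeMatrix, SummaryStats
from stratgen.prs import (
    ClumpResult,
    adjust_tc,
    assign_set_variants,
    clump,
    competitive_p,
    gxsex_scan,
    prs_scores,
    prs_sex_interaction,
    score_and_fit,
)
from conftest import make_genotypes


def _gwas_for(g: GenotypeMatrix, betas=None, ps=None, n=1000):
    m = g.n_variants
    betas = np.asarray(betas if betas is not None else np.full(m, 0.1))
    ps = np.asarray(ps if ps is not None else np.full(m, 0.5))
    t = g.variants.copy()
    t["eaf"] = g.eaf()
    t["beta"] = betas
    t["se"] = 0.05
    t["p"] = ps
    t["n"] = n
    return SummaryStats(t)


class TestClump:
    def test_single_variant_retained(self):
        g = make_genotypes(n=30, m=1, seed=100)
        res = clump(_gwas_for(g), g)
        assert res.index_variants == ["rs0"]

    def test_correlated_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(101)
        base = rng.binomial(2, 0.4, size=500).astype(float)
        noisy = base.copy()
        flip = rng.random(500) < 0.15
        noisy[flip] = rng.binomial(2, 0.4, size=flip.sum())
        variants = pd.DataFrame({
            "id": ["lead", "tag"], "chrom": "1", "pos": [100_000, 110_000],
            "effect_allele": "A", "other_allele": "G"})
        g = GenotypeMatrix([f"I{i}" for i in range(500)], variants,
                           np.column_stack([base, noisy]))
        assert np.corrcoef(base, noisy)[0, 1] ** 2 > 0.1
        res = clump(_gwas_for(g, ps=[1e-9, 1e-5]), g, r2_threshold=0.1)
        assert res.index_variants == ["lead"]
        assert res.assignment["tag"] == "lead"

    def test_independent_variants_all_retained(self):
        g = make_genotypes(n=400, m=10, seed=102)
        res = clump(_gwas_for(g, ps=np.linspace(1e-8, 1e-2, 10)), g)
        assert len(res.index_variants) == 10

    def test_far_apart_correlated_variants_both_kept(self):
        # identical dosages but 10 Mb apart: outside the clumping window
        base = np.tile([0.0, 1, 2, 1, 0], 20)
        variants = pd.DataFrame({
            "id": ["a", "b"], "chrom": "1", "pos": [1_000, 10_001_000],
            "effect_allele": "A", "other_allele": "G"})
        g = GenotypeMatrix([f"I{i}" for i in range(100)], variants,
                           np.column_stack([base, base]))
        res = clump(_gwas_for(g, ps=[1e-9, 1e-5]), g, window_kb=250)
        assert set(res.index_variants) == {"a", "b"}

    def test_p_ceiling_excludes(self):
        g = make_genotypes(n=50, m=3, seed=103)
        res = clump(_gwas_for(g, ps=[1e-8, 0.2, 0.9]), g, p_ceiling=0.5)
        assert "rs2" not in res.index_variants


class TestAssignSetVariants:
    def _setup(self):
        variants = pd.DataFrame({
            "id": ["inside", "at_100kb", "at_600kb"],
            "chrom": "1",
            "pos": [1_000_500, 1_120_000, 1_620_000],
            "effect_allele": "A", "other_allele": "G"})
        g = GenotypeMatrix(["i1"], variants, np.zeros((1, 3)))
        # gene body 1,000,000-1,020,000 with 500 kb flank -> [500000, 1520000]
        windows = {"G1": CisWindow.from_gene("G1", "1", 1_000_000, 1_020_000)}
        clumped = ClumpResult(["inside", "at_100kb", "at_600kb"], {}, 0.1, 250, 1.0)
        return clumped, windows, g

    def test_window_membership(self):
        clumped, windows, g = self._setup()
        out = assign_set_variants(clumped, windows, g)
        assert out == ["inside", "at_100kb"]

    def test_union_counts_once(self):
        clumped, windows, g = self._setup()
        windows["G2"] = CisWindow.from_gene("G2", "1", 1_010_000, 1_030_000)
        out = assign_set_variants(clumped, windows, g)
        assert out.count("inside") == 1


class TestScoreAndFit:
    def test_scores_are_linear_in_weights(self):
        g = make_genotypes(n=3, m=1, seed=104)
        g.dosages[:, 0] = [0, 1, 2]
        s = prs_scores(["rs0"], _gwas_for(g, betas=[0.2]), g)
        np.testing.assert_allclose(s.to_numpy(), [0.0, 0.2, 0.4])

    def test_score_additive_over_variant_sets(self):
        g = make_genotypes(n=50, m=10, seed=105)
        gwas = _gwas_for(g, betas=np.linspace(-0.3, 0.3, 10))
        ids = g.variants["id"].tolist()
        s_all = prs_scores(ids, gwas, g)
        s_a = prs_scores(ids[:4], gwas, g)
        s_b = prs_scores(ids[4:], gwas, g)
        np.testing.assert_allclose(s_all, s_a + s_b, atol=1e-12)

    def test_weights_flip_with_opposite_effect_allele(self):
        g = make_genotypes(n=30, m=1, seed=106)
        gwas = _gwas_for(g, betas=[0.2])
        gwas.table.loc[0, ["effect_allele", "other_allele"]] = ["G", "A"]
        s = prs_scores(["rs0"], gwas, g)
        s_direct = -0.2 * g.dosages[:, 0]
        np.testing.assert_allclose(s.to_numpy(), s_direct, atol=1e-12)

    def test_null_outcome_gives_near_zero_r2(self):
        rng = np.random.default_rng(107)
        r2s = []
        for seed in range(20):
            g = make_genotypes(n=200, m=10, seed=200 + seed)
            gwas = _gwas_for(g)
            fit = score_and_fit(g.variants["id"].tolist(), gwas, g,
                                rng.normal(size=200))
            r2s.append(fit.r2)
        assert np.mean(r2s) < 2 / 200 * 2

    def test_matches_nested_ols_oracle(self):
        """Incremental R2 equals explicit residual-sum-of-squares difference."""
        rng = np.random.default_rng(108)
        n = 50
        g = make_genotypes(n=n, m=5, seed=109)
        gwas = _gwas_for(g, betas=rng.normal(size=5))
        cov = pd.DataFrame({"age": rng.uniform(20, 70, n),
                            "bmi": rng.normal(30, 5, n)})
        y = rng.normal(size=n)
        fit = score_and_fit(g.variants["id"].tolist(), gwas, g, y, cov)
        import statsmodels.api as sm
        X0 = sm.add_constant(cov.to_numpy())
        X1 = np.column_stack([X0, fit.scores.to_numpy()])
        r2_0 = sm.OLS(y, X0).fit().rsquared
        r2_1 = sm.OLS(y, X1).fit().rsquared
        assert fit.r2 == pytest.approx(r2_1 - r2_0, abs=1e-10)

    def test_zero_variance_score_r2_zero(self):
        g = make_genotypes(n=30, m=2, seed=110)
        gwas = _gwas_for(g, betas=[0.0, 0.0])
        fit = score_and_fit(["rs0", "rs1"], gwas, g,
                            np.random.default_rng(1).normal(size=30))
        assert fit.r2 == 0.0


class TestCompetitiveP:
    def test_rank_formula_lower_bound(self):
        g = make_genotypes(n=150, m=60, seed=111)
        rng = np.random.default_rng(112)
        ids = g.variants["id"].tolist()
        betas = rng.normal(0, 0.2, 60)
        gwas = _gwas_for(g, betas=betas)
        y = prs_scores(ids[:10], gwas, g).to_numpy()  # perfectly explained
        y = y + 0.01 * rng.normal(size=150)
        fit = score_and_fit(ids[:10], gwas, g, y)
        out = competitive_p(fit, ids, gwas, g, y, n_perm=200, seed=113)
        assert out.p_comp == pytest.approx(1 / 201, abs=1e-12)

    def test_monotone_in_observed_r2(self):
        g = make_genotypes(n=100, m=40, seed=114)
        gwas = _gwas_for(g, betas=np.random.default_rng(115).normal(0, 0.2, 40))
        ids = g.variants["id"].tolist()
        y = np.random.default_rng(116).normal(size=100)
        fit = score_and_fit(ids[:8], gwas, g, y)
        weak = competitive_p(fit, ids, gwas, g, y, n_perm=100, seed=1)
        strong_fit = type(fit)(fit.scores, fit.r2 * 10 + 0.5, fit.p,
                               fit.stratum, variant_ids=fit.variant_ids)
        strong = competitive_p(strong_fit, ids, gwas, g, y, n_perm=100, seed=1)
        assert strong.p_comp <= weak.p_comp

    def test_calibrated_under_null_sets(self):
        """Random observed sets: empirical type-I at 0.05 in [0.03, 0.07]."""
        g = make_genotypes(n=250, m=80, seed=117)
        rng = np.random.default_rng(118)
        gwas = _gwas_for(g, betas=rng.normal(0, 0.2, 80))
        ids = g.variants["id"].tolist()
        y = rng.normal(size=250)
        rejections = 0
        n_rep = 100
        for rep in range(n_rep):
            obs = list(rng.choice(ids, 12, replace=False))
            fit = score_and_fit(obs, gwas, g, y)
            out = competitive_p(fit, ids, gwas, g, y, n_perm=100,
                                seed=int(rng.integers(2 ** 31)))
            rejections += out.p_comp <= 0.05
        assert 0.01 <= rejections / n_rep <= 0.10

    def test_background_too_small_raises(self):
        g = make_genotypes(n=30, m=5, seed=119)
        gwas = _gwas_for(g)
        fit = score_and_fit(g.variants["id"].tolist(), gwas, g,
                            np.random.default_rng(2).normal(size=30))
        with pytest.raises(ValueError, match="background"):
            competitive_p(fit, ["rs0"], gwas, g, np.zeros(30), n_perm=100)


class TestAdjustTc:
    def test_medicated_rescaled(self):
        assert adjust_tc(160, True) == pytest.approx(200.0)

    def test_unmedicated_unchanged(self):
        assert adjust_tc(160, False) == 160

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            adjust_tc(0, True)


class TestGxSexScan:
    def _inputs(self, n=2000, seed=120, beta_male=0.25):
        rng = np.random.default_rng(seed)
        g = make_genotypes(n=n, m=6, seed=seed + 1, maf_range=(0.3, 0.3))
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        g.sex = sex
        male = (sex == "male").astype(float)
        y = beta_male * g.dosages[:, 0] * male + rng.normal(size=n)
        gwas_m = _gwas_for(g, ps=[1e-9, 0.5, 0.5, 1e-9, 0.5, 0.5])
        gwas_f = _gwas_for(g, ps=[0.5, 0.5, 0.5, 1e-9, 0.5, 0.5])
        return g, y, sex, gwas_m, gwas_f

    def test_candidate_selection_rule(self):
        g, y, sex, gwas_m, gwas_f = self._inputs()
        out = gxsex_scan(gwas_m, gwas_f, g, y, sex)
        # rs0 is GWS in males only -> candidate; rs3 GWS in both -> excluded
        assert "rs0" in set(out["variant_id"])
        assert "rs3" not in set(out["variant_id"])

    def test_detects_planted_male_only_effect(self):
        """beta_male=0.25, MAF 0.3, n=2000: interaction q < 0.1 in most seeds."""
        hits = 0
        for seed in range(5):
            g, y, sex, gwas_m, gwas_f = self._inputs(seed=300 + seed)
            out = gxsex_scan(gwas_m, gwas_f, g, y, sex)
            row = out[out["variant_id"] == "rs0"]
            hits += bool(len(row) and row["q"].iloc[0] < 0.1)
        assert hits >= 4

    def test_window_restriction(self):
        g, y, sex, gwas_m, gwas_f = self._inputs()
        far = {"G": CisWindow("G", "9", 1, 10)}
        out = gxsex_scan(gwas_m, gwas_f, g, y, sex, set_windows=far)
        assert len(out) == 0


class TestPrsSexInteraction:
    def test_recovers_positive_male_amplification(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            n = 1000
            g = make_genotypes(n=n, m=20, seed=500 + seed)
            gwas = _gwas_for(g, betas=rng.normal(0.1, 0.05, 20))
            s = prs_scores(g.variants["id"].tolist(), gwas, g)
            sex = np.where(rng.random(n) < 0.5, "male", "female")
            male = (sex == "male").astype(float)
            y = s * (0.5 + 0.5 * male) + rng.normal(size=n)
            res = prs_sex_interaction(s, y, sex)
            hits += res["beta_interaction"] > 0
        assert hits >= 9

    def test_null_interaction_centred_on_zero(self):
        rng = np.random.default_rng(121)
        betas, ps = [], []
        for seed in range(20):
            n = 300
            g = make_genotypes(n=n, m=10, seed=600 + seed)
            gwas = _gwas_for(g)
            s = prs_scores(g.variants["id"].tolist(), gwas, g)
            sex = np.where(rng.random(n) < 0.5, "male", "female")
            y = s.to_numpy() + rng.normal(size=n)
            res = prs_sex_interaction(s, y, sex)
            betas.append(res["beta_interaction"])
            ps.append(res["p"])
        sem = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas)) < 3 * sem
        assert (np.asarray(ps) < 0.05).mean() <= 0.15

    def test_matches_interaction_ols_oracle(self):
        rng = np.random.default_rng(122)
        n = 60
        s = pd.Series(rng.normal(size=n))
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        y = rng.normal(size=n)
        cov = pd.DataFrame({"age": rng.uniform(20, 70, n)})
        res = prs_sex_interaction(s, y, sex, cov)
        import statsmodels.api as sm
        male = (sex == "male").astype(float)
        X = sm.add_constant(np.column_stack(
            [cov.to_numpy(), s.to_numpy(), male, s.to_numpy() * male]))
        fit = sm.OLS(y, X).fit()
        assert res["beta_interaction"] == pytest.approx(fit.params[-1], abs=1e-10)
        assert res["p"] == pytest.approx(fit.pvalues[-1], abs=1e-10)

    def test_single_sex_cohort_raises(self):
        s = pd.Series(np.arange(10.0))
        with pytest.raises(ValueError, match="both sexes"):
            prs_sex_interaction(s, np.zeros(10), np.array(["male"] * 10))
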