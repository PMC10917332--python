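import math

import numpy as np
import pytest
from scipy import stats

from pfda_audit.diagnostics import (
    conover_squared_ranks,
    fit_candidates,
    hopkins,
    joint_normality_probability,
    kde_and_qq,
    variance_tests,
)

SINGLE_FAMILIES = ("normal", "uniform", "weibull3", "logistic")


class TestFitCandidates:
    def test_logliks_match_independent_closed_forms(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 2.0, 59)
        fc = fit_candidates(x, families=("normal", "uniform"), pooled_sigma=None)
        df = fc.table().set_index("family")
        # independent closed forms
        mu, sd = x.mean(), x.std(ddof=0)
        ll_norm = np.sum(stats.norm.logpdf(x, mu, sd))
        ll_unif = -59 * math.log(x.max() - x.min())
        assert df.loc["normal", "loglik"] == pytest.approx(ll_norm)
        assert df.loc["uniform", "loglik"] == pytest.approx(ll_unif)
        # AICc formula: -2ll + 2k + 2k(k+1)/(n-k-1), here k=2, n=59
        assert df.loc["normal", "AICc"] == pytest.approx(
            -2 * ll_norm + 4 + 12 / 56
        )

    def test_uniform_sample_selects_uniform(self):
        rng = np.random.default_rng(1)
        wins = sum(
            fit_candidates(rng.uniform(0, 1, 59), families=SINGLE_FAMILIES).best_family()
            == "uniform"
            for _ in range(20)
        )
        assert wins >= 18

    def test_normal_sample_gets_strong_support(self):
        # with same-k competitors (logistic) the normal is not always the
        # single best family, but it carries strong support (dAICc < 2)
        rng = np.random.default_rng(2)
        strong = 0
        for _ in range(20)        :
            df = fit_candidates(rng.normal(0, 1, 59), families=SINGLE_FAMILIES).table()
            strong += float(df.loc[df.family == "normal", "dAICc"].iloc[0]) < 2.0
        assert strong >= 18

    def test_adding_worse_candidate_keeps_best(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 80)
        best_small = fit_candidates(x, families=("uniform", "normal")).best_family()
        best_big = fit_candidates(
            x, families=("uniform", "normal", "logistic", "weibull3")
        ).best_family()
        assert best_small == best_big == "uniform"

    def test_weights_normalize_and_min_daicc_zero(self):
        rng = np.random.default_rng(4)
        df = fit_candidates(rng.normal(0, 1, 40)).table()
        ok = df[df.converged]
        assert ok.dAICc.min() == 0.0
        assert ok.P_dist.sum() == pytest.approx(1.0)
        assert np.allclose(ok.W, np.exp(-ok.dAICc / 2))

    def test_pooled_sigma_family_and_joint_probability(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        fa = fit_candidates(a, families=("pooled_normal",), pooled_sigma=pooled)
        fb = fit_candidates(b, families=("pooled_normal",), pooled_sigma=pooled)
        # single candidate: P_dist = 1 for both, product = 1
        assert joint_normality_probability(fa, fb) == pytest.approx(1.0)
        fa2 = fit_candidates(a, pooled_sigma=pooled)
        fb2 = fit_candidates(b, pooled_sigma=pooled)
        prod = joint_normality_probability(fa2, fb2)
        assert prod == pytest.approx(
            fa2.p_dist("pooled_normal") * fb2.p_dist("pooled_normal")
        )

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_candidates(np.arange(10.0))


class TestVarianceTests:
    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(6)
        rej = {"brown_forsythe": 0, "levene": 0, "conover": 0}
        n_rep = 120
        for _ in range(n_rep):
            a, b = rng.normal(0, 1, 60), rng.normal(0, 1, 60)
            res = variance_tests(a, b)
            for k, (_, p) in res.items():
                rej[k] += p < 0.05
        for k, c in rej.items():
            assert 0.01 <= c / n_rep <= 0.10, k

    def test_power_against_doubled_scale(self):
        rng = np.random.default_rng(7)
        rej = 0
        for _ in range(50):
            a, b = rng.normal(0, 1, 60), rng.normal(0, 2, 60)
            rej += variance_tests(a, b)["brown_forsythe"][1] < 0.05
        assert rej / 50 >= 0.8

    def test_conover_z_matches_permutation_oracle(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 12), rng.normal(0, 1.8, 12)
        z, p = conover_squared_ranks(a, b)
        # permutation oracle on the squared-rank sum
        u = np.concatenate([np.abs(a - a.mean()), np.abs(b - b.mean())])
        r = stats.rankdata(u) ** 2
        obs = r[:12].sum()
        mu = r.mean() * 12
        devs = []
        for _ in range(20_000):
            perm = rng.permutation(r)
            devs.append(perm[:12].sum() - mu)
        p_perm = (np.sum(np.abs(devs) >= abs(obs - mu)) + 1) / 20_001
        assert p == pytest.approx(p_perm, abs=0.02)

    def test_degenerate_group_flagged(self):
        with pytest.raises(ValueError):
            variance_tests(np.ones(10), np.random.default_rng(0).normal(size=10))


class TestHopkins:
    def test_uniform_data_not_flagged(self):
        rng = np.random.default_rng(9)
        h = hopkins(rng.random((80, 2)), reps=20, mc_trials=200, seed=1)
        assert 0.35 < h.H < 0.65
        assert h.p_mc > 0.05

    def test_two_tight_blobs_detected(self):
        rng = np.random.default_rng(10)
        pts = np.vstack([rng.normal(0, 0.05, (30, 2)), rng.normal(4, 0.05, (30, 2))])
        h = hopkins(pts, reps=20, mc_trials=300, seed=2)
        assert h.p_mc < 0.01

    def test_representation_agnostic_on_whitened_points(self):
        # arbitrary affine representation flows through unchanged
        rng = np.random.default_rng(11)
        pts = rng.random((40, 2)) @ np.array([[2.0, 0.3], [0.1, 0.5]]) + [5, -3]
        h = hopkins(pts, reps=10, mc_trials=100, seed=3)
        assert 0.0 < h.H < 1.0

    def test_variants_and_duplicate_jitter(self):
        rng = np.random.default_rng(12)
        pts = np.repeat(rng.random((20, 2)), 2, axis=0)  # all duplicated
        for variant in ("original", "lj", "fpm"):
            h = hopkins(pts, variant=variant, reps=5, mc_trials=0, seed=4)
            assert np.isfinite(h.H)
        with pytest.raises(ValueError):
            hopkins(rng.random((10, 2)), mc_trials=0)


class TestKdeQq:
    def test_normal_vs_normal_near_identity(self):
        rng = np.random.default_rng(13)
        q = kde_and_qq(rng.normal(0, 1, 200), "normal")
        resid = q["qq_empirical"] - q["qq_theoretical"]
        assert np.max(np.abs(resid)) < 0.45
        assert np.corrcoef(q["qq_empirical"], q["qq_theoretical"])[0, 1] > 0.995

    def test_uniform_vs_normal_shows_s_shape(self):
        rng = np.random.default_rng(14)
        q = kde_and_qq(rng.uniform(-1, 1, 300), "normal")
        resid = q["qq_empirical"] - q["qq_theoretical"]
        # short tails: empirical above theoretical at the bottom, below at top
        assert resid[:10].mean() > 0
        assert resid[-10:].mean() < 0

    def test_constant_sample_degenerate(self):
        with pytest.raises(ValueError):
            kde_and_qq(np.ones(30), "normal")
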