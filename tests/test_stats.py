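"""Rank tests and JZS Bayes factors against independent oracles."""

import itertools
import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats as sps

from crttdyad.simulate import GenerativeParams, simulate_study
from crttdyad.stats import (
    DEFAULT_PRIOR_SCALE,
    DegenerateDataError,
    forced_break_contrast,
    jzs_linear_model_bf,
    jzs_regression_bf,
    jzs_ttest_bf,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


# --- independent enumeration oracles (written against the textbook
# definitions, not the implementation) ------------------------------------


def rank_sum_exact_p_oracle(x, y):
    """Two-sided permutation p for the rank-sum test by full enumeration."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1, n = len(x), len(pooled)
    offset = n1 * (n1 + 1) / 2.0
    observed = ranks[:n1].sum() - offset
    stats = np.array(
        [ranks[list(c)].sum() - offset for c in itertools.combinations(range(n), n1)]
    )
    lo = np.mean(stats <= observed + 1e-12)
    hi = np.mean(stats >= observed - 1e-12)
    return min(1.0, 2.0 * min(lo, hi))


def signed_rank_exact_p_oracle(x, mu, alternative="two-sided"):
    d = np.asarray(x, dtype=float) - mu
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    stats = np.array(
        [np.dot(signs, ranks) for signs in itertools.product((0, 1), repeat=len(d))]
    )
    if alternative == "greater":
        return np.mean(stats >= observed - 1e-12)
    if alternative == "less":
        return np.mean(stats <= observed + 1e-12)
    lo = np.mean(stats <= observed + 1e-12)
    hi = np.mean(stats >= observed - 1e-12)
    return min(1.0, 2.0 * min(lo, hi))


def jzs_t_bf_oracle(t, df, n_eff, r, grid=200_001):
    """Fine-grid trapezoid integration of the JZS t marginal-likelihood ratio."""
    u = np.linspace(-15.0, 15.0, grid)
    g = np.exp(u)
    shrink = 1.0 + n_eff * g
    log_lik = -0.5 * np.log(shrink) - (df + 1) / 2.0 * np.log1p(t * t / (shrink * df))
    log_prior = (
        0.5 * np.log(r**2 / 2.0) - special.gammaln(0.5) - 1.5 * np.log(g) - r**2 / (2 * g)
    )
    integrand = np.exp(log_lik + log_prior + u)  # Jacobian e^u
    integral = np.trapezoid(integrand, u)
    null = (1.0 + t * t / df) ** (-(df + 1) / 2.0)
    return integral / null


def jzs_regression_bf_oracle(r2, n, k, r, grid=200_001):
    u = np.linspace(-15.0, 15.0, grid)
    g = np.exp(u)
    log_ratio = (n - 1 - k) / 2.0 * np.log1p(g) - (n - 1) / 2.0 * np.log1p(g * (1 - r2))
    scale = n * r**2 / 2.0
    log_prior = 0.5 * np.log(scale) - special.gammaln(0.5) - 1.5 * np.log(g) - scale / g
    return np.trapezoid(np.exp(log_ratio + log_prior + u), u)


# --- rank-sum -------------------------------------------------------------


class TestRankSum:
    def test_separated_triples_exact_p(self):
        """{1,2,3} vs {4,5,6}: two-sided permutation p = 2/20 = 0.1."""
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.exact
        assert res.p_two_sided == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_null(self):
        res = wilcoxon_rank_sum([1, 2, 3, 4, 5] * 3, [1, 2, 3, 4, 5] * 3)
        assert res.p_two_sided > 0.95
        assert res.effect_size_r == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        x=st.lists(st.integers(1, 8), min_size=1, max_size=8),
        y=st.lists(st.integers(1, 8), min_size=1, max_size=8),
    )
    def test_exact_path_matches_enumeration_oracle(self, x, y):
        """For combined n <= 12, the p-value equals full enumeration of
        C(N, n1) assignments, ties included."""
        if len(x) + len(y) > 12:
            return
        if len(set(x) | set(y)) == 1:
            return  # all tied: degenerate
        res = wilcoxon_rank_sum(x, y)
        assert res.exact
        assert res.p_two_sided == pytest.approx(rank_sum_exact_p_oracle(x, y), abs=1e-12)

    def test_asymptotic_path_matches_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.integers(1, 9, 40).astype(float)
        y = rng.integers(1, 9, 55).astype(float)
        res = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
        assert not res.exact
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-12)

    def test_group_swap_flips_z_only(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.5, 1, 30)
        y = rng.normal(0.0, 1, 25)
        a = wilcoxon_rank_sum(x, y)
        b = wilcoxon_rank_sum(y, x)
        assert b.z == pytest.approx(-a.z, rel=1e-12)
        assert b.p_two_sided == pytest.approx(a.p_two_sided, rel=1e-12)
        assert b.effect_size_r == pytest.approx(a.effect_size_r, rel=1e-12)

    def test_effect_size_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.5, 1, 30)
        y = rng.normal(0.0, 1, 25)
        a = wilcoxon_rank_sum(x, y)
        b = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert b.effect_size_r == pytest.approx(a.effect_size_r, rel=1e-12)
        assert b.p_two_sided == pytest.approx(a.p_two_sided, rel=1e-12)

    def test_type_one_error_calibrated(self):
        """Simulated size at alpha = 0.05 under the null lies in [0.04, 0.06]
        over 10,000 replicates (n = 25 per group)."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 10_000
        for _ in range(n_rep):
            x = rng.standard_normal(25)
            y = rng.standard_normal(25)
            rejections += wilcoxon_rank_sum(x, y).p_two_sided < 0.05
        assert 0.04 <= rejections / n_rep <= 0.06

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


# --- signed-rank ----------------------------------------------------------


class TestSignedRank:
    def test_symmetric_sample_null(self):
        x = np.array([-3, -2, -1, 1, 2, 3]) + 5.0
        res = wilcoxon_signed_rank(x, mu=5.0)
        assert res.p_two_sided > 0.9

    def test_all_positive_one_sided_exact(self):
        """{2,3,4} against 1: every sign pattern below the observed one,
        one-sided exact p = 1/8."""
        res = wilcoxon_signed_rank([2, 3, 4], mu=1.0, alternative="greater")
        assert res.exact
        assert res.p_two_sided == pytest.approx(1.0 / 8.0, abs=1e-12)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        x=st.lists(st.integers(1, 8), min_size=1, max_size=10),
        mu=st.sampled_from([1.0, 2.5, 4.0]),
    )
    def test_exact_path_matches_sign_enumeration(self, x, mu):
        d = np.asarray(x, dtype=float) - mu
        if np.all(d == 0):
            return
        res = wilcoxon_signed_rank(x, mu=mu)
        assert res.exact
        assert res.p_two_sided == pytest.approx(signed_rank_exact_p_oracle(x, mu), abs=1e-12)

    def test_asymptotic_path_matches_scipy(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.3, 1.0, 60)
        res = wilcoxon_signed_rank(d, mu=0.0)
        ref = sps.wilcoxon(d, correction=True, alternative="two-sided", method="approx")
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-12)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([3.0, 3.0, 3.0], mu=3.0)


# --- Bayes factors --------------------------------------------------------


class TestJZSTTest:
    def test_null_t_favours_null(self):
        # symmetric sample: t exactly 0
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = jzs_ttest_bf(x, mu=3.0)
        assert res.bf10 < 1.0

    def test_two_sample_matches_fine_grid_oracle(self):
        """Fixed synthetic vectors: quadrature matches an independent
        trapezoid oracle to at least 4 significant figures."""
        rng = np.random.default_rng(7)
        x = rng.normal(0.8, 1, 10)
        y = rng.normal(0.0, 1, 10)
        res = jzs_ttest_bf(x, y)
        df = 18
        pooled = (9 * x.var(ddof=1) + 9 * y.var(ddof=1)) / df
        t = (x.mean() - y.mean()) / math.sqrt(pooled * (2 / 10))
        oracle = jzs_t_bf_oracle(t, df, 5.0, DEFAULT_PRIOR_SCALE)
        assert res.bf10 == pytest.approx(oracle, rel=1e-4)
        assert res.integration_error < 1e-6

    def test_one_sample_matches_fine_grid_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.5, 1, 15)
        res = jzs_ttest_bf(x)
        t = x.mean() / (x.std(ddof=1) / math.sqrt(15))
        oracle = jzs_t_bf_oracle(t, 14, 15.0, DEFAULT_PRIOR_SCALE)
        assert res.bf10 == pytest.approx(oracle, rel=1e-4)

    def test_reciprocal_identity(self):
        rng = np.random.default_rng(9)
        res = jzs_ttest_bf(rng.normal(0.4, 1, 12), rng.normal(0, 1, 14))
        assert res.bf10 * res.bf01 == pytest.approx(1.0, abs=1e-9)

    def test_invariant_under_common_affine_rescaling(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0.4, 1, 12)
        y = rng.normal(0.0, 1, 14)
        a = jzs_ttest_bf(x, y)
        b = jzs_ttest_bf(3.0 * x + 7.0, 3.0 * y + 7.0)
        assert b.bf10 == pytest.approx(a.bf10, rel=1e-9)

    def test_matches_pingouin_reference_implementation(self):
        """Independent cross-check against another JZS implementation."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        x = rng.normal(0.5, 1, 20)
        y = rng.normal(0.0, 1, 25)
        res = jzs_ttest_bf(x, y)
        df = 43
        pooled = (19 * x.var(ddof=1) + 24 * y.var(ddof=1)) / df
        t = (x.mean() - y.mean()) / math.sqrt(pooled * (1 / 20 + 1 / 25))
        ref = float(pg.bayesfactor_ttest(t, 20, 25, paired=False, r=DEFAULT_PRIOR_SCALE))
        assert res.bf10 == pytest.approx(ref, rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            jzs_ttest_bf([2.0, 2.0, 2.0], [5.0, 5.0, 5.0])


class TestJZSRegression:
    def test_small_design_matches_fine_grid_oracle(self):
        """n = 20 single-predictor design with known R^2."""
        rng = np.random.default_rng(12)
        x = rng.standard_normal(20)
        e = rng.standard_normal(20)
        y = 0.7 * x + e
        # R^2 computed independently from the correlation coefficient
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        res = jzs_linear_model_bf(r2, 20, 1)
        oracle = jzs_regression_bf_oracle(r2, 20, 1, DEFAULT_PRIOR_SCALE)
        assert res.bf10 == pytest.approx(oracle, rel=1e-4)

    def test_orthogonal_predictor_disfavoured(self):
        rng = np.random.default_rng(13)
        n = 400
        data = pd.DataFrame(
            {"y": rng.standard_normal(n), "x1": rng.standard_normal(n), "x2": rng.standard_normal(n)}
        )
        data["y"] = 0.6 * data["x1"] + rng.standard_normal(n)
        res = jzs_regression_bf(data, "y", ["x1", "x2"], ["x1"])
        assert res.bf10 < 1.0

    def test_informative_predictor_favoured(self):
        rng = np.random.default_rng(14)
        n = 200
        data = pd.DataFrame({"x1": rng.standard_normal(n)})
        data["y"] = 0.8 * data["x1"] + rng.standard_normal(n)
        res = jzs_regression_bf(data, "y", ["x1"], [])
        assert res.bf10 > 100.0

    def test_non_nested_models_rejected(self):
        data = pd.DataFrame({"y": [1.0, 2, 3, 4], "a": [1.0, 0, 1, 0], "b": [0.0, 1, 0, 1]})
        with pytest.raises(ValueError, match="nested"):
            jzs_regression_bf(data, "y", ["a"], ["b"])


# --- forced-break contrast ------------------------------------------------


class TestForcedBreakContrast:
    def test_no_effect_generative_null(self):
        """With the reduction switched off, neither stratum rejects more than
        chance plus clustering noise allows (measured over 30 seeds)."""
        null_params = replace(GenerativeParams(), forced_break_reduction=0.0)
        ww_rej = mp_rej = 0
        n_seeds = 30
        for seed in range(n_seeds):
            trials = simulate_study(40, 0, 40, params=null_params, seed=5000 + seed)
            rep = forced_break_contrast(trials)
            ww_rej += rep.ww_test.p_two_sided < 0.05
            mp_rej += rep.mplus_test.p_two_sided < 0.05
        assert ww_rej <= 8
        assert mp_rej <= 8

    def test_reduction_detected_only_in_man_containing_pairs(self, default_params):
        """Monte-Carlo power check at 100 dyads per stratum-condition cell,
        50 replicates: the M+ stratum is significant essentially always, the
        WW stratum stays near its null rate."""
        ww_rej = mp_rej = 0
        n_rep = 50
        for seed in range(n_rep):
            trials = simulate_study(200, 0, 200, params=default_params, seed=7000 + seed)
            rep = forced_break_contrast(trials)
            ww_rej += rep.ww_test.p_two_sided < 0.05
            mp_rej += rep.mplus_test.p_two_sided < 0.05
        assert mp_rej >= 47
        assert ww_rej <= 15

    def test_floor_tests_reject_floor(self, default_params):
        trials = simulate_study(60, 0, 60, params=default_params, seed=9001)
        rep = forced_break_contrast(trials)
        assert rep.ww_floor_immediate.p_two_sided < 1e-6
        assert rep.ww_floor_forced.p_two_sided < 1e-6

    def test_missing_cell_rejected(self, default_params):
        trials = simulate_study(10, 0, 10, params=default_params, seed=3, condition_mix=0.0)
        with pytest.raises(ValueError, match="missing cell"):
            forced_break_contrast(trials)

    def test_bootstrap_subtraction_tracks_observed_difference(self, default_params):
        trials = simulate_study(60, 0, 60, params=default_params, seed=15)
        rep = forced_break_contrast(trials, bootstrap=500, rng=np.random.default_rng(1))
        diffs = rep.bootstrap_differences["M+"]
        observed = rep.stratum_means["M+:immediate"] - rep.stratum_means["M+:forced_break"]
        assert diffs.shape == (500,)
        assert abs(float(diffs.mean()) - observed) < 0.25
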