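"""Nonparametric and Bayesian inference, implemented from first principles.

Blast data are bounded, discrete and skewed, so comparisons of location use
Wilcoxon rank tests (normal approximation with tie correction and a 0.5
continuity correction; exact enumeration whenever the combined sample size
is at most 12) with the bounded effect size r = |z| / sqrt(N).

Bayesian evidence uses the JZS (Jeffreys-Zellner-Siow) framework: a Jeffreys
prior on the variance and a Cauchy prior (default scale sqrt(2)/2) on the
standardised effect.  The t-test Bayes factor integrates the marginal
likelihood ratio over the Cauchy-mixing parameter g numerically; the
regression Bayes factor uses the corresponding mixture-of-g prior on
standardised coefficients, and a nested-model comparison reports the
with/without evidence ratio for a predictor block.

The forced-break contrast stratifies dyads into woman-woman (WW) versus
pairs containing at least one man (M+), tests immediate vs forced-break
blast levels within each stratum, tests the between-strata difference on
dyad-level contrasts, runs the WW floor checks against the minimum blast,
and can bootstrap a "simulated subtraction" distribution of condition
differences for visualisation.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

__all__ = [
    "RankTestResult",
    "BayesFactorResult",
    "ForcedBreakReport",
    "DegenerateDataError",
    "DEFAULT_PRIOR_SCALE",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "jzs_ttest_bf",
    "jzs_linear_model_bf",
    "jzs_regression_bf",
    "forced_break_contrast",
]

#: Default Cauchy scale on the standardised effect ("medium" evidence prior).
DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0

#: Largest combined sample size for which rank-test p-values are computed by
#: exhaustive enumeration instead of the normal approximation.
EXACT_LIMIT = 12


class DegenerateDataError(ValueError):
    """Data carry no information for the requested test (e.g. all ties)."""


@dataclass(frozen=True)
class RankTestResult:
    statistic: float  # rank-sum U or signed-rank W+
    z: float  # continuity- and tie-corrected normal deviate
    p_two_sided: float
    effect_size_r: float  # |z| / sqrt(N)
    n1: int
    n2: int  # 0 for one-sample tests
    exact: bool
    alternative: str = "two-sided"

    @property
    def p_value(self) -> float:
        return self.p_two_sided

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    prior_scale: float
    integration_error: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rank_with_ties(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    return ranks, counts


def _two_sided_from_cdf(stat: float, pmf_stats: np.ndarray, pmf_probs: np.ndarray) -> float:
    """Two-sided exact p by the doubling rule: 2 * min(P(T<=t), P(T>=t)), capped at 1."""
    lo = float(pmf_probs[pmf_stats <= stat + 1e-12].sum())
    hi = float(pmf_probs[pmf_stats >= stat - 1e-12].sum())
    return min(1.0, 2.0 * min(lo, hi))


def _one_sided_from_cdf(
    stat: float, pmf_stats: np.ndarray, pmf_probs: np.ndarray, alternative: str
) -> float:
    if alternative == "greater":
        return float(pmf_probs[pmf_stats >= stat - 1e-12].sum())
    return float(pmf_probs[pmf_stats <= stat + 1e-12].sum())


def wilcoxon_rank_sum(
    x,
    y,
    alternative: str = "two-sided",
    continuity: bool = True,
    exact_limit: int = EXACT_LIMIT,
) -> RankTestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    The z statistic uses the tie-corrected variance and a 0.5 continuity
    correction; p-values come from exhaustive enumeration of the C(N, n1)
    group assignments when N = n1 + n2 <= ``exact_limit``, otherwise from
    the normal approximation.  The effect size is r = |z| / sqrt(N), which
    is invariant under any strictly monotone transform of the pooled data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks, tie_counts = _rank_with_ties(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)  # Mann-Whitney U for x

    mu = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise DegenerateDataError("all pooled observations tied; rank-sum test undefined")
    diff = u - mu
    cc = 0.5 if continuity and diff != 0 else 0.0
    z = (diff - math.copysign(cc, diff)) / math.sqrt(var)

    if n <= exact_limit:
        u_stats, u_probs = _exact_rank_sum_distribution(pooled, n1)
        if alternative == "two-sided":
            p = _two_sided_from_cdf(u, u_stats, u_probs)
        else:
            p = _one_sided_from_cdf(u, u_stats, u_probs, alternative)
        exact = True
    else:
        if alternative == "two-sided":
            p = 2.0 * sps.norm.sf(abs(z))
        elif alternative == "greater":
            p = float(sps.norm.sf(z))
        else:
            p = float(sps.norm.cdf(z))
        p = min(1.0, float(p))
        exact = False

    return RankTestResult(
        statistic=u,
        z=float(z),
        p_two_sided=float(p) if alternative == "two-sided" else float(p),
        effect_size_r=min(1.0, abs(z) / math.sqrt(n)),
        n1=n1,
        n2=n2,
        exact=exact,
        alternative=alternative,
    )


def _exact_rank_sum_distribution(pooled: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of U for x over all C(N, n1) group assignments.

    Ties are handled exactly: mid-ranks are computed once for the pooled
    sample and U is evaluated for every subset of positions."""
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    offset = n1 * (n1 + 1) / 2.0
    stats_list = [ranks[list(idx)].sum() - offset for idx in itertools.combinations(range(n), n1)]
    values, counts = np.unique(np.round(stats_list, 10), return_counts=True)
    return values, counts / counts.sum()


def wilcoxon_signed_rank(
    x,
    mu: float = 0.0,
    alternative: str = "two-sided",
    continuity: bool = True,
    zero_method: str = "drop",
    exact_limit: int = EXACT_LIMIT,
) -> RankTestResult:
    """One-sample Wilcoxon signed-rank test of symmetry about ``mu``.

    Zero differences are dropped before ranking (the classical rule;
    ``zero_method="keep"`` retains them in the ranking with half their rank
    weight split between the tails).  Exact enumeration of the 2^n sign
    patterns is used for n <= ``exact_limit``.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("sample must be nonempty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = x - mu
    if zero_method == "drop":
        d = d[d != 0]
    elif zero_method != "keep":
        raise ValueError(f"unknown zero_method {zero_method!r}")
    if d.size == 0 or np.all(d == 0):
        raise DegenerateDataError("all differences are zero; signed-rank test undefined")
    n = d.size
    absd = np.abs(d)
    ranks = sps.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())

    mu_w = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float((tie_counts**3 - tie_counts).sum()) / 48.0
    if zero_method == "keep":
        nz = int((d == 0).sum())
        mu_w -= nz * (nz + 1) / 4.0  # zeros contribute no signed rank
    if var <= 0:
        raise DegenerateDataError("no variance in signed ranks")
    diff = w_plus - mu_w
    cc = 0.5 if continuity and diff != 0 else 0.0
    z = (diff - math.copysign(cc, diff)) / math.sqrt(var)

    if n <= exact_limit:
        w_stats, w_probs = _exact_signed_rank_distribution(ranks, d)
        if alternative == "two-sided":
            p = _two_sided_from_cdf(w_plus, w_stats, w_probs)
        else:
            p = _one_sided_from_cdf(w_plus, w_stats, w_probs, alternative)
        exact = True
    else:
        if alternative == "two-sided":
            p = 2.0 * sps.norm.sf(abs(z))
        elif alternative == "greater":
            p = float(sps.norm.sf(z))
        else:
            p = float(sps.norm.cdf(z))
        p = min(1.0, float(p))
        exact = False

    return RankTestResult(
        statistic=w_plus,
        z=float(z),
        p_two_sided=float(p),
        effect_size_r=min(1.0, abs(z) / math.sqrt(n)),
        n1=n,
        n2=0,
        exact=exact,
        alternative=alternative,
    )


def _exact_signed_rank_distribution(ranks: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of W+ over all 2^n sign patterns of the observed ranks."""
    nonzero_ranks = ranks[d != 0]
    n = len(nonzero_ranks)
    stats_list = []
    for signs in itertools.product((0, 1), repeat=n):
        stats_list.append(float(np.dot(signs, nonzero_ranks)))
    values, counts = np.unique(np.round(stats_list, 10), return_counts=True)
    return values, counts / counts.sum()


# ---------------------------------------------------------------------------
# JZS Bayes factors
# ---------------------------------------------------------------------------


def _log_invgamma_half(g: np.ndarray, scale: float) -> np.ndarray:
    """log density of InverseGamma(1/2, scale/2) at g (the Cauchy mixing law)."""
    return (
        0.5 * np.log(scale / 2.0)
        - special.gammaln(0.5)
        - 1.5 * np.log(g)
        - scale / (2.0 * g)
    )


def _log_jzs_t_integrand(g: np.ndarray, t: float, df: float, n_eff: float, r: float) -> np.ndarray:
    """log marginal likelihood of t under the alternative, per unit prior mass.

    g carries the Cauchy prior on the standardised effect as a scale mixture
    of normals: delta | g ~ N(0, g), g ~ InverseGamma(1/2, r^2/2).
    """
    g = np.asarray(g, dtype=float)
    shrink = 1.0 + n_eff * g
    log_lik = -0.5 * np.log(shrink) - (df + 1.0) / 2.0 * np.log1p(t * t / (shrink * df))
    return log_lik + _log_invgamma_half(g, r**2)


def _integrate_log_over_g(log_f, u_range: tuple[float, float] = (-40.0, 40.0)) -> tuple[float, float]:
    """Integrate exp(log_f(g)) dg over (0, inf) in log space.

    Substitutes g = e^u and shifts by the grid maximum of the transformed
    log-integrand so astronomically large or small evidence never overflows.
    Returns (log of the integral, relative quadrature error estimate).
    """
    u_grid = np.linspace(*u_range, 1201)
    log_h = log_f(np.exp(u_grid)) + u_grid  # Jacobian dg = e^u du
    shift = float(np.max(log_h))
    if not np.isfinite(shift):
        raise FloatingPointError("JZS integrand is degenerate on the search grid")
    value, abserr = integrate.quad(
        lambda u: math.exp(min(log_f(np.array([math.exp(u)]))[0] + u - shift, 700.0)),
        u_range[0], u_range[1], epsabs=0.0, epsrel=1e-10, limit=300,
    )
    return shift + math.log(value), abserr / value


def jzs_ttest_bf(
    x,
    y=None,
    mu: float = 0.0,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> BayesFactorResult:
    """JZS Bayes factor for a one- or two-sample comparison of means.

    ``y=None`` gives the one-sample test of the mean against ``mu``;
    otherwise the two-sample (pooled-variance) comparison.  BF10 > 1 favours
    a nonzero standardised effect under a Cauchy(0, ``prior_scale``) prior.
    """
    x = np.asarray(x, dtype=float)
    if y is None:
        n = x.size
        if n < 2:
            raise ValueError("need n >= 2 observations")
        sd = x.std(ddof=1)
        if sd == 0:
            raise DegenerateDataError("zero variance; t statistic undefined")
        t = (x.mean() - mu) / (sd / math.sqrt(n))
        df = n - 1.0
        n_eff = float(n)
    else:
        y = np.asarray(y, dtype=float)
        n1, n2 = x.size, y.size
        if n1 < 2 or n2 < 2:
            raise ValueError("need n >= 2 per group")
        df = n1 + n2 - 2.0
        pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
        if pooled_var == 0:
            raise DegenerateDataError("zero variance in both groups")
        t = (x.mean() - y.mean()) / math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
        n_eff = n1 * n2 / (n1 + n2)

    log_null = -(df + 1.0) / 2.0 * math.log1p(t * t / df)
    log_integral, rel_err = _integrate_log_over_g(
        lambda g: _log_jzs_t_integrand(g, float(t), df, n_eff, prior_scale)
    )
    return BayesFactorResult(
        bf10=float(math.exp(min(log_integral - log_null, 700.0))),
        prior_scale=prior_scale,
        integration_error=float(rel_err),
    )


def _log_jzs_regression_integrand(g: np.ndarray, n: int, k: int, r2: float, r: float) -> np.ndarray:
    """log Zellner-Siow marginal-likelihood ratio density over g.

    Model vs intercept-only: (1+g)^((n-1-k)/2) * (1 + g(1-R^2))^(-(n-1)/2),
    with g ~ InverseGamma(1/2, n r^2 / 2).
    """
    g = np.asarray(g, dtype=float)
    log_ratio = (n - 1.0 - k) / 2.0 * np.log1p(g) - (n - 1.0) / 2.0 * np.log1p(g * (1.0 - r2))
    return log_ratio + _log_invgamma_half(g, n * r**2)


def jzs_linear_model_bf(
    r_squared: float,
    n: int,
    n_predictors: int,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> BayesFactorResult:
    """Bayes factor of a k-predictor linear model against the intercept-only null."""
    if not (0.0 <= r_squared < 1.0):
        raise ValueError("r_squared must lie in [0, 1)")
    if n_predictors < 1 or n <= n_predictors + 1:
        raise ValueError("need n > k + 1 observations")
    log_integral, rel_err = _integrate_log_over_g(
        lambda g: _log_jzs_regression_integrand(
            g, int(n), int(n_predictors), float(r_squared), prior_scale
        )
    )
    return BayesFactorResult(
        bf10=float(math.exp(min(log_integral, 700.0))),
        prior_scale=prior_scale,
        integration_error=float(rel_err),
    )


def _ols_r2(data: pd.DataFrame, outcome: str, predictors: list[str]) -> float:
    y = data[outcome].to_numpy(dtype=float)
    y = y - y.mean()
    if not predictors:
        return 0.0
    X = data[list(predictors)].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(y @ y)
    if tss == 0:
        raise DegenerateDataError("outcome has zero variance")
    return 1.0 - float(resid @ resid) / tss


def jzs_regression_bf(
    data: pd.DataFrame,
    outcome: str,
    predictors_with: list[str],
    predictors_without: list[str],
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> BayesFactorResult:
    """Evidence for including a predictor block in a linear model.

    The two predictor sets must be nested; the result is the ratio of each
    model's JZS Bayes factor against the intercept-only null, i.e. the
    with/without evidence ratio.
    """
    w, wo = set(predictors_with), set(predictors_without)
    if not (wo < w):
        raise ValueError("models must be nested: predictors_without a strict subset of predictors_with")
    n = len(data)
    bf_with = jzs_linear_model_bf(
        _ols_r2(data, outcome, sorted(w)), n, len(w), prior_scale
    )
    if wo:
        bf_without = jzs_linear_model_bf(
            _ols_r2(data, outcome, sorted(wo)), n, len(wo), prior_scale
        )
        bf10 = bf_with.bf10 / bf_without.bf10
        err = bf10 * (
            bf_with.integration_error / bf_with.bf10
            + bf_without.integration_error / bf_without.bf10
        )
    else:
        bf10 = bf_with.bf10
        err = bf_with.integration_error
    return BayesFactorResult(bf10=float(bf10), prior_scale=prior_scale, integration_error=float(err))


# ---------------------------------------------------------------------------
# Forced-break contrast
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForcedBreakReport:
    """Stratified immediate vs forced-break comparison (WW vs M+)."""

    ww_test: RankTestResult
    mplus_test: RankTestResult
    between_test: RankTestResult
    ww_floor_immediate: RankTestResult
    ww_floor_forced: RankTestResult
    stratum_means: dict[str, float]
    bootstrap_differences: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "ww_test": self.ww_test.to_dict(),
            "mplus_test": self.mplus_test.to_dict(),
            "between_test": self.between_test.to_dict(),
            "ww_floor_immediate": self.ww_floor_immediate.to_dict(),
            "ww_floor_forced": self.ww_floor_forced.to_dict(),
            "stratum_means": dict(self.stratum_means),
        }
        if self.bootstrap_differences:
            out["bootstrap_differences"] = {
                k: {"mean": float(v.mean()), "sd": float(v.std(ddof=1)), "n": int(v.size)}
                for k, v in self.bootstrap_differences.items()
            }
        return out


def _stratum(trials: pd.DataFrame) -> pd.Series:
    genders = trials.groupby("dyad_id").apply(
        lambda d: "WW" if set(d["winner_gender"]) | set(d["loser_gender"]) == {"woman"} else "M+",
        include_groups=False,
    )
    return trials["dyad_id"].map(genders)


def forced_break_contrast(
    trials: pd.DataFrame,
    bootstrap: int = 0,
    rng: np.random.Generator | None = None,
) -> ForcedBreakReport:
    """Does a forced break lower aggression, and only in pairs with a man?

    Within each stratum (WW and M+) trial-level blasts are compared across
    conditions by rank-sum test.  The between-strata difference compares
    dyad-level mean blasts of forced-break dyads, centred on their stratum's
    immediate-condition mean, across strata.  WW floor tests check that
    blasts sit above the scale minimum in both conditions.  With
    ``bootstrap`` > 0, a per-stratum "simulated subtraction" distribution of
    condition differences in dyad means is resampled for visualisation.
    """
    trials = trials.copy()
    trials["stratum"] = _stratum(trials)
    for stratum in ("WW", "M+"):
        for condition in ("immediate", "forced_break"):
            cell = trials[(trials["stratum"] == stratum) & (trials["condition"] == condition)]
            if len(cell) == 0:
                raise ValueError(f"missing cell: stratum {stratum}, condition {condition}")

    def cell(stratum: str, condition: str) -> np.ndarray:
        sel = (trials["stratum"] == stratum) & (trials["condition"] == condition)
        return trials.loc[sel, "blast_level"].to_numpy(dtype=float)

    ww_test = wilcoxon_rank_sum(cell("WW", "immediate"), cell("WW", "forced_break"))
    mplus_test = wilcoxon_rank_sum(cell("M+", "immediate"), cell("M+", "forced_break"))

    dyad_means = (
        trials.groupby(["stratum", "condition", "dyad_id"])["blast_level"].mean().reset_index()
    )

    def centred_forced(stratum: str) -> np.ndarray:
        sel = dyad_means["stratum"] == stratum
        imm = dyad_means.loc[sel & (dyad_means["condition"] == "immediate"), "blast_level"]
        forced = dyad_means.loc[sel & (dyad_means["condition"] == "forced_break"), "blast_level"]
        return forced.to_numpy(dtype=float) - float(imm.mean())

    between_test = wilcoxon_rank_sum(centred_forced("M+"), centred_forced("WW"))

    ww_floor_immediate = wilcoxon_signed_rank(cell("WW", "immediate"), mu=1.0, alternative="greater")
    ww_floor_forced = wilcoxon_signed_rank(cell("WW", "forced_break"), mu=1.0, alternative="greater")

    stratum_means = {
        f"{s}:{c}": float(cell(s, c).mean())
        for s in ("WW", "M+")
        for c in ("immediate", "forced_break")
    }

    boot: dict[str, np.ndarray] = {}
    if bootstrap > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        for stratum in ("WW", "M+"):
            sel = dyad_means["stratum"] == stratum
            imm = dyad_means.loc[sel & (dyad_means["condition"] == "immediate"), "blast_level"].to_numpy()
            forced = dyad_means.loc[sel & (dyad_means["condition"] == "forced_break"), "blast_level"].to_numpy()
            diffs = np.empty(bootstrap)
            for b in range(bootstrap):
                diffs[b] = (
                    rng.choice(imm, size=imm.size, replace=True).mean()
                    - rng.choice(forced, size=forced.size, replace=True).mean()
                )
            boot[stratum] = diffs

    return ForcedBreakReport(
        ww_test=ww_test,
        mplus_test=mplus_test,
        between_test=between_test,
        ww_floor_immediate=ww_floor_immediate,
        ww_floor_forced=ww_floor_forced,
        stratum_means=stratum_means,
        bootstrap_differences=boot,
    )
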