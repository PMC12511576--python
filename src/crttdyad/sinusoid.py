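"""Grand-mean oscillation of aggression across rounds.

Averaging the winner's blast at each round index over all dyads produces a
grand-mean series whose cyclic escalation/de-escalation structure is
summarised by the four-parameter sinusoid

    y(t) = a * sin(b * t + c) + d

fit by nonlinear least squares on the 1-based round index t.  Initialisation
is multi-start: the offset starts at the series mean, the amplitude at
sqrt(2) times the series standard deviation, the frequency at the dominant
discrete-Fourier frequency of the demeaned series, and the phase over a grid
of eight values; the best start by residual norm wins.  The fit is reported
in canonical form (a >= 0, c in [0, 2*pi)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["SinusoidFit", "SinusoidConvergenceError", "grand_mean_by_round", "fit_sinusoid"]

_TWO_PI = 2.0 * math.pi


class SinusoidConvergenceError(RuntimeError):
    """No start converged to a usable least-squares solution."""


@dataclass(frozen=True)
class SinusoidFit:
    """y(t) = amplitude * sin(frequency * t + phase) + offset."""

    amplitude: float
    frequency: float  # radians per round
    phase: float  # radians, in [0, 2*pi)
    offset: float  # blast units
    residual_se: float
    p_values: dict[str, float]
    converged: bool
    n_points: int

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.sin(self.frequency * t + self.phase) + self.offset

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "frequency": self.frequency,
            "phase": self.phase,
            "offset": self.offset,
            "residual_se": self.residual_se,
            "p_values": dict(self.p_values),
            "converged": self.converged,
            "n_points": self.n_points,
        }


def grand_mean_by_round(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean winner blast at each round index, averaged over dyads.

    All dyads must share the same round count; ragged inputs raise an error
    naming the offending dyads.
    """
    counts = trials.groupby("dyad_id")["round_index"].count()
    if counts.nunique() > 1:
        # reference count: the most common one, ties broken toward the larger
        freq = counts.value_counts()
        reference = max(freq.index[freq == freq.max()])
        bad = sorted(counts.index[counts != reference])
        raise ValueError(f"ragged round counts; offending dyads: {bad}")
    series = (
        trials.groupby("round_index")["blast_level"]
        .mean()
        .rename("mean_blast")
        .reset_index()
        .sort_values("round_index")
        .reset_index(drop=True)
    )
    return series


def _model(t: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    return a * np.sin(b * t + c) + d


def _canonical(a: float, b: float, c: float, d: float) -> tuple[float, float, float, float]:
    # a*sin(-|b| t + c) = -a*sin(|b| t - c); fold the sign of b, then of a,
    # into the phase, and wrap the phase into [0, 2*pi).
    if b < 0:
        a, b, c = -a, -b, -c
    if a < 0:
        a, c = -a, c + math.pi
    return a, b, c % _TWO_PI, d


def _fourier_frequency(y: np.ndarray) -> float:
    """Angular frequency of the dominant nonzero DFT bin of the demeaned series."""
    n = len(y)
    spectrum = np.abs(np.fft.rfft(y - y.mean()))
    if len(spectrum) <= 1:
        return _TWO_PI / n
    k = int(np.argmax(spectrum[1:])) + 1
    return _TWO_PI * k / n


def fit_sinusoid(
    series: pd.DataFrame | np.ndarray,
    t: np.ndarray | None = None,
    n_phase_starts: int = 8,
) -> SinusoidFit:
    """Least-squares sinusoid fit of a grand-mean series.

    ``series`` may be the frame from :func:`grand_mean_by_round` or a plain
    array of values with ``t`` supplied separately (defaulting to 1-based
    indices).  Needs at least 8 points (four parameters plus slack).

    If even the best sinusoid fits worse than the constant model (residual
    standard error above the series standard deviation), the constant fit
    d = mean is returned with a warning rather than an overfit oscillation.
    """
    if isinstance(series, pd.DataFrame):
        t = series["round_index"].to_numpy(dtype=float)
        y = series["mean_blast"].to_numpy(dtype=float)
    else:
        y = np.asarray(series, dtype=float)
        t = np.arange(1, len(y) + 1, dtype=float) if t is None else np.asarray(t, dtype=float)
    n = len(y)
    if n < 8:
        raise ValueError(f"need >= 8 points to fit 4 parameters, got {n}")

    d0 = float(y.mean())
    sd = float(y.std(ddof=1))
    a0 = math.sqrt(2.0) * sd if sd > 0 else 1e-3
    b0 = _fourier_frequency(y)

    # Frequency is confined to [pi/n, pi] radians/round: at least half a cycle
    # over the observed window (slower sines are indistinguishable from a
    # trend) and at most the Nyquist rate of round-indexed data.
    bounds = ([0.0, math.pi / n, -_TWO_PI, -np.inf], [np.inf, math.pi, 2 * _TWO_PI, np.inf])
    b0 = min(max(b0, bounds[0][1]), bounds[1][1])

    best = None
    diagnostics = []
    for c0 in np.linspace(0.0, _TWO_PI, n_phase_starts, endpoint=False):
        try:
            popt, pcov = optimize.curve_fit(
                _model, t, y, p0=[a0, b0, c0, d0], maxfev=20000,
                bounds=bounds, ftol=1e-14, xtol=1e-14, gtol=1e-14,
            )
        except (RuntimeError, optimize.OptimizeWarning) as exc:  # no convergence from this start
            diagnostics.append(f"start c0={c0:.3f}: {exc}")
            continue
        ssr = float(np.sum((y - _model(t, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise SinusoidConvergenceError(
            "sinusoid fit failed from every start; diagnostics: " + "; ".join(diagnostics)
        )

    ssr, popt, pcov = best
    df = n - 4
    residual_se = math.sqrt(ssr / df)
    if sd > 0 and residual_se > sd:
        warnings.warn(
            "sinusoid fits worse than the constant model; returning d = mean",
            RuntimeWarning,
            stacklevel=2,
        )
        const_se = math.sqrt(float(np.sum((y - d0) ** 2)) / (n - 1))
        return SinusoidFit(
            amplitude=0.0, frequency=0.0, phase=0.0, offset=d0,
            residual_se=const_se,
            p_values={"amplitude": 1.0, "frequency": 1.0, "phase": 1.0, "offset": 0.0},
            converged=False, n_points=n,
        )

    a, b, c, d = _canonical(*popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    p_values = {}
    for name, est, s in zip(("amplitude", "frequency", "phase", "offset"), (a, b, c, d), se):
        if s == 0 or not np.isfinite(s):
            p_values[name] = 0.0 if est != 0 else 1.0
        else:
            p_values[name] = float(2.0 * stats.t.sf(abs(est) / s, df))
    return SinusoidFit(
        amplitude=a, frequency=b, phase=c, offset=d,
        residual_se=residual_se, p_values=p_values, converged=True, n_points=n,
    )
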