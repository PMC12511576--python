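"""Initiation of heightened aggression within dyads.

A dyad's *initiation of heightened aggression* is the earliest round whose
blast is at or above the pair's overall mean blast; the winner of that round
is the initiator.  Such a round always exists because the maximum blast is
at least the mean.  Constant-blast dyads initiate at round 1 by this
convention and are flagged as degenerate so callers can exclude them.

The gender asymmetry in initiation is summarised over mixed-gender dyads as
the proportions of man/woman initiators, their odds ratio, and an
intercept-only logistic regression of the initiator-is-man indicator (whose
exponentiated intercept equals the odds ratio).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "InitiationResult",
    "InitiationGenderSummary",
    "pair_mean",
    "find_initiation",
    "initiation_table",
    "initiation_gender_analysis",
]


@dataclass(frozen=True)
class InitiationResult:
    dyad_id: str
    initiator_id: str
    initiator_gender: str
    initiation_round: int
    pair_mean: float
    #: True when no blast differs from any other (every round ties the mean).
    degenerate: bool


@dataclass(frozen=True)
class InitiationGenderSummary:
    n_dyads: int
    n_man: int
    n_woman: int
    p_man: float
    p_woman: float
    odds_ratio: float
    log_odds: float
    log_odds_se: float
    p_value: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def pair_mean(records: pd.DataFrame) -> float:
    """Arithmetic mean blast over all the dyad's rounds."""
    if len(records) == 0:
        raise ValueError("empty dyad: pair mean undefined")
    return float(records["blast_level"].astype(float).mean())


def find_initiation(records: pd.DataFrame, at_or_above: bool = True) -> InitiationResult:
    """Earliest round whose blast reaches the pair mean, and its winner.

    ``at_or_above=True`` (default) uses blast >= mean; set False for a
    strict > comparison (which can fail on constant dyads — an error).
    """
    mean = pair_mean(records)
    recs = records.sort_values("round_index", kind="mergesort")
    blasts = recs["blast_level"].to_numpy(dtype=float)
    hits = blasts >= mean if at_or_above else blasts > mean
    idx = np.flatnonzero(hits)
    if idx.size == 0:
        raise ValueError("no round strictly above the pair mean (constant dyad under strict comparison)")
    first = recs.iloc[int(idx[0])]
    return InitiationResult(
        dyad_id=str(first["dyad_id"]),
        initiator_id=str(first["winner_id"]),
        initiator_gender=str(first["winner_gender"]),
        initiation_round=int(first["round_index"]),
        pair_mean=mean,
        degenerate=bool(blasts.max() == blasts.min()),
    )


def initiation_table(trials: pd.DataFrame, at_or_above: bool = True) -> pd.DataFrame:
    """Per-dyad initiation results for a whole study."""
    results = [
        find_initiation(dyad, at_or_above=at_or_above)
        for _, dyad in trials.groupby("dyad_id", sort=True)
    ]
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def _is_mixed(dyad: pd.DataFrame) -> bool:
    return set(dyad["winner_gender"]) | set(dyad["loser_gender"]) == {"man", "woman"}


def initiation_gender_analysis(
    trials: pd.DataFrame, at_or_above: bool = True
) -> InitiationGenderSummary:
    """Who initiates in mixed-gender dyads: proportions, odds ratio, logistic fit.

    The logistic model is intercept-only on the initiator-is-man indicator,
    one observation per mixed dyad, so exp(intercept) is exactly the odds
    ratio n_man / n_woman.
    """
    mixed = trials.groupby("dyad_id", sort=True).filter(_is_mixed)
    if len(mixed) == 0:
        raise ValueError("no mixed-gender dyads present")
    table = initiation_table(mixed, at_or_above=at_or_above)
    y = (table["initiator_gender"] == "man").to_numpy(dtype=float)
    n = len(y)
    n_man = int(y.sum())
    n_woman = n - n_man
    if n_man == 0 or n_woman == 0:
        # complete separation: the odds ratio is unbounded, not undefined
        warnings.warn(
            "all initiations from one gender; odds ratio unbounded", RuntimeWarning, stacklevel=2
        )
        unbounded = math.inf if n_woman == 0 else 0.0
        return InitiationGenderSummary(
            n_dyads=n,
            n_man=n_man,
            n_woman=n_woman,
            p_man=n_man / n,
            p_woman=n_woman / n,
            odds_ratio=unbounded,
            log_odds=math.inf if n_woman == 0 else -math.inf,
            log_odds_se=math.nan,
            p_value=math.nan,
            ci_low=math.nan,
            ci_high=math.nan,
        )
    res = sm.Logit(y, np.ones((n, 1))).fit(disp=False)
    log_odds = float(res.params[0])
    se = float(res.bse[0])
    ci_low, ci_high = (float(v) for v in res.conf_int()[0])
    return InitiationGenderSummary(
        n_dyads=n,
        n_man=n_man,
        n_woman=n_woman,
        p_man=n_man / n,
        p_woman=n_woman / n,
        odds_ratio=math.exp(log_odds),
        log_odds=log_odds,
        log_odds_se=se,
        p_value=float(res.pvalues[0]),
        ci_low=ci_low,
        ci_high=ci_high,
    )
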