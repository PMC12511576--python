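"""Cross-lagged kinematic features of blast sequences.

Only round winners emit blasts, so each player's aggression trace is the
subsequence of rounds they won.  For a player's win series we define, at any
point in the series:

* **level** — the blast chosen at that point;
* **velocity** — the change in level across the player's two most recent
  blasts (round-to-round escalation);
* **acceleration** — the change in velocity across the three most recent
  blasts (change in the rate of escalation).

The modelling table pairs each won round (the outcome blast) with both
players' kinematics computed strictly before that round.  Rows lacking any of
the six lagged quantities are dropped rather than zero-filled: "no history"
is not the same observation as "no change".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "KinematicFeatures",
    "LaggedRow",
    "PREDICTORS",
    "ROW_COLUMNS",
    "player_series",
    "kinematics_at",
    "build_lagged_rows",
    "lagged_table",
    "rows_to_frame",
]

#: Predictor columns of the modelling table, aggressor first.
PREDICTORS = [
    "agg_level",
    "agg_velocity",
    "agg_acceleration",
    "tgt_level",
    "tgt_velocity",
    "tgt_acceleration",
]

ROW_COLUMNS = [
    "dyad_id",
    "aggressor_id",
    "target_id",
    "aggressor_gender",
    "target_gender",
    "condition",
    "outcome_blast",
    *PREDICTORS,
]


@dataclass(frozen=True)
class KinematicFeatures:
    """Level/velocity/acceleration at one point of a player's win series.

    Velocity requires two prior blasts and acceleration three; unavailable
    lags are ``None`` (missing), never silently zero.
    """

    level: float
    velocity: float | None
    acceleration: float | None

    @property
    def complete(self) -> bool:
        return self.velocity is not None and self.acceleration is not None


@dataclass(frozen=True)
class LaggedRow:
    """One modelling observation: the aggressor's next blast plus both
    players' preceding kinematics (all six lags present by construction)."""

    dyad_id: str
    aggressor_id: str
    target_id: str
    aggressor_gender: str
    target_gender: str
    condition: str
    outcome_blast: int
    agg_level: float
    agg_velocity: float
    agg_acceleration: float
    tgt_level: float
    tgt_velocity: float
    tgt_acceleration: float


def _sorted_records(records: pd.DataFrame) -> pd.DataFrame:
    if records["dyad_id"].nunique() > 1:
        raise ValueError("records must belong to a single dyad")
    return records.sort_values("round_index", kind="mergesort")


def player_series(records: pd.DataFrame, player_id: str) -> list[tuple[int, int]]:
    """The rounds won by ``player_id`` with their chosen blasts, in order."""
    recs = _sorted_records(records)
    known = set(recs["winner_id"]) | set(recs["loser_id"])
    if player_id not in known:
        raise KeyError(f"unknown player_id {player_id!r}; dyad players are {sorted(known)}")
    won = recs[recs["winner_id"] == player_id]
    return list(zip(won["round_index"].astype(int), won["blast_level"].astype(int)))


def kinematics_at(series: Sequence[tuple[int, int]], position: int) -> KinematicFeatures:
    """Kinematics of a win series at a 0-based position within it."""
    if not (0 <= position < len(series)):
        raise IndexError(f"position {position} out of range for series of length {len(series)}")
    blasts = [b for _, b in series]
    level = float(blasts[position])
    velocity = float(blasts[position] - blasts[position - 1]) if position >= 1 else None
    acceleration = None
    if position >= 2:
        prev_velocity = float(blasts[position - 1] - blasts[position - 2])
        acceleration = velocity - prev_velocity
    return KinematicFeatures(level=level, velocity=velocity, acceleration=acceleration)


def _kinematics_before(series: Sequence[tuple[int, int]], round_index: int) -> KinematicFeatures | None:
    """Kinematics at the last win strictly before ``round_index``, or None."""
    prior = [item for item in series if item[0] < round_index]
    if not prior:
        return None
    return kinematics_at(prior, len(prior) - 1)


def build_lagged_rows(records: pd.DataFrame) -> list[LaggedRow]:
    """Complete-case modelling rows for one dyad.

    For every round won by player P, the outcome is P's blast and the
    predictors are P's and the opponent's kinematics over their own win
    series strictly before that round.  A row is emitted only when both
    series supply level, velocity and acceleration (three prior wins each),
    so no feature ever postdates its outcome.
    """
    recs = _sorted_records(records)
    ids = sorted(set(recs["winner_id"]) | set(recs["loser_id"]))
    series = {pid: player_series(recs, pid) for pid in ids}
    rows: list[LaggedRow] = []
    for rec in recs.itertuples(index=False):
        agg = _kinematics_before(series[rec.winner_id], rec.round_index)
        tgt = _kinematics_before(series[rec.loser_id], rec.round_index)
        if agg is None or tgt is None or not agg.complete or not tgt.complete:
            continue
        rows.append(
            LaggedRow(
                dyad_id=rec.dyad_id,
                aggressor_id=rec.winner_id,
                target_id=rec.loser_id,
                aggressor_gender=rec.winner_gender,
                target_gender=rec.loser_gender,
                condition=rec.condition,
                outcome_blast=int(rec.blast_level),
                agg_level=agg.level,
                agg_velocity=agg.velocity,
                agg_acceleration=agg.acceleration,
                tgt_level=tgt.level,
                tgt_velocity=tgt.velocity,
                tgt_acceleration=tgt.acceleration,
            )
        )
    return rows


def rows_to_frame(rows: Iterable[LaggedRow]) -> pd.DataFrame:
    frame = pd.DataFrame([dataclasses.asdict(r) for r in rows], columns=ROW_COLUMNS)
    if len(frame):
        frame["outcome_blast"] = frame["outcome_blast"].astype(int)
    return frame


def lagged_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Modelling table for a whole study: lagged rows of every dyad."""
    rows: list[LaggedRow] = []
    for _, dyad in trials.groupby("dyad_id", sort=True):
        rows.extend(build_lagged_rows(dyad))
    return rows_to_frame(rows)
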