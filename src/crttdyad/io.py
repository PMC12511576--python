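"""CSV/JSON input-output, validation, seed management and the full pipeline.

Trial tables are tidy CSV, one row per round, with the documented column
set; condition labels are normalised at read time (a ``forced_response``
trial is collapsed into ``immediate``, since timed-out winners still respond
without a break).  Validation aggregates every violation with its 1-based
file line number before failing.

All randomness flows from an explicit master seed; JSON reports embed the
seed, a hash of the configuration, the package version and the schema
version so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .escalation import initiation_gender_analysis, initiation_table
from .features import ROW_COLUMNS, lagged_table
from .oscillator import fit_general, fit_moderated
from .simulate import CONDITIONS, GENDERS, TRIAL_COLUMNS, GenerativeParams, simulate_study
from .sinusoid import fit_sinusoid, grand_mean_by_round
from .stats import DEFAULT_PRIOR_SCALE, forced_break_contrast, jzs_ttest_bf, wilcoxon_rank_sum

__all__ = [
    "SCHEMA_VERSION",
    "TrialValidationError",
    "RunConfig",
    "read_trials",
    "write_trials",
    "read_rows",
    "write_rows",
    "write_report",
    "run_pipeline",
]

SCHEMA_VERSION = "1"
logger = logging.getLogger("crttdyad")

_READ_CONDITIONS = (*CONDITIONS, "forced_response")


class TrialValidationError(ValueError):
    """Aggregated, line-numbered schema violations in a trial CSV."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid trial data:\n" + "\n".join(problems))


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial CSV; collapse forced_response into immediate."""
    frame = pd.read_csv(path)
    problems: list[str] = []
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialValidationError([f"missing columns: {missing}"])

    # data lines start at 2 (line 1 is the header)
    for pos, row in enumerate(frame.itertuples(index=False), start=2):
        blast = row.blast_level
        if not float(blast).is_integer() or not (1 <= int(blast) <= 8):
            problems.append(f"line {pos}: blast_level {blast!r} outside 1-8")
        for label, g in (("winner_gender", row.winner_gender), ("loser_gender", row.loser_gender)):
            if g not in GENDERS:
                problems.append(f"line {pos}: unknown {label} {g!r}")
        if row.condition not in _READ_CONDITIONS:
            problems.append(f"line {pos}: unknown condition {row.condition!r}")
        if row.winner_id == row.loser_id:
            problems.append(f"line {pos}: winner_id equals loser_id ({row.winner_id!r})")
        for label, rt in (("winner_rt_ms", row.winner_rt_ms), ("loser_rt_ms", row.loser_rt_ms)):
            if not np.isfinite(rt) or rt <= 0:
                problems.append(f"line {pos}: {label} {rt!r} not a positive number")

    for dyad_id, sub in frame.groupby("dyad_id"):
        rounds = sub["round_index"].to_list()
        if sorted(rounds) != list(range(1, len(rounds) + 1)):
            problems.append(
                f"dyad {dyad_id!r}: round_index not contiguous from 1 (got {sorted(rounds)[:5]}...)"
            )

    if problems:
        raise TrialValidationError(problems)

    n_collapsed = int((frame["condition"] == "forced_response").sum())
    if n_collapsed:
        logger.info("collapsing %d forced_response trials into immediate", n_collapsed)
        frame.loc[frame["condition"] == "forced_response", "condition"] = "immediate"
    frame["round_index"] = frame["round_index"].astype(int)
    frame["blast_level"] = frame["blast_level"].astype(int)
    return frame[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_rows(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ROW_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"modelling table lacks columns: {missing}")
    frame["outcome_blast"] = frame["outcome_blast"].astype(int)
    return frame[ROW_COLUMNS]


def write_rows(rows: pd.DataFrame, path: str | Path) -> None:
    rows[ROW_COLUMNS].to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run needs, seed included."""

    seed: int
    n_ww: int = 20
    n_wm: int = 20
    n_mm: int = 20
    condition_mix: float = 0.5
    n_rounds: int = 30
    model_method: str = "mixed"  # or "pooled"
    prior_scale: float = DEFAULT_PRIOR_SCALE
    initiation_at_or_above: bool = True
    params: GenerativeParams = field(default_factory=GenerativeParams)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "seed" not in raw:
            raise ValueError("config must state an explicit master seed")
        params = GenerativeParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_report(payload: dict, path: str | Path, config: RunConfig) -> None:
    """Write a stage report with reproducibility metadata embedded."""
    body = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        **payload,
    }
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """simulate -> features -> fit -> escalate -> oscillate -> stats.

    Writes trials.csv, rows.csv and one JSON report per stage plus a
    combined summary; byte-identical across runs with the same config.
    """
    if config.n_ww + config.n_wm + config.n_mm <= 0:
        raise ValueError("config requests zero dyads; nothing to run")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    def stage(name, func):
        logger.info("stage %s", name)
        try:
            return func()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    trials = stage(
        "simulate",
        lambda: simulate_study(
            config.n_ww, config.n_wm, config.n_mm,
            params=config.params, seed=config.seed,
            condition_mix=config.condition_mix, n_rounds=config.n_rounds,
        ),
    )
    write_trials(trials, outdir / "trials.csv")
    summary["simulate"] = {"n_dyads": int(trials["dyad_id"].nunique()), "n_trials": len(trials)}

    rows = stage("features", lambda: lagged_table(trials))
    write_rows(rows, outdir / "rows.csv")
    summary["features"] = {"n_rows": len(rows)}

    fit = stage("fit_general", lambda: fit_general(rows, method=config.model_method))
    write_report(fit.to_dict(), outdir / "fit_general.json", config)
    summary["fit_general"] = {
        "r2_marginal": fit.r2_marginal,
        "r2_conditional": fit.r2_conditional,
        "agg_velocity_B": fit.coefficients["agg_velocity"],
    }

    moderated = stage("fit_woman_aggressor", lambda: fit_moderated(rows, method=config.model_method))
    write_report(moderated.to_dict(), outdir / "fit_woman_aggressor.json", config)
    summary["fit_woman_aggressor"] = {
        "reference_intercept": moderated.reference["intercept"],
        "man_target_intercept_delta": moderated.man_target_delta["intercept"],
    }

    def escalate():
        table = initiation_table(trials, at_or_above=config.initiation_at_or_above)
        gender = initiation_gender_analysis(trials, at_or_above=config.initiation_at_or_above)
        return table, gender

    table, gender = stage("escalate", escalate)
    table.to_csv(outdir / "initiation.csv", index=False)
    write_report(gender.to_dict(), outdir / "initiation.json", config)
    summary["escalate"] = {"odds_ratio": gender.odds_ratio, "n_mixed_dyads": gender.n_dyads}

    def oscillate():
        series = grand_mean_by_round(trials)
        return series, fit_sinusoid(series)

    series, sin_fit = stage("oscillate", oscillate)
    series.to_csv(outdir / "grand_mean.csv", index=False)
    write_report(sin_fit.to_dict(), outdir / "sinusoid.json", config)
    summary["oscillate"] = {"frequency": sin_fit.frequency, "offset": sin_fit.offset}

    def stats_stage():
        men = trials.loc[trials["winner_gender"] == "man", "blast_level"].to_numpy(dtype=float)
        women = trials.loc[trials["winner_gender"] == "woman", "blast_level"].to_numpy(dtype=float)
        out: dict = {}
        if men.size and women.size:
            gender_test = wilcoxon_rank_sum(men, women)
            out["gender_rank_sum"] = gender_test.to_dict()
            out["gender_bf"] = jzs_ttest_bf(men, women, prior_scale=config.prior_scale).to_dict()
        out["forced_break"] = forced_break_contrast(trials).to_dict()
        return out

    stats_report = stage("stats", stats_stage)
    write_report(stats_report, outdir / "stats.json", config)
    summary["stats"] = {
        "mplus_forced_break_r": stats_report["forced_break"]["mplus_test"]["effect_size_r"],
        "ww_forced_break_r": stats_report["forced_break"]["ww_test"]["effect_size_r"],
    }

    write_report(summary, outdir / "summary.json", config)
    return summary
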