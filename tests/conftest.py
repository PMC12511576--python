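import numpy as np
import pandas as pd
import pytest

from crttdyad.features import lagged_table
from crttdyad.simulate import (
    DyadSpec,
    GenerativeParams,
    PlayerSpec,
    records_to_frame,
    simulate_dyad,
    simulate_study,
)


def make_dyad(genders=("woman", "man"), condition="immediate", n_rounds=30, dyad_id="d0"):
    players = (
        PlayerSpec(player_id=f"{dyad_id}_p0", gender=genders[0]),
        PlayerSpec(player_id=f"{dyad_id}_p1", gender=genders[1]),
    )
    return DyadSpec(dyad_id=dyad_id, players=players, condition=condition, n_rounds=n_rounds)


def manual_trials(blasts_and_winners, dyad_id="d0", genders=None, condition="immediate"):
    """Build a trial frame by hand: list of (winner_key, blast) per round.

    winner_key is "p0"/"p1"; reaction times are synthetic fillers consistent
    with who won.
    """
    genders = genders or {"p0": "woman", "p1": "man"}
    rows = []
    for i, (winner, blast) in enumerate(blasts_and_winners, start=1):
        loser = "p1" if winner == "p0" else "p0"
        rows.append(
            {
                "dyad_id": dyad_id,
                "round_index": i,
                "winner_id": f"{dyad_id}_{winner}",
                "loser_id": f"{dyad_id}_{loser}",
                "winner_gender": genders[winner],
                "loser_gender": genders[loser],
                "blast_level": blast,
                "condition": condition,
                "winner_rt_ms": 300.0,
                "loser_rt_ms": 450.0,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_params():
    return GenerativeParams()


@pytest.fixture(scope="session")
def core_params():
    """Homogeneous oscillator process: context shifts switched off."""
    return GenerativeParams().without_context_effects()


@pytest.fixture(scope="session")
def small_study(default_params):
    return simulate_study(8, 8, 8, params=default_params, seed=11)


@pytest.fixture(scope="session")
def small_rows(small_study):
    return lagged_table(small_study)


@pytest.fixture(scope="session")
def medium_core_study(core_params):
    """60 dyads from the homogeneous process, for model-level checks."""
    return simulate_study(20, 20, 20, params=core_params, seed=29)


@pytest.fixture(scope="session")
def medium_core_rows(medium_core_study):
    return lagged_table(medium_core_study)
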