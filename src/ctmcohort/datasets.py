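"""Packaged example data for tests, demos and documentation.

Two small fixtures ship with the package: the published 10-state
cardiovascular jump-frequency matrix, and a two-patient snapshot of raw
episode rows illustrating same-day multimorbidity and consecutive duplicate
episodes.  A synthetic 10-state generator is also provided for demos; its
exit rates are invented, so it must never be treated as an estimate of real
cardiovascular transition rates.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .episodes import EpisodeTable, read_episodes
from .estimation import GeneratorMatrix, TransitionCounts, jump_probability_matrix
from .states import CVD_STATE_ORDER, StateSpace


def _data_path(name: str):
    return resources.files("ctmcohort.data").joinpath(name)


def cvd_state_space() -> StateSpace:
    """The 10-state cardiovascular state space with death absorbing."""
    return StateSpace(states=CVD_STATE_ORDER, absorbing=frozenset({"Death"}))


def load_cvd_jump_frequencies() -> TransitionCounts:
    """The published cohort's jump-frequency matrix (counts only, no waits)."""
    with resources.as_file(_data_path("cvd_jump_frequencies.csv")) as path:
        df = pd.read_csv(path, index_col=0)
    space = cvd_state_space()
    N = df.loc[list(space.states), list(space.states)].to_numpy(dtype=int)
    return TransitionCounts(state_space=space, N=N)


def load_demo_episodes() -> EpisodeTable:
    """Two illustrative patients' raw episode rows (12 records)."""
    with resources.as_file(_data_path("demo_episodes.csv")) as path:
        return read_episodes(path)


def synthetic_cvd_generator(mean_hold_days: float = 400.0) -> GeneratorMatrix:
    """A synthetic 10-state generator for demos and documentation only.

    The embedded jump probabilities come from the packaged jump-frequency
    fixture, but the per-state exit rates are invented (every transient
    state gets the same ``1 / mean_hold_days`` exit rate) because the
    cohort's holding-time totals are not published.  Do not use as ground
    truth for anything beyond illustration.
    """
    counts = load_cvd_jump_frequencies()
    jump = jump_probability_matrix(counts, absorbing_self_loop=False)
    rate = 1.0 / mean_hold_days
    Q = jump * rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return GeneratorMatrix(state_space=counts.state_space, Q=Q, mode="paper")
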