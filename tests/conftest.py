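import numpy as np
import pytest

import ctmcohort as cc
from ctmcohort.datasets import load_cvd_jump_frequencies, load_demo_episodes


@pytest.fixture(scope="session")
def demo_table():
    """Two-patient raw episode snapshot (same-day multimorbidity, duplicates)."""
    return load_demo_episodes()


@pytest.fixture(scope="session")
def cvd_counts():
    """The packaged 10-state cardiovascular jump-frequency matrix."""
    return load_cvd_jump_frequencies()


def make_generator(states, rows, absorbing=("Death",)):
    """Generator from an off-diagonal rate table; diagonals filled in."""
    space = cc.StateSpace(states=tuple(states), absorbing=frozenset(absorbing) & set(states))
    Q = np.array(rows, dtype=float)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return cc.GeneratorMatrix(state_space=space, Q=Q)


@pytest.fixture(scope="session")
def four_state_generator():
    """CHF/Stroke/MI + absorbing death, calibrated for good per-pair counts.

    Exit rates 1/250, 1/300 and 1/200 per day; each jump goes to the other
    two transient states with probability 0.4 each and to death with 0.2.
    """
    return make_generator(
        ("CHF", "Stroke", "MI", "Death"),
        [
            [0, 0.004 * 0.4, 0.004 * 0.4, 0.004 * 0.2],
            [0.4 / 300, 0, 0.4 / 300, 0.2 / 300],
            [0.005 * 0.4, 0.005 * 0.4, 0, 0.005 * 0.2],
            [0, 0, 0, 0],
        ],
    )
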