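"""Time-variant transition probabilities P(t) = e^{Qt} and derived forecasts.

Given a generator matrix Q (rates per day), the transition probability
matrix after t days is the matrix exponential of Q·t, computed by SciPy's
scaling-and-squaring implementation.  Rows of P(t) are probability
distributions; they are never renormalised — drift beyond tolerance is
treated as a defect, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .estimation import GeneratorMatrix
from .states import StateSpace

#: default review interval ("3 months") and horizon ("5 years") in days
DEFAULT_INTERVAL_DAYS = 90.0
DEFAULT_HORIZON_DAYS = 1800.0


@dataclass
class TransitionProbabilityMatrix:
    """P(t): probability of being in state j after t days given start i."""

    state_space: StateSpace
    t: float
    P: np.ndarray

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        n = len(self.state_space)
        if self.P.shape != (n, n):
            raise ValueError(f"P must be {n}x{n}")

    def check(self, tol: float = 1e-9) -> None:
        if np.any(self.P < -tol) or np.any(self.P > 1 + tol):
            raise ValueError("transition probabilities outside [0, 1]")
        if np.any(np.abs(self.P.sum(axis=1) - 1.0) > tol):
            raise ValueError("transition probability rows must sum to 1")
        for a in self.state_space.absorbing:
            i = self.state_space.index(a)
            unit = np.zeros(len(self.state_space))
            unit[i] = 1.0
            if np.any(np.abs(self.P[i] - unit) > tol):
                raise ValueError(f"absorbing state {a!r} row is not a unit vector")

    def row(self, state: str) -> np.ndarray:
        return self.P[self.state_space.index(state)]

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.state_space.states)
        return pd.DataFrame(self.P, index=labels, columns=labels)


@dataclass
class ProgressionPattern:
    """Start-state-conditional probabilities over a regular time grid."""

    state_space: StateSpace
    start_state: str
    grid: np.ndarray          # strictly increasing times, days
    probs: np.ndarray         # len(grid) x n_states; rows sum to 1

    def to_frame(self) -> pd.DataFrame:
        """Long format: (start_state, time_days, to_state, probability)."""
        rows = []
        for k, t in enumerate(self.grid):
            for j, s in enumerate(self.state_space.states):
                rows.append(
                    {
                        "start_state": self.start_state,
                        "time_days": float(t),
                        "to_state": s,
                        "probability": float(self.probs[k, j]),
                    }
                )
        return pd.DataFrame(rows)

    def to_wide(self) -> pd.DataFrame:
        """Wide heat-map layout: one row per grid time, one column per state."""
        return pd.DataFrame(
            self.probs,
            index=pd.Index(self.grid, name="time_days"),
            columns=list(self.state_space.states),
        )


def transition_probability(Q: GeneratorMatrix, t: float) -> TransitionProbabilityMatrix:
    """P(t) = e^{Qt} for t >= 0 days; P(0) is exactly the identity."""
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    Q.check()
    n = len(Q.state_space)
    P = np.eye(n) if t == 0 else expm(Q.Q * float(t))
    result = TransitionProbabilityMatrix(state_space=Q.state_space, t=float(t), P=P)
    result.check()
    return result


def progression_series(
    Q: GeneratorMatrix,
    start_state: str,
    interval_days: float = DEFAULT_INTERVAL_DAYS,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
) -> ProgressionPattern:
    """Start-state row of P(t) on the grid Δ, 2Δ, …, up to the horizon.

    The defaults (90-day interval, 1800-day horizon) give the 20-point
    quarterly five-year review grid.
    """
    if interval_days <= 0:
        raise ValueError("interval_days must be positive")
    if horizon_days < interval_days:
        raise ValueError("horizon_days must be at least interval_days")
    i = Q.state_space.index(start_state)
    n_steps = int(np.floor(horizon_days / interval_days + 1e-9))
    grid = interval_days * np.arange(1, n_steps + 1)
    probs = np.empty((n_steps, len(Q.state_space)))
    for k, t in enumerate(grid):
        probs[k] = transition_probability(Q, t).P[i]
    return ProgressionPattern(
        state_space=Q.state_space, start_state=start_state, grid=grid, probs=probs
    )


def forecast_state_mix(
    Q: GeneratorMatrix, initial_mix, t: float, tol: float = 1e-9
) -> np.ndarray:
    """Propagate a cohort composition forward: mix(t) = mix(0) · P(t).

    ``initial_mix`` must be a probability vector over the state space.
    """
    mix = np.asarray(initial_mix, dtype=float)
    if mix.shape != (len(Q.state_space),):
        raise ValueError(f"initial_mix must have length {len(Q.state_space)}")
    if np.any(mix < -tol):
        raise ValueError("initial_mix entries must be nonnegative")
    if abs(mix.sum() - 1.0) > tol:
        raise ValueError(f"initial_mix must sum to 1, got {mix.sum()!r}")
    return mix @ transition_probability(Q, t).P
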