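"""Estimation of the embedded jump chain and the generator (intensity) matrix.

Two generator estimators are provided.  ``mode="paper"`` uses the
destination-specific ratio q_ij = n_ij / r_ij, where r_ij is the total time
held in state i across exactly those stays that ended with a jump to j.
``mode="mle"`` is the classical maximum-likelihood estimator for a fully
observed Markov jump process, q_ij = n_ij / T_i, with T_i the total holding
time in i regardless of destination.  The two coincide only when every exit
from i is equally fast on average; the destination-specific form estimates
the exit rate of i separately from each realised destination, while the MLE
splits the exit rate across destinations in proportion to the embedded jump
probabilities.  Both are kept because cohort reports in this style publish
the destination-specific worked numbers, while simulation-grounded
inference calls for the MLE.

Right censoring is ignored throughout: time after a patient's last observed
episode contributes no exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .states import PatientTrajectory, StateSpace

logger = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (spreadsheet-style), e.g. 0.05 -> 0.1."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def as_percent(values, decimals: int = 1) -> np.ndarray:
    """Fractions -> percents rounded half-up to ``decimals`` places."""
    arr = np.asarray(values, dtype=float) * 100.0
    return np.vectorize(lambda v: round_half_up(v, decimals))(arr)


@dataclass
class TransitionCounts:
    """Observed one-step jump counts and destination-specific wait times.

    ``N[i, j]`` counts observed i→j transitions; ``R[i, j]`` is the total
    number of days held in i immediately before those jumps; ``wait_samples``
    keeps the individual waits per ordered pair.  ``R``/``wait_samples`` may
    be ``None`` for count-only sources such as a published jump frequency
    table.  Absorbing-state rows are identically zero.
    """

    state_space: StateSpace
    N: np.ndarray
    R: np.ndarray | None = None
    wait_samples: Mapping[tuple[str, str], list[float]] | None = None

    def __post_init__(self):
        self.N = np.asarray(self.N)
        n = len(self.state_space)
        if self.N.shape != (n, n):
            raise ValueError(f"N must be {n}x{n}")
        if self.R is not None:
            self.R = np.asarray(self.R, dtype=float)
            if self.R.shape != (n, n):
                raise ValueError(f"R must be {n}x{n}")
        self.check()

    def check(self) -> None:
        if np.any(np.diag(self.N) != 0):
            raise ValueError("self-transitions must have been merged away (diag N != 0)")
        if np.any(self.N < 0):
            raise ValueError("negative transition counts")
        for a in self.state_space.absorbing:
            i = self.state_space.index(a)
            if self.N[i].any() or (self.R is not None and self.R[i].any()):
                raise ValueError(f"absorbing state {a!r} has outgoing mass")
        if self.R is not None:
            if np.any(self.R < 0):
                raise ValueError("negative wait times")
            mask = self.N > 0
            if np.any(self.R[mask] < self.N[mask]):
                raise ValueError("total waits below one day per transition")
        if self.wait_samples is not None and self.R is not None:
            for (a, b), samples in self.wait_samples.items():
                i, j = self.state_space.index(a), self.state_space.index(b)
                if len(samples) != self.N[i, j]:
                    raise ValueError(f"sample count mismatch for {a}->{b}")
                if abs(sum(samples) - self.R[i, j]) > 1e-9 * max(1.0, self.R[i, j]):
                    raise ValueError(f"sample total mismatch for {a}->{b}")

    @property
    def total_holding_time(self) -> np.ndarray:
        """T_i: total observed days held in each state before any jump."""
        if self.R is None:
            raise ValueError("wait times unavailable in this counts object")
        return self.R.sum(axis=1)

    def to_frame(self, which: str = "N") -> pd.DataFrame:
        arr = {"N": self.N, "R": self.R}[which]
        labels = list(self.state_space.states)
        return pd.DataFrame(arr, index=labels, columns=labels)


@dataclass
class GeneratorMatrix:
    """Infinitesimal generator Q: rates per day, zero row sums.

    Off-diagonal entries are nonnegative transition rates; each diagonal
    entry is the negative row sum, so −q_ii is the exit rate of state i.
    Absorbing rows are identically zero.
    """

    state_space: StateSpace
    Q: np.ndarray
    mode: str = "paper"

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        n = len(self.state_space)
        if self.Q.shape != (n, n):
            raise ValueError(f"Q must be {n}x{n}")
        self.check()

    def check(self) -> None:
        off = self.Q - np.diag(np.diag(self.Q))
        if np.any(off < 0):
            raise ValueError("negative off-diagonal rate in generator")
        scale = np.maximum(np.abs(self.Q).sum(axis=1), 1.0)
        if np.any(np.abs(self.Q.sum(axis=1)) > 1e-12 * scale):
            raise ValueError("generator row sums must be zero")
        for a in self.state_space.absorbing:
            if self.Q[self.state_space.index(a)].any():
                raise ValueError(f"absorbing state {a!r} has nonzero rates")

    @property
    def exit_rates(self) -> np.ndarray:
        return -np.diag(self.Q)

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.state_space.states)
        return pd.DataFrame(self.Q, index=labels, columns=labels)


def count_transitions(
    trajectories: Sequence[PatientTrajectory], state_space: StateSpace
) -> TransitionCounts:
    """Tally one-step jumps and their waits from preprocessed trajectories.

    Each consecutive visit pair (s@d1, s'@d2) contributes one i→j count and
    d2−d1 days of destination-specific wait.  Single-visit trajectories
    contribute nothing; neither does time after the final visit.
    """
    n = len(state_space)
    N = np.zeros((n, n), dtype=int)
    R = np.zeros((n, n), dtype=float)
    samples: dict[tuple[str, str], list[float]] = {}
    for traj in trajectories:
        for (s_a, d_a), (s_b, d_b) in zip(traj.visits, traj.visits[1:]):
            i, j = state_space.index(s_a), state_space.index(s_b)
            N[i, j] += 1
            R[i, j] += d_b - d_a
            samples.setdefault((s_a, s_b), []).append(float(d_b - d_a))
    return TransitionCounts(state_space=state_space, N=N, R=R, wait_samples=samples)


def jump_probability_matrix(
    counts: TransitionCounts, absorbing_self_loop: bool = True
) -> np.ndarray:
    """Embedded jump-chain probabilities: row-normalised jump frequencies.

    Absorbing rows become identity rows when ``absorbing_self_loop`` (the
    convention used in published jump tables, where the death row reads
    100% death), otherwise all-zero.  A non-absorbing state with no
    observed exits cannot be normalised; its row is emitted all-zero with a
    warning.
    """
    N = counts.N.astype(float)
    P = np.zeros_like(N)
    totals = N.sum(axis=1)
    for i, state in enumerate(counts.state_space.states):
        if totals[i] > 0:
            P[i] = N[i] / totals[i]
        elif counts.state_space.is_absorbing(state):
            if absorbing_self_loop:
                P[i, i] = 1.0
        else:
            logger.warning(
                "state %r has no observed outgoing transitions; jump row left zero",
                state,
            )
    return P


def estimate_generator(counts: TransitionCounts, mode: str = "paper") -> GeneratorMatrix:
    """Estimate the generator matrix from jump counts and wait times.

    ``mode="paper"``: q_ij = n_ij / r_ij (destination-specific waits);
    ``mode="mle"``: q_ij = n_ij / T_i (total holding time in i).  In both
    modes q_ij = 0 whenever n_ij = 0 (no smoothing), diagonals make row sums
    zero, and absorbing rows are zero.
    """
    if mode not in ("paper", "mle"):
        raise ValueError(f"unknown estimator mode {mode!r}")
    if counts.R is None:
        raise ValueError("generator estimation needs wait times (R)")
    n = len(counts.state_space)
    Q = np.zeros((n, n), dtype=float)
    if mode == "paper":
        mask = counts.N > 0
        Q[mask] = counts.N[mask] / counts.R[mask]
    else:
        T = counts.total_holding_time
        rows = T > 0
        Q[rows] = counts.N[rows] / T[rows, None]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return GeneratorMatrix(state_space=counts.state_space, Q=Q, mode=mode)


def transition_time_stats(counts: TransitionCounts) -> pd.DataFrame:
    """Per-pair mean and population SD of the observed waits, in days.

    Only pairs with at least one observed transition appear; with a single
    observation the SD is 0 by the population (divisor n) convention.
    """
    if counts.wait_samples is None:
        raise ValueError("individual wait samples unavailable in this counts object")
    rows = []
    order = {s: k for k, s in enumerate(counts.state_space.states)}
    for (a, b), samples in sorted(
        counts.wait_samples.items(), key=lambda kv: (order[kv[0][0]], order[kv[0][1]])
    ):
        arr = np.asarray(samples, dtype=float)
        rows.append(
            {
                "from_state": a,
                "to_state": b,
                "n": len(arr),
                "mean_days": float(arr.mean()),
                "sd_days": float(arr.std(ddof=0)),
            }
        )
    return pd.DataFrame(rows, columns=["from_state", "to_state", "n", "mean_days", "sd_days"])


def first_episode_distribution(
    trajectories: Sequence[PatientTrajectory],
    restrict_to: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Distribution of each patient's first recorded state.

    With ``restrict_to``, only patients whose first state lies in the subset
    are counted and fractions are over that restricted denominator.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    firsts = [t.first_state for t in trajectories]
    if restrict_to is not None:
        allowed = set(restrict_to)
        firsts = [s for s in firsts if s in allowed]
    if not firsts:
        raise ValueError("no patients selected by restrict_to")
    series = pd.Series(firsts).value_counts()
    total = int(series.sum())
    df = pd.DataFrame(
        {
            "state": series.index,
            "count": series.values,
            "fraction": series.values / total,
        }
    ).reset_index(drop=True)
    return df


@dataclass
class DeathAttribution:
    """Share of entries into the absorbing state attributed to each source."""

    table: pd.DataFrame
    subset_share: float
    total_deaths: int


def death_attribution(
    counts: TransitionCounts,
    absorbing_state: str = "Death",
    subset: Iterable[str] | None = None,
) -> DeathAttribution:
    """Attribute absorbing-state entries to their immediate source states.

    ``share[i] = N[i, death] / total deaths``; the optional ``subset`` share
    aggregates the shares of the listed source states.
    """
    j = counts.state_space.index(absorbing_state)
    col = counts.N[:, j]
    total = int(col.sum())
    if total == 0:
        raise ValueError(f"no transitions into {absorbing_state!r} observed")
    rows = [
        {"source_state": s, "count": int(col[i]), "share": col[i] / total}
        for i, s in enumerate(counts.state_space.states)
        if col[i] > 0
    ]
    table = pd.DataFrame(rows, columns=["source_state", "count", "share"])
    table = table.sort_values("count", ascending=False).reset_index(drop=True)
    chosen = set(subset) if subset is not None else set(table["source_state"])
    subset_share = float(table.loc[table["source_state"].isin(chosen), "share"].sum())
    return DeathAttribution(table=table, subset_share=subset_share, total_deaths=total)
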