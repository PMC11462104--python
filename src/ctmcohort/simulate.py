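"""Synthetic episodic cohorts drawn from a known generator matrix.

The simulator realises the standard mechanics of a Markov jump process: a
patient holds in state i for an Exponential(−q_ii) number of days, then
jumps to j ≠ i with probability q_ij / (−q_ii), until absorption or the end
of follow-up.  Its output is an ordinary episode table, so every stage of
the pipeline can be exercised without restricted registry data.

:func:`roughen_episodes` then re-introduces the raw-data pathologies the
preprocessing rules exist for — composite states split back into same-day
component episodes, and duplicate reports of an ongoing state — in a way
that is guaranteed to be undone exactly by trajectory construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .episodes import EpisodeTable
from .estimation import GeneratorMatrix
from .states import CompositeNamingScheme, cvd_naming_scheme

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Ground truth and realism controls for a simulated cohort.

    ``initial_distribution`` is over the full state space but may put no
    mass on absorbing states.  ``round_days`` rounds each exponential
    holding time up to a whole day (minimum one day), matching whole-day
    registry records; ``decompose_composites`` and ``duplicate_rate`` are
    applied by :func:`roughen_episodes`, not by the simulator itself.
    """

    Q_true: GeneratorMatrix
    initial_distribution: Sequence[float]
    n_patients: int
    max_followup_days: float = 5800.0
    seed: int = 0
    decompose_composites: bool = False
    duplicate_rate: float = 0.0
    round_days: bool = True
    naming: CompositeNamingScheme = field(default_factory=cvd_naming_scheme)
    id_prefix: str = "SIM"
    covariates: Mapping[str, Sequence[tuple[str, float]]] | None = None

    def __post_init__(self):
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate must lie in [0, 1]")
        if self.initial_distribution.shape != (len(self.Q_true.state_space),):
            raise ValueError("initial_distribution length must match the state space")
        if abs(self.initial_distribution.sum() - 1.0) > 1e-9:
            raise ValueError("initial_distribution must sum to 1")
        if np.any(self.initial_distribution < 0):
            raise ValueError("initial_distribution entries must be nonnegative")
        for a in self.Q_true.state_space.absorbing:
            if self.initial_distribution[self.Q_true.state_space.index(a)] > 0:
                raise ValueError(f"initial mass on absorbing state {a!r}")


def _patient_ids(prefix: str, n: int) -> list[str]:
    width = max(6, len(str(n)))
    return [f"{prefix}-{k:0{width}d}" for k in range(1, n + 1)]


def simulate_cohort(config: SimulationConfig) -> EpisodeTable:
    """Draw a cohort of episode rows from the configured jump process.

    Each patient starts at day 0 in a state drawn from the initial
    distribution and contributes one row per state entered.  A state with
    zero exit rate that is not flagged absorbing freezes the patient there
    (with a warning) until the end of follow-up.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    space = config.Q_true.state_space
    Q = config.Q_true.Q
    states = list(space.states)
    n = len(states)
    rows: list[tuple[str, str, int]] = []
    cov_values: dict[str, list[str]] = {}
    cov_spec = config.covariates or {}
    for label, pairs in cov_spec.items():
        values = [v for v, _ in pairs]
        probs = np.asarray([p for _, p in pairs], dtype=float)
        cov_values[label] = [
            values[k]
            for k in rng.choice(len(values), size=config.n_patients, p=probs / probs.sum())
        ]
    ids = _patient_ids(config.id_prefix, config.n_patients)
    for p, pid in enumerate(ids):
        i = int(rng.choice(n, p=config.initial_distribution))
        day = 0.0
        rows.append((pid, states[i], 0))
        while True:
            exit_rate = -Q[i, i]
            if space.is_absorbing(states[i]):
                break
            if exit_rate <= 0:
                logger.warning(
                    "state %r has zero exit rate but is not absorbing; "
                    "patient %s frozen until end of follow-up", states[i], pid,
                )
                break
            hold = rng.exponential(1.0 / exit_rate)
            if config.round_days:
                hold = max(1.0, math.ceil(hold))
            next_day = day + hold
            if next_day > config.max_followup_days:
                break
            jump_probs = Q[i].clip(min=0.0) / exit_rate
            jump_probs[i] = 0.0
            jump_probs = jump_probs / jump_probs.sum()
            i = int(rng.choice(n, p=jump_probs))
            day = next_day
            rows.append((pid, states[i], int(day) if config.round_days else day))
    covariate_labels = tuple(cov_spec.keys())
    table = EpisodeTable.from_records(
        rows, source=f"simulate_cohort(seed={config.seed})"
    )
    for label in covariate_labels:
        by_patient = dict(zip(ids, cov_values[label]))
        table.df[label] = table.df["patient_id"].map(by_patient)
    table = EpisodeTable(
        table.df, source=table.source, covariate_labels=covariate_labels
    )
    return table.sort()


def roughen_episodes(table: EpisodeTable, config: SimulationConfig) -> EpisodeTable:
    """Make clean simulator output look like raw registry data.

    With ``decompose_composites``, every composite-state row is replaced by
    one row per component episode on the same day (they recompose to the
    original state).  With probability ``duplicate_rate`` per non-final
    visit, a duplicate same-state row is injected at a day strictly inside
    the holding interval (skipped when the interval has no interior day).
    Trajectory construction undoes both transforms exactly.
    """
    rng = np.random.default_rng(config.seed + 1)
    naming = config.naming
    df = table.sort().df
    rows: list[dict] = []

    def emit(pid: str, state: str, day: int, covariates: dict) -> None:
        labels = naming.decompose(state) if config.decompose_composites else [state]
        for label in labels:
            rows.append({"patient_id": pid, "episode": label, "day": day, **covariates})

    for pid, group in df.groupby("patient_id", sort=True):
        visits = list(zip(group["episode"], group["day"].astype(int)))
        covs = {
            label: group.iloc[0][label] for label in table.covariate_labels
        }
        for k, (state, day) in enumerate(visits):
            emit(pid, state, day, covs)
            if k + 1 < len(visits) and config.duplicate_rate > 0:
                next_day = visits[k + 1][1]
                if next_day - day >= 2 and rng.random() < config.duplicate_rate:
                    dup_day = int(rng.integers(day + 1, next_day))
                    emit(pid, state, dup_day, covs)
    out = EpisodeTable.from_records(
        [(r["patient_id"], r["episode"], r["day"]) for r in rows],
        source=table.source + "+roughened",
    )
    for label in table.covariate_labels:
        out.df[label] = [r[label] for r in rows]
    out = EpisodeTable(
        out.df, source=out.source, covariate_labels=table.covariate_labels
    )
    return out.sort()
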