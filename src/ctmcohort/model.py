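"""Model/Results interface tying the pipeline together.

:class:`CTMCModel` holds a preprocessed cohort (trajectories plus state
space); :meth:`CTMCModel.fit` estimates the generator and returns a
:class:`CTMCResults` carrying the estimates, the embedded jump chain,
descriptive transition statistics and prediction methods, with a
``summary()`` in the style of statistical modelling packages.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import estimation, prediction
from .episodes import EpisodeTable, read_episodes
from .states import (
    CVD_STATE_ORDER,
    CompositeNamingScheme,
    PatientTrajectory,
    StateSpace,
    build_trajectories,
    cvd_naming_scheme,
)


class CTMCModel:
    """Continuous-time Markov chain model of cohort disease progression.

    Construction runs the full preprocessing pipeline (composite-state
    naming, rare-state pruning, run merging, absorbing truncation) so the
    model exposes Markov-valid trajectories and the induced state space.

    Parameters
    ----------
    table
        Raw episode rows (one row per patient/episode/day).
    naming
        Composite naming scheme; defaults to the cardiovascular scheme.
    absorbing
        Episode labels that terminate a trajectory (default ``("Death",)``).
    min_state_count
        Occurrence threshold below which a state is pruned (0 keeps all).
    state_order
        Preferred display order for the state space.
    """

    def __init__(
        self,
        table: EpisodeTable,
        naming: CompositeNamingScheme | None = None,
        absorbing: Iterable[str] = ("Death",),
        min_state_count: int = 0,
        state_order: Sequence[str] | None = CVD_STATE_ORDER,
        prune_policy: str = "drop_records",
    ):
        self.table = table
        self.naming = naming if naming is not None else cvd_naming_scheme()
        self.absorbing_labels = tuple(absorbing)
        self.min_state_count = min_state_count
        self.trajectories, self.state_space = build_trajectories(
            table,
            naming=self.naming,
            min_count=min_state_count,
            absorbing_labels=absorbing,
            state_order=state_order,
            prune_policy=prune_policy,
        )

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_csv(cls, path, delimiter: str = ",", columns=None, **kwargs) -> "CTMCModel":
        return cls(read_episodes(path, delimiter=delimiter, columns=columns), **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        patient_col: str = "patient_id",
        episode_col: str = "episode",
        day_col: str = "day",
        covariate_cols: Sequence[str] = (),
        **kwargs,
    ) -> "CTMCModel":
        frame = df.rename(
            columns={patient_col: "patient_id", episode_col: "episode", day_col: "day"}
        )
        keep = ["patient_id", "episode", "day", *covariate_cols]
        table = EpisodeTable(
            frame.loc[:, keep].copy(), covariate_labels=tuple(covariate_cols)
        ).sort()
        return cls(table, **kwargs)

    # -- properties ---------------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.trajectories)

    @property
    def n_transitions(self) -> int:
        return sum(len(t.visits) - 1 for t in self.trajectories)

    def fit(self, mode: str = "paper") -> "CTMCResults":
        """Estimate the generator and return a results object."""
        counts = estimation.count_transitions(self.trajectories, self.state_space)
        generator = estimation.estimate_generator(counts, mode=mode)
        return CTMCResults(self, counts, generator)


class CTMCResults:
    """Fitted generator, embedded chain, statistics and predictions."""

    def __init__(
        self, model: CTMCModel, counts: estimation.TransitionCounts,
        generator: estimation.GeneratorMatrix,
    ):
        self.model = model
        self.counts = counts
        self.generator = generator
        self.state_space = model.state_space

    @property
    def mode(self) -> str:
        return self.generator.mode

    @property
    def Q(self) -> np.ndarray:
        return self.generator.Q

    def jump_probability_matrix(self, absorbing_self_loop: bool = True) -> pd.DataFrame:
        P = estimation.jump_probability_matrix(
            self.counts, absorbing_self_loop=absorbing_self_loop
        )
        labels = list(self.state_space.states)
        return pd.DataFrame(P, index=labels, columns=labels)

    def transition_time_stats(self) -> pd.DataFrame:
        return estimation.transition_time_stats(self.counts)

    def first_episode_distribution(self, restrict_to=None) -> pd.DataFrame:
        return estimation.first_episode_distribution(
            self.model.trajectories, restrict_to=restrict_to
        )

    def death_attribution(self, absorbing_state: str | None = None, subset=None):
        if absorbing_state is None:
            if len(self.state_space.absorbing) != 1:
                raise ValueError("specify absorbing_state explicitly")
            (absorbing_state,) = self.state_space.absorbing
        return estimation.death_attribution(
            self.counts, absorbing_state=absorbing_state, subset=subset
        )

    # -- prediction ---------------------------------------------------------
    def transition_probability(self, t: float) -> prediction.TransitionProbabilityMatrix:
        return prediction.transition_probability(self.generator, t)

    def progression(
        self,
        start_state: str,
        interval_days: float = prediction.DEFAULT_INTERVAL_DAYS,
        horizon_days: float = prediction.DEFAULT_HORIZON_DAYS,
    ) -> prediction.ProgressionPattern:
        return prediction.progression_series(
            self.generator, start_state, interval_days, horizon_days
        )

    def forecast_state_mix(self, initial_mix, t: float) -> pd.Series:
        mix = prediction.forecast_state_mix(self.generator, initial_mix, t)
        return pd.Series(mix, index=list(self.state_space.states), name=f"mix(t={t})")

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        model = self.model
        lines = []
        w = 72
        lines.append("Continuous-Time Markov Chain Cohort Model".center(w))
        lines.append("=" * w)
        lines.append(f"{'No. patients:':<28}{model.n_patients}")
        lines.append(f"{'No. observed transitions:':<28}{model.n_transitions}")
        lines.append(f"{'No. states:':<28}{len(self.state_space)}")
        lines.append(f"{'Absorbing states:':<28}{', '.join(sorted(self.state_space.absorbing)) or '(none)'}")
        if self.state_space.dropped_states:
            dropped = ", ".join(f"{s} ({c})" for s, c in self.state_space.dropped_states)
            lines.append(f"{'Pruned rare states:':<28}{dropped}")
        lines.append(f"{'Generator estimator:':<28}{self.mode}")
        lines.append("-" * w)
        lines.append("State        Exit rate (/day)   Mean hold (days)   Out-transitions")
        for i, s in enumerate(self.state_space.states):
            rate = self.generator.exit_rates[i]
            hold = f"{1.0 / rate:14.1f}" if rate > 0 else f"{'—':>14}"
            n_out = int(self.counts.N[i].sum())
            tag = " (absorbing)" if self.state_space.is_absorbing(s) else ""
            lines.append(f"{s:<12} {rate:16.6f}  {hold}   {n_out:15d}{tag}")
        lines.append("=" * w)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<CTMCResults: {self.model.n_patients} patients, "
            f"{len(self.state_space)} states, mode={self.mode!r}>"
        )
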