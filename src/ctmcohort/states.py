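"""Construction of Markov-valid patient trajectories from raw episodes.

A Markov chain requires a patient to occupy exactly one state at a time, so
same-day co-occurring episodes (comorbidity/multimorbidity) are mapped to a
single composite state whose name concatenates short component codes in a
fixed order — e.g. congestive heart failure + myocardial infarction on the
same day becomes the state ``CHMI``.  Consecutive repeats of the same state
are merged into one continuous stay (the interim period counts as held time,
not remission), rare states can be pruned, and absorbing states such as
death terminate a trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .episodes import EpisodeTable

logger = logging.getLogger(__name__)

#: canonical ordering of the default 10-state cardiovascular state space
CVD_STATE_ORDER = (
    "MI", "Stroke", "Death", "CHF", "CHMI",
    "CHST", "Angina", "CHANMI", "ANMI", "CHAN",
)


@dataclass(frozen=True)
class CompositeNamingScheme:
    """Deterministic naming of composite multimorbidity states.

    ``component_codes`` maps a raw episode label to its short code;
    composite names concatenate the codes of the co-occurring labels in
    ``component_order`` so the same label set always yields the same name.
    ``single_names`` optionally renames a label when it occurs alone (e.g.
    "Congestive heart failure" -> "CHF").  ``special_states`` are labels,
    typically absorbing ones, that are never composed with anything.
    """

    component_codes: Mapping[str, str]
    component_order: tuple[str, ...]
    special_states: frozenset = frozenset()
    single_names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        codes = list(self.component_codes.values())
        if len(set(codes)) != len(codes):
            raise ValueError("component codes must be unique")
        unknown = set(codes) - set(self.component_order)
        if unknown:
            raise ValueError(f"codes missing from component_order: {sorted(unknown)}")

    def state_name(self, label: str) -> str:
        """Name of the state for a label occurring alone on a day."""
        return self.single_names.get(label, label)

    def compose(self, labels: Iterable[str]) -> str:
        """Canonical state name for a set of same-day episode labels."""
        distinct = sorted(set(labels))
        if not distinct:
            raise ValueError("cannot compose an empty label set")
        special = [s for s in distinct if s in self.special_states]
        if special:
            if len(distinct) > 1:
                logger.warning(
                    "absorbing label %s co-occurring with %s; absorbing state wins",
                    special[0], [s for s in distinct if s not in special],
                )
            return self.state_name(special[0])
        if len(distinct) == 1:
            return self.state_name(distinct[0])
        try:
            codes = {self.component_codes[s] for s in distinct}
        except KeyError as exc:
            raise ValueError(
                f"label {exc.args[0]!r} has no component code; cannot compose {distinct}"
            ) from None
        return "".join(c for c in self.component_order if c in codes)

    def decompose(self, state: str) -> list[str]:
        """Inverse of :meth:`compose`: component labels of a composite state.

        Single (non-composite) states map back to their raw label; states
        that do not parse as a code concatenation are returned unchanged.
        """
        reverse_single = {v: k for k, v in self.single_names.items()}
        if state in reverse_single:
            return [reverse_single[state]]
        reverse_code = {v: k for k, v in self.component_codes.items()}
        remaining, labels = state, []
        for code in self.component_order:
            if remaining.startswith(code):
                labels.append(reverse_code[code])
                remaining = remaining[len(code):]
        if remaining or len(labels) < 2:
            return [state]
        return labels


def cvd_naming_scheme() -> CompositeNamingScheme:
    """The default cardiovascular scheme (CH < AN < MI < ST; Death special)."""
    return CompositeNamingScheme(
        component_codes={
            "Congestive heart failure": "CH",
            "Angina": "AN",
            "Myocardial infarction": "MI",
            "Stroke": "ST",
        },
        component_order=("CH", "AN", "MI", "ST"),
        special_states=frozenset({"Death"}),
        single_names={
            "Congestive heart failure": "CHF",
            "Myocardial infarction": "MI",
            "Angina": "Angina",
            "Stroke": "Stroke",
        },
    )


@dataclass(frozen=True)
class StateSpace:
    """Ordered Markov state set with its absorbing subset."""

    states: tuple[str, ...]
    absorbing: frozenset = frozenset()
    dropped_states: tuple[tuple[str, int], ...] = ()

    def __post_init__(self):
        if len(set(self.states)) != len(self.states):
            raise ValueError("state labels must be unique")
        if not self.absorbing <= set(self.states):
            raise ValueError("absorbing states must be a subset of states")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    def __contains__(self, state: str) -> bool:
        return state in self.states

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(
                f"unknown state {state!r}; valid states: {list(self.states)}"
            ) from None

    def is_absorbing(self, state: str) -> bool:
        return state in self.absorbing


@dataclass
class PatientTrajectory:
    """One patient's post-preprocessing state sequence.

    ``visits`` is an ordered list of (state, entry day) with strictly
    increasing days, no consecutive repeats, and an absorbing state only as
    the final visit.
    """

    patient_id: str
    visits: list[tuple[str, int]]
    covariates: Mapping[str, str] = field(default_factory=dict)

    @property
    def first_state(self) -> str:
        return self.visits[0][0]

    def check(self, absorbing: Iterable[str] = ()) -> None:
        days = [d for _, d in self.visits]
        if days != sorted(set(days)):
            raise ValueError(f"{self.patient_id}: entry days not strictly increasing")
        states = [s for s, _ in self.visits]
        for a, b in zip(states, states[1:]):
            if a == b:
                raise ValueError(f"{self.patient_id}: consecutive repeat of {a!r}")
        absorbing = set(absorbing)
        hit = [i for i, s in enumerate(states) if s in absorbing]
        if hit and hit != [len(states) - 1]:
            raise ValueError(f"{self.patient_id}: absorbing visit not final")


def compose_same_day_states(
    table: EpisodeTable, naming: CompositeNamingScheme
) -> EpisodeTable:
    """Collapse each (patient, day) group of episodes to one composite state.

    Exact duplicate labels on a day collapse to one; a special (absorbing)
    label co-occurring with others wins with a logged warning.  Idempotent.
    """
    df = table.sort().df
    rows = []
    for (pid, day), group in df.groupby(["patient_id", "day"], sort=True):
        state = naming.compose(group["episode"])
        row = {"patient_id": pid, "episode": state, "day": day}
        first = group.iloc[0]
        for label in table.covariate_labels:
            row[label] = first[label]
        rows.append(row)
    out = pd.DataFrame(rows, columns=list(df.columns))
    if len(out) and (out["day"].astype(float) == out["day"].astype(float).round()).all():
        out["day"] = out["day"].astype("int64")
    return EpisodeTable(
        out, source=table.source, covariate_labels=table.covariate_labels
    ).sort()


def merge_consecutive_runs(visits: Sequence[tuple[str, int]]) -> list[tuple[str, int]]:
    """Collapse maximal runs of identical consecutive states to their first visit.

    A repeat of state s after an intervening different state is preserved as a
    genuine re-entry.  Idempotent.
    """
    merged: list[tuple[str, int]] = []
    for state, day in visits:
        if merged and merged[-1][0] == state:
            continue
        merged.append((state, day))
    return merged


def prune_rare_states(
    table: EpisodeTable, min_count: int, policy: str = "drop_records"
) -> tuple[EpisodeTable, StateSpace]:
    """Remove states whose occurrence count falls below ``min_count``.

    Both policies remove the affected records from the table; because
    trajectory construction re-sorts each patient's remaining visits, the
    neighbouring visits become adjacent in either case (``splice`` states
    that intent explicitly).  Returns the pruned table and a draft state
    space (absorbing subset not yet assigned) recording what was dropped.
    """
    if policy not in ("drop_records", "splice"):
        raise ValueError(f"unknown pruning policy {policy!r}")
    counts = table.df["episode"].value_counts()
    dropped = tuple(
        (label, int(counts[label]))
        for label in sorted(counts.index[counts < min_count])
    )
    surviving = [label for label in counts.index if counts[label] >= min_count]
    if not surviving:
        raise ValueError("pruning removed every state; lower min_count")
    if dropped:
        logger.info("pruned %d rare state(s): %s", len(dropped), dropped)
        keep = table.df["episode"].isin(surviving)
        df = table.df.loc[keep].reset_index(drop=True)
        table = EpisodeTable(df, source=table.source, covariate_labels=table.covariate_labels)
    draft = StateSpace(states=tuple(sorted(surviving)), dropped_states=dropped)
    return table.sort(), draft


def _ordered_states(
    observed: Iterable[str], preferred_order: Sequence[str] | None
) -> tuple[str, ...]:
    observed = set(observed)
    ordered: list[str] = []
    if preferred_order:
        ordered = [s for s in preferred_order if s in observed]
    ordered += sorted(observed - set(ordered))
    return tuple(ordered)


def build_trajectories(
    table: EpisodeTable,
    naming: CompositeNamingScheme | None = None,
    min_count: int = 0,
    absorbing_labels: Iterable[str] = ("Death",),
    state_order: Sequence[str] | None = CVD_STATE_ORDER,
    prune_policy: str = "drop_records",
) -> tuple[list[PatientTrajectory], StateSpace]:
    """Full preprocessing pipeline: compose → prune → sort → truncate → merge.

    Episodes recorded after a patient's first absorbing visit are discarded
    with a warning (registry noise), so each trajectory holds at most one
    absorbing visit, in final position.  Returns trajectories ordered by
    patient id plus the resulting :class:`StateSpace`.
    """
    if naming is None:
        naming = cvd_naming_scheme()
    absorbing_labels = {naming.state_name(a) for a in absorbing_labels}
    composed = compose_same_day_states(table, naming)
    pruned, draft = prune_rare_states(composed, min_count, policy=prune_policy)
    trajectories: list[PatientTrajectory] = []
    observed: set[str] = set()
    df = pruned.df
    for pid, group in df.groupby("patient_id", sort=True):
        days = group["day"]
        if (days.astype(float) == days.astype(float).round()).all():
            days = days.astype(int)
        visits = list(zip(group["episode"], days))
        cut = next(
            (k + 1 for k, (s, _) in enumerate(visits) if s in absorbing_labels),
            len(visits),
        )
        if cut < len(visits):
            logger.warning(
                "patient %s: discarding %d episode(s) after absorbing state",
                pid, len(visits) - cut,
            )
        visits = merge_consecutive_runs(visits[:cut])
        if not visits:
            continue
        covariates = {
            label: group.iloc[0][label] for label in pruned.covariate_labels
        }
        traj = PatientTrajectory(patient_id=pid, visits=visits, covariates=covariates)
        observed.update(s for s, _ in visits)
        trajectories.append(traj)
    if not trajectories:
        raise ValueError("no trajectories left after preprocessing")
    space = StateSpace(
        states=_ordered_states(observed, state_order),
        absorbing=frozenset(observed & absorbing_labels),
        dropped_states=draft.dropped_states,
    )
    for traj in trajectories:
        traj.check(absorbing=space.absorbing)
    return trajectories, space
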