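"""Reading, validating and writing episodic cohort records.

The input format is deliberately minimal: one row per disease episode with a
patient identifier, an episode (state) label, and the episode time expressed
as whole days since the patient's baseline date.  Any additional columns are
carried along as per-record covariates (for example ``sex``) so that cohorts
can later be stratified.  Times are baseline-relative integers by design;
calendar-date parsing is out of scope.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: names of the three mandatory columns, in canonical order
REQUIRED_COLUMNS = ("patient_id", "episode", "day")


@dataclass(frozen=True)
class EpisodeRecord:
    """A single disease episode: who, what, and when (days from baseline)."""

    patient_id: str
    episode: str
    day: int
    covariates: Mapping[str, str] = field(default_factory=dict)


@dataclass
class EpisodeTable:
    """An ordered collection of episode records backed by a DataFrame.

    The frame always carries the columns ``patient_id``, ``episode`` and
    ``day`` (int64), followed by ``covariate_labels`` in order.  Canonical
    order is (patient_id, day, episode); :meth:`sort` is idempotent.
    """

    df: pd.DataFrame
    source: str = ""
    covariate_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.df.columns:
                raise ValueError(f"episode table is missing required column {col!r}")
        for label in self.covariate_labels:
            if label not in self.df.columns:
                raise ValueError(f"covariate column {label!r} absent from frame")
        ordered = list(REQUIRED_COLUMNS) + list(self.covariate_labels)
        self.df = self.df.loc[:, ordered]

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_patients(self) -> int:
        return self.df["patient_id"].nunique()

    @property
    def records(self) -> list[EpisodeRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            cov = {c: getattr(row, c) for c in self.covariate_labels}
            out.append(EpisodeRecord(row.patient_id, row.episode, int(row.day), cov))
        return out

    def sort(self) -> "EpisodeTable":
        """Return the table in canonical (patient_id, day, episode) order."""
        df = self.df.sort_values(
            ["patient_id", "day", "episode"], kind="mergesort"
        ).reset_index(drop=True)
        return EpisodeTable(df, source=self.source, covariate_labels=self.covariate_labels)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, int]] | Iterable[EpisodeRecord],
        source: str = "",
        covariate_labels: Sequence[str] = (),
    ) -> "EpisodeTable":
        rows = []
        for rec in records:
            if isinstance(rec, EpisodeRecord):
                row = {"patient_id": rec.patient_id, "episode": rec.episode, "day": rec.day}
                row.update(rec.covariates)
            else:
                pid, episode, day = rec
                row = {"patient_id": pid, "episode": episode, "day": day}
            rows.append(row)
        labels = tuple(covariate_labels)
        if rows:
            df = pd.DataFrame(rows)
        else:
            df = pd.DataFrame(columns=list(REQUIRED_COLUMNS) + list(labels))
        for label in labels:
            if label not in df.columns:
                df[label] = ""
        if len(df) and (df["day"].astype(float) == df["day"].astype(float).round()).all():
            df["day"] = df["day"].astype("int64")
        df["patient_id"] = df["patient_id"].astype(str)
        df["episode"] = df["episode"].astype(str)
        return cls(df, source=source, covariate_labels=labels)


@dataclass
class ValidationReport:
    """Row-level data-quality findings; the table is accepted iff no errors."""

    n_records: int
    n_patients: int
    errors: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[tuple[int, str]] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return not self.errors


def _coerce_days(raw: pd.Series) -> pd.Series:
    """Parse a string day column into nonnegative int64, failing loudly."""
    numeric = pd.to_numeric(raw, errors="coerce")
    for idx, value in numeric.items():
        if pd.isna(value):
            raise ValueError(f"row {idx}: unparseable day field {raw[idx]!r}")
        if float(value) != int(value):
            raise ValueError(f"row {idx}: day must be a whole number of days, got {raw[idx]!r}")
        if value < 0:
            raise ValueError(f"row {idx}: day must be nonnegative, got {raw[idx]!r}")
    return numeric.astype("int64")


def read_episodes(
    path_or_stream,
    delimiter: str = ",",
    has_header: bool = True,
    columns: Mapping[str, str | int] | None = None,
    source_name: str | None = None,
) -> EpisodeTable:
    """Read a delimited episode file into a canonical-ordered :class:`EpisodeTable`.

    Parameters
    ----------
    path_or_stream
        File path or readable text stream.
    delimiter
        Field delimiter; comma by default, ``"\\t"`` selects TSV.
    has_header
        Whether the first line names the columns.
    columns
        Optional mapping from the required field names (``patient_id``,
        ``episode``, ``day``) to the column names (with a header) or integer
        positions (without) that hold them.  By default the required fields
        are looked up by name when a header is present, else taken as the
        first three columns.

    Extra columns become covariates.  Duplicate rows are preserved;
    collapsing same-day duplicates is a state-construction concern.
    """
    if source_name is None:
        source_name = getattr(path_or_stream, "name", str(path_or_stream))
    try:
        df = pd.read_csv(
            path_or_stream,
            sep=delimiter,
            header=0 if has_header else None,
            dtype=str,
            skipinitialspace=True,
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{source_name}: empty episode file") from None
    if df.empty and has_header and df.shape[1] == 0:
        raise ValueError(f"{source_name}: empty episode file")

    if not has_header:
        df.columns = [f"c{i}" for i in range(df.shape[1])]
        mapping = dict(columns or {"patient_id": 0, "episode": 1, "day": 2})
        mapping = {k: (f"c{v}" if isinstance(v, int) else v) for k, v in mapping.items()}
    else:
        mapping = {k: k for k in REQUIRED_COLUMNS}
        if columns:
            for k, v in columns.items():
                mapping[k] = df.columns[v] if isinstance(v, int) else v

    for field_name in REQUIRED_COLUMNS:
        col = mapping.get(field_name)
        if col is None or col not in df.columns:
            raise ValueError(f"{source_name}: missing required column for {field_name!r}")

    renamed = df.rename(columns={mapping[k]: k for k in REQUIRED_COLUMNS})
    covariate_labels = tuple(c for c in renamed.columns if c not in REQUIRED_COLUMNS)
    renamed["day"] = _coerce_days(renamed["day"])
    renamed["episode"] = renamed["episode"].astype(str).str.strip()
    renamed["patient_id"] = renamed["patient_id"].astype(str).str.strip()
    table = EpisodeTable(renamed, source=source_name, covariate_labels=covariate_labels)
    return table.sort()


def write_episodes(table: EpisodeTable, path_or_stream, delimiter: str = ",") -> None:
    """Write a table in canonical order; re-reading reproduces it exactly."""
    out = table.sort()
    out.df.to_csv(path_or_stream, sep=delimiter, index=False)


def episodes_to_string(table: EpisodeTable, delimiter: str = ",") -> str:
    buf = io.StringIO()
    write_episodes(table, buf, delimiter=delimiter)
    return buf.getvalue()


def validate_episodes(
    table: EpisodeTable, absorbing_labels: Iterable[str] = ("Death",)
) -> ValidationReport:
    """Report row-level problems without raising.

    Errors (reject the table): blank episode labels, missing/negative or
    fractional days.  Warnings: episodes recorded after a patient has already
    entered an absorbing state such as death — downstream trajectory
    construction discards these.
    """
    absorbing = set(absorbing_labels)
    report = ValidationReport(n_records=table.n_records, n_patients=table.n_patients)
    df = table.sort().df
    for idx, row in enumerate(df.itertuples(index=False)):
        label = str(row.episode).strip()
        if not label:
            report.errors.append((idx, "blank episode label"))
        day = row.day
        if pd.isna(day):
            report.errors.append((idx, "missing day"))
        elif float(day) != int(day):
            report.errors.append((idx, f"fractional day {day!r}"))
        elif int(day) < 0:
            report.errors.append((idx, f"negative day {day!r}"))
    dead_since: dict[str, int] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        pid = row.patient_id
        if pid in dead_since:
            report.warnings.append(
                (idx, f"episode {row.episode!r} after absorbing state for patient {pid}")
            )
        elif row.episode in absorbing:
            dead_since[pid] = idx
    return report
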