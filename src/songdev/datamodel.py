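"""Data types and I/O for longitudinal per-syllable feature tables.

A song ontogeny is a year-scale record of every syllable a bird produced
across three experimental phases: a first hormone treatment (``T1_PLUS``,
song develops and crystallizes), hormone withdrawal (``T1_MINUS``, the bird
falls silent), and a second treatment (``T2_PLUS``, song re-develops).
Each syllable carries its timing within a song bout and eight acoustic
features measured by an upstream extractor:

======  ===============================  =================
short   column                           units
======  ===============================  =================
d       duration_ms                      ms, > 0
i       pause_ms                         ms, >= 0; absent for bout-final
SR      syllable_rate_hz                 Hz, = 1000/(d+i); derived
FM      fm                               extractor-native
AM      am                               extractor-native
BW      bandwidth_hz                     Hz, >= 0
MF      mean_frequency_hz                Hz, > 0
E       wiener_entropy                   log scale, <= 0
======  ===============================  =================

Records live in a pandas DataFrame (one row per syllable) wrapped together
with a :class:`PhaseCalendar` in an :class:`OntogenyDataset`.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "PhaseWindow",
    "PhaseCalendar",
    "OntogenyDataset",
    "SchemaError",
    "EmptyDatasetError",
    "ValidationError",
    "FEATURES",
    "FEATURE_COLUMNS",
    "TABLE_COLUMNS",
    "read_feature_table",
    "read_sql_dump",
    "write_feature_table",
    "assign_phase_days",
]

#: short feature code -> table column name
FEATURES: dict[str, str] = {
    "d": "duration_ms",
    "i": "pause_ms",
    "SR": "syllable_rate_hz",
    "FM": "fm",
    "AM": "am",
    "BW": "bandwidth_hz",
    "MF": "mean_frequency_hz",
    "E": "wiener_entropy",
}

FEATURE_COLUMNS = tuple(FEATURES.values())

#: native delimited-text schema, in column order
TABLE_COLUMNS = (
    "bird_id",
    "phase",
    "experiment_day",
    "phase_day",
    "bout_id",
    "bout_position",
    "syllable_type",
    "onset_ms",
    "duration_ms",
    "pause_ms",
    "syllable_rate_hz",
    "fm",
    "am",
    "bandwidth_hz",
    "mean_frequency_hz",
    "wiener_entropy",
)

_NUMERIC_COLUMNS = (
    "experiment_day",
    "phase_day",
    "bout_position",
    "onset_ms",
) + FEATURE_COLUMNS

#: sentinel label for syllables without a type assignment
UNTYPED = "untyped"


class SchemaError(ValueError):
    """A required column is missing or unusable."""


class EmptyDatasetError(ValueError):
    """The table contains no data rows."""


class ValidationError(ValueError):
    """Rows violate a dataset invariant."""


class Phase(str, Enum):
    """Experimental phases, in chronological order."""

    T1_PLUS = "T1_PLUS"
    T1_MINUS = "T1_MINUS"
    T2_PLUS = "T2_PLUS"

    @property
    def order(self) -> int:
        return ("T1_PLUS", "T1_MINUS", "T2_PLUS").index(self.value)


@dataclass(frozen=True)
class PhaseWindow:
    """Extent of one phase on the experiment-day axis.

    ``start_day`` is the first day of the phase (for treatment phases, the
    implant day; for withdrawal, the removal day).  ``first_song_day`` is
    the first day song was detected in the phase (None while silent).
    ``implant_day`` defaults to ``start_day`` and anchors implant-relative
    day counting for stabilization reporting.
    """

    start_day: int
    end_day: int
    first_song_day: int | None = None
    implant_day: int | None = None

    def __post_init__(self):
        if self.end_day < self.start_day:
            raise ValueError("phase end_day precedes start_day")
        if self.implant_day is None:
            object.__setattr__(self, "implant_day", self.start_day)


@dataclass(frozen=True)
class PhaseCalendar:
    """Per-bird phase bookkeeping (ordered, non-overlapping windows)."""

    bird_id: str
    windows: dict[Phase, PhaseWindow]

    def __post_init__(self):
        ordered = sorted(self.windows, key=lambda p: p.order)
        prev_end = None
        for ph in ordered:
            w = self.windows[ph]
            if prev_end is not None and w.start_day <= prev_end:
                raise ValueError(f"phase windows overlap at {ph.value}")
            prev_end = w.end_day

    def window(self, phase: Phase) -> PhaseWindow:
        return self.windows[Phase(phase)]


@dataclass
class OntogenyDataset:
    """A bird's full syllable record plus its phase calendar.

    ``records`` is a DataFrame with the columns of :data:`TABLE_COLUMNS`
    (plus optional derived columns), sorted by (experiment_day, onset_ms).
    """

    bird_id: str
    calendar: PhaseCalendar
    records: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.records)

    def singing_days(self, phase: Phase | None = None) -> np.ndarray:
        """Sorted experiment days with at least one recorded syllable."""
        rec = self.records
        if phase is not None:
            rec = rec[rec["phase"] == Phase(phase).value]
        return np.sort(rec["experiment_day"].unique())


# ---------------------------------------------------------------------------
# validation

def _validate_records(df: pd.DataFrame, sr_rtol: float = 0.01) -> pd.DataFrame:
    """Check invariants, fill derived SR, and reject bad rows.

    Returns the validated frame; raises :class:`ValidationError` for hard
    violations and warns (listing rows) when a stored syllable rate
    disagrees with 1000/(d+i) by more than ``sr_rtol``.
    """
    bad = df.index[~(df["duration_ms"] > 0)]
    if len(bad):
        raise ValidationError(f"non-positive duration_ms at rows {list(bad[:10])}")
    has_i = df["pause_ms"].notna()
    bad = df.index[has_i & (df["pause_ms"] < 0)]
    if len(bad):
        raise ValidationError(f"negative pause_ms at rows {list(bad[:10])}")
    bad = df.index[df["bout_position"] < 0]
    if len(bad):
        raise ValidationError(f"negative bout_position at rows {list(bad[:10])}")
    bad = df.index[df["phase_day"].notna() & (df["phase_day"] < 0)]
    if len(bad):
        raise ValidationError(f"negative phase_day at rows {list(bad[:10])}")

    # bout_position strictly increasing within a bout
    pos = df.groupby(["bird_id", "bout_id"], sort=False)["bout_position"].diff()
    if (pos.dropna() <= 0).any():
        raise ValidationError("bout_position not strictly increasing within a bout")

    derived = 1000.0 / (df["duration_ms"] + df["pause_ms"])
    stored = df["syllable_rate_hz"]
    check = has_i & stored.notna()
    off = df.index[check & (np.abs(stored - derived) > sr_rtol * derived)]
    if len(off):
        warnings.warn(
            "syllable_rate_hz disagrees with 1000/(duration_ms+pause_ms) "
            f"by >{sr_rtol:.0%} at rows {list(off[:20])}",
            stacklevel=3,
        )
    df = df.copy()
    # derived SR: present iff pause present
    df["syllable_rate_hz"] = np.where(has_i, derived, np.nan)
    df.loc[~has_i, "pause_ms"] = np.nan
    df = df.sort_values(["experiment_day", "onset_ms"], kind="stable")
    return df.reset_index(drop=True)


def _infer_calendar(df: pd.DataFrame, bird_id: str) -> PhaseCalendar:
    windows = {}
    for ph in Phase:
        sub = df[df["phase"] == ph.value]
        if len(sub):
            days = sub["experiment_day"]
            windows[ph] = PhaseWindow(
                start_day=int(days.min()),
                end_day=int(days.max()),
                first_song_day=int(days.min()),
            )
    return PhaseCalendar(bird_id=bird_id, windows=windows)


# ---------------------------------------------------------------------------
# readers / writers

def _frame_to_dataset(
    df: pd.DataFrame, calendar: PhaseCalendar | None
) -> OntogenyDataset:
    birds = df["bird_id"].unique()
    if len(birds) != 1:
        raise ValidationError(
            f"one dataset holds one bird; table names {len(birds)} bird_ids"
        )
    bird = str(birds[0])
    df = _validate_records(df)
    cal = calendar if calendar is not None else _infer_calendar(df, bird)
    bad_phase = set(df["phase"].unique()) - {p.value for p in Phase}
    if bad_phase:
        raise ValidationError(f"unknown phase labels {sorted(bad_phase)}")
    return OntogenyDataset(bird_id=bird, calendar=cal, records=df)


def read_feature_table(
    path: str | Path,
    dialect: str = "csv",
    calendar: PhaseCalendar | None = None,
) -> OntogenyDataset:
    """Read a delimited per-syllable feature table.

    Parameters
    ----------
    path
        CSV (``dialect="csv"``) or TSV (``"tsv"``) file with a header row
        naming the columns of :data:`TABLE_COLUMNS`.  Empty fields mean
        "absent".
    calendar
        Optional explicit phase calendar (with true implant days).  When
        omitted, phase windows are inferred from the observed records, so
        implant-relative days coincide with first-observed-song days.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    try:
        df = pd.read_csv(path, sep=sep, dtype={"bird_id": str, "bout_id": str,
                                               "syllable_type": str})
    except pd.errors.EmptyDataError:
        raise EmptyDatasetError(f"{path} has no content") from None
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyDatasetError(f"{path} has a header but no data rows")
    for col in _NUMERIC_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValidationError(
                f"unparseable numeric in column {col!r} near line {line}: {exc}"
            ) from None
    for col in ("experiment_day", "bout_position"):
        df[col] = df[col].astype(np.int64)
    df["syllable_type"] = df["syllable_type"].fillna(UNTYPED)
    return _frame_to_dataset(df, calendar)


_INSERT_RE = re.compile(
    r"INSERT\s+INTO\s+`?(\w+)`?\s*(?:\(([^)]*)\))?\s*VALUES\s*(.*?);",
    re.IGNORECASE | re.DOTALL,
)
_TUPLE_RE = re.compile(r"\(((?:[^()']|'(?:[^'\\]|\\.)*')*)\)")


def read_sql_dump(
    path: str | Path,
    column_map: dict[str, str],
    calendar: PhaseCalendar | None = None,
) -> OntogenyDataset:
    """Ingest an SQL dump of per-syllable features via its INSERT tuples.

    ``column_map`` maps dump column names to the native schema of
    :data:`TABLE_COLUMNS` (the dump schema is not standardized, so the
    mapping is required).  Unmapped native columns must be derivable
    (``phase_day`` / ``syllable_rate_hz``) or are filled with defaults.
    """
    text = Path(path).read_text()
    rows: list[list[str]] = []
    columns: list[str] | None = None
    for m in _INSERT_RE.finditer(text):
        cols = m.group(2)
        if cols:
            columns = [c.strip(" `\n") for c in cols.split(",")]
        for tup in _TUPLE_RE.finditer(m.group(3)):
            fields = next(
                iter(pd.read_csv(io.StringIO(tup.group(1)), header=None,
                                 quotechar="'", skipinitialspace=True)
                     .astype(object).values.tolist())
            )
            rows.append(fields)
    if not rows:
        raise EmptyDatasetError(f"no INSERT tuples found in {path}")
    if columns is None:
        raise SchemaError("SQL dump lists no column names; cannot map fields")
    df = pd.DataFrame(rows, columns=columns)
    df = df.rename(columns=column_map)
    missing = [c for c in column_map.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"column_map targets absent from dump: {missing}")
    for col in TABLE_COLUMNS:
        if col not in df.columns:
            if col == "phase_day":
                df[col] = np.nan
            elif col == "syllable_rate_hz":
                df[col] = np.nan
            elif col == "syllable_type":
                df[col] = UNTYPED
            else:
                raise SchemaError(f"missing required column(s): {col}")
    df = df[list(TABLE_COLUMNS)]
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("experiment_day", "bout_position"):
        df[col] = df[col].astype(np.int64)
    for col in ("bird_id", "phase", "bout_id", "syllable_type"):
        df[col] = df[col].astype(str).str.strip("'\"")
    return _frame_to_dataset(df, calendar)


def write_feature_table(
    dataset: OntogenyDataset, path: str | Path, dialect: str = "csv"
) -> Path:
    """Write a dataset losslessly to delimited text (empty string = absent)."""
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    out = dataset.records.reindex(columns=list(TABLE_COLUMNS))
    out.to_csv(path, sep=sep, index=False, na_rep="")
    return path


def assign_phase_days(dataset: OntogenyDataset) -> OntogenyDataset:
    """Fill per-record day indices from the calendar.

    Adds/overwrites two columns: ``phase_day`` (days since the phase's
    first detected song — the cross-bird alignment axis) and
    ``treatment_day`` (days since the phase's implant — the axis on which
    stabilization durations are reported).
    """
    df = dataset.records.copy()
    phase_day = np.full(len(df), np.nan)
    treat_day = np.full(len(df), np.nan)
    for ph in Phase:
        mask = (df["phase"] == ph.value).to_numpy()
        if not mask.any():
            continue
        w = dataset.calendar.window(ph)
        days = df.loc[mask, "experiment_day"].to_numpy()
        if (days < w.start_day).any():
            raise ValidationError(
                f"records dated before the {ph.value} phase start ({w.start_day})"
            )
        if w.first_song_day is not None:
            phase_day[mask] = days - w.first_song_day
        treat_day[mask] = days - w.implant_day
    df["phase_day"] = phase_day
    df["treatment_day"] = treat_day
    return replace(dataset, records=df)
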