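"""Call-table data model and CSV I/O.

The call table is the exchange format shared by every analysis stage: one
row per vocalization, identified by the sequence (bout/trial) it belongs
to, the individual (bird, recording, or human participant) that produced
it, and its 1-based ordinal position within the sequence.  Durations are
stored in seconds; the log transform used by the models is applied
downstream, never at I/O time.

Required columns: ``context``, ``individual_id``, ``sequence_id``,
``position``, ``duration_s``.  Optional columns: ``cue_number``,
``correct``, ``onset_s``, ``offset_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("context", "individual_id", "sequence_id", "position", "duration_s")
OPTIONAL_COLUMNS = ("cue_number", "correct", "onset_s", "offset_s")
ALL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS

#: tolerance for duration_s == offset_s - onset_s consistency (seconds)
ONSET_OFFSET_TOL = 1e-6


class CallTableError(ValueError):
    """Base class for call-table problems."""


class FormatError(CallTableError):
    """The file/frame does not have the canonical call-table shape."""


class ValidationError(CallTableError):
    """Rows violate call-table invariants.

    ``rows`` holds 0-based positional indices of offending rows (or the
    offending sequence ids, for sequence-level invariants).
    """

    def __init__(self, message: str, rows: Iterable | None = None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class EmptyTableError(CallTableError):
    """A filter left no records; raised instead of returning a 0-row table."""


@dataclass(frozen=True)
class CallRecord:
    """One vocalization."""

    context: str
    individual_id: str
    sequence_id: str
    position: int
    duration_s: float
    cue_number: int | None = None
    correct: bool | None = None
    onset_s: float | None = None
    offset_s: float | None = None


@dataclass
class CallTable:
    """A validated, ordered collection of vocalizations.

    Wraps a :class:`pandas.DataFrame` with the canonical columns.  On
    construction the invariants are checked:

    * ``duration_s > 0``; where onset/offset are present,
      ``duration_s == offset_s - onset_s`` within 1e-6 s;
    * ``position >= 1`` and, within each sequence, positions are exactly
      ``1..n`` with no gaps or duplicates;
    * each ``sequence_id`` maps to exactly one ``individual_id`` and one
      ``context``.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.df = _canonicalize(self.df)
        _validate(self.df)

    # -- derived quantities -------------------------------------------------

    @property
    def n_calls(self) -> int:
        return len(self.df)

    @property
    def n_sequences(self) -> int:
        return self.df["sequence_id"].nunique()

    @property
    def n_individuals(self) -> int:
        return self.df["individual_id"].nunique()

    def sequence_sizes(self) -> pd.Series:
        """Number of calls per sequence, indexed by sequence_id."""
        return self.df.groupby("sequence_id", sort=False).size()

    def with_sizes(self) -> pd.DataFrame:
        """The frame plus a ``seq_size`` column (size of the row's sequence)."""
        out = self.df.copy()
        out["seq_size"] = out.groupby("sequence_id", sort=False)["position"].transform("size")
        return out

    def records(self) -> list[CallRecord]:
        recs = []
        for row in self.df.itertuples(index=False):
            recs.append(
                CallRecord(
                    context=row.context,
                    individual_id=row.individual_id,
                    sequence_id=row.sequence_id,
                    position=int(row.position),
                    duration_s=float(row.duration_s),
                    cue_number=None if pd.isna(row.cue_number) else int(row.cue_number),
                    correct=None if pd.isna(row.correct) else bool(row.correct),
                    onset_s=None if pd.isna(row.onset_s) else float(row.onset_s),
                    offset_s=None if pd.isna(row.offset_s) else float(row.offset_s),
                )
            )
        return recs


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"call table is missing required columns: {missing}")
    df = df.copy().reset_index(drop=True)
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[list(ALL_COLUMNS)]
    df["context"] = df["context"].astype(str)
    df["individual_id"] = df["individual_id"].astype(str)
    df["sequence_id"] = df["sequence_id"].astype(str)
    try:
        df["position"] = df["position"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"position column is not integer-valued: {exc}") from exc
    df["duration_s"] = df["duration_s"].astype(float)
    df["cue_number"] = df["cue_number"].astype("Int64")
    df["correct"] = df["correct"].astype("boolean")
    df["onset_s"] = df["onset_s"].astype("Float64")
    df["offset_s"] = df["offset_s"].astype("Float64")
    return df


def _validate(df: pd.DataFrame) -> None:
    bad = df.index[~(df["duration_s"] > 0)].tolist()
    if bad:
        raise ValidationError(f"non-positive duration_s at rows {bad}", rows=bad)
    bad = df.index[df["position"] < 1].tolist()
    if bad:
        raise ValidationError(f"position < 1 at rows {bad}", rows=bad)

    has_bounds = df["onset_s"].notna() & df["offset_s"].notna()
    if has_bounds.any():
        sub = df.loc[has_bounds]
        mismatch = (sub["offset_s"] - sub["onset_s"] - sub["duration_s"]).abs() > ONSET_OFFSET_TOL
        bad = sub.index[mismatch.to_numpy(dtype=bool)].tolist()
        if bad:
            raise ValidationError(
                f"duration_s != offset_s - onset_s (tol {ONSET_OFFSET_TOL}) at rows {bad}",
                rows=bad,
            )
    half = df["onset_s"].notna() ^ df["offset_s"].notna()
    if half.any():
        bad = df.index[half].tolist()
        raise ValidationError(f"onset_s/offset_s present without partner at rows {bad}", rows=bad)

    by_seq = df[["sequence_id", "position"]].sort_values(
        ["sequence_id", "position"], kind="stable"
    )
    expected = by_seq.groupby("sequence_id", sort=False).cumcount() + 1
    mismatch = by_seq["position"].to_numpy() != expected.to_numpy()
    bad_seqs = by_seq.loc[mismatch, "sequence_id"].unique().tolist()
    if bad_seqs:
        raise ValidationError(
            f"sequences with non-contiguous or duplicated positions: {bad_seqs}",
            rows=bad_seqs,
        )

    multi = df.groupby("sequence_id", sort=False).agg(
        n_ind=("individual_id", "nunique"), n_ctx=("context", "nunique")
    )
    bad_seqs = multi.index[(multi["n_ind"] > 1) | (multi["n_ctx"] > 1)].tolist()
    if bad_seqs:
        raise ValidationError(
            f"sequences mapping to multiple individuals/contexts: {bad_seqs}",
            rows=bad_seqs,
        )


# -- I/O -------------------------------------------------------------------


def read_call_table(path: str | Path, **csv_options) -> CallTable:
    """Read a call table from CSV (UTF-8, comma-separated, header required)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, **csv_options)
    return CallTable(df)


def write_call_table(table: CallTable, path: str | Path) -> None:
    """Write a call table as canonical CSV (round-trips bit-exactly)."""
    table.df.to_csv(path, index=False)


def table_from_records(records: Iterable[CallRecord]) -> CallTable:
    return CallTable(pd.DataFrame([r.__dict__ for r in records]))


# -- filtering and summaries -----------------------------------------------


def filter_table(
    table: CallTable,
    context: str | None = None,
    exclude_singles: bool = False,
    correct_only: bool = False,
) -> CallTable:
    """Subset a call table.

    ``exclude_singles`` drops every sequence with a single call.  Error
    trials are kept by default (the analyses use all trials); pass
    ``correct_only=True`` to keep only ``correct == True`` rows.

    Raises :class:`EmptyTableError` if nothing survives.
    """
    df = table.df
    if context is not None:
        df = df[df["context"] == context]
    if correct_only:
        df = df[df["correct"].fillna(False).to_numpy(dtype=bool)]
    if exclude_singles and len(df):
        sizes = df.groupby("sequence_id", sort=False)["position"].transform("size")
        df = df[sizes >= 2]
    if df.empty:
        raise EmptyTableError(
            f"no records left after filtering (context={context!r}, "
            f"exclude_singles={exclude_singles}, correct_only={correct_only})"
        )
    return CallTable(df.reset_index(drop=True))


def summarize(table: CallTable) -> dict:
    """Counts of vocalizations, sequences and individuals, with a
    per-individual breakdown.  Totals are exact group counts."""
    df = table.df
    per_ind = (
        df.groupby("individual_id", sort=True)
        .agg(n_calls=("duration_s", "size"), n_sequences=("sequence_id", "nunique"))
        .reset_index()
    )
    return {
        "n_calls": int(len(df)),
        "n_sequences": int(df["sequence_id"].nunique()),
        "n_individuals": int(df["individual_id"].nunique()),
        "contexts": sorted(df["context"].unique().tolist()),
        "per_individual": {
            row.individual_id: {
                "n_calls": int(row.n_calls),
                "n_sequences": int(row.n_sequences),
            }
            for row in per_ind.itertuples(index=False)
        },
    }
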