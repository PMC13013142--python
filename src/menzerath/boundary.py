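"""Boundary-call statistics: first/last correlations and final lengthening.

Two complementary views of how sequence edges behave:

* Pearson correlations between sequence size and the duration of the
  first call, and between size and the duration of the last call — one
  point per sequence.  For single-call sequences the lone call is both
  first and last; they are included by default.
* The final-lengthening test: within each sequence, durations are
  divided by the sequence's mean duration; the relative duration of the
  final call is compared with the mean relative duration of the
  non-final calls by a paired t-test across sequences (so the test is
  invariant to global rescaling of durations).  Single-call sequences
  have no non-final partner and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import CallTable


@dataclass
class BoundaryResult:
    r_first: float
    p_first: float
    r_last: float
    p_last: float
    n_sequences_used: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class FinalLengtheningResult:
    mean_relative_final: float
    mean_relative_nonfinal: float
    t_statistic: float
    df: int
    p_value: float
    n_sequences: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


class DegenerateStatisticError(ValueError):
    """A statistic is undefined on this input (e.g. zero variance)."""


def _per_sequence(table: CallTable):
    df = table.df.sort_values(["sequence_id", "position"], kind="stable")
    grp = df.groupby("sequence_id", sort=False)["duration_s"]
    sizes = grp.size().to_numpy(dtype=float)
    first = grp.first().to_numpy()
    last = grp.last().to_numpy()
    return sizes, first, last


def first_last_correlation(table: CallTable, include_singles: bool = True) -> BoundaryResult:
    """Pearson r/p of first- and last-call duration against sequence size.

    One (duration, size) point per sequence.  ``include_singles=False``
    drops size-1 sequences from both correlations.
    """
    sizes, first, last = _per_sequence(table)
    if not include_singles:
        keep = sizes >= 2
        sizes, first, last = sizes[keep], first[keep], last[keep]
    if len(sizes) < 3 or np.unique(sizes).size < 2:
        raise DegenerateStatisticError("need >= 3 sequences with >= 2 distinct sizes")
    if np.ptp(first) == 0 or np.ptp(last) == 0:
        raise DegenerateStatisticError("zero variance in first- or last-call durations; correlation undefined")
    r_first, p_first = stats.pearsonr(first, sizes)
    r_last, p_last = stats.pearsonr(last, sizes)
    return BoundaryResult(
        r_first=float(r_first), p_first=float(p_first),
        r_last=float(r_last), p_last=float(p_last),
        n_sequences_used=len(sizes),
    )


def final_lengthening_test(table: CallTable) -> FinalLengtheningResult:
    """Paired t-test of relative final vs mean relative non-final duration.

    Per multi-call sequence: relative duration = duration / sequence mean;
    the pair is (relative duration of the last call, mean relative
    duration of the other calls).  df = number of sequences - 1.  If every
    paired difference is exactly zero the result is t = 0, p = 1.
    """
    df = table.df.sort_values(["sequence_id", "position"], kind="stable")
    sizes = df.groupby("sequence_id", sort=False)["position"].transform("size")
    multi = df[sizes >= 2]
    if multi["sequence_id"].nunique() < 2:
        raise DegenerateStatisticError("need >= 2 sequences with >= 2 calls")

    rel = multi["duration_s"] / multi.groupby("sequence_id", sort=False)["duration_s"].transform("mean")
    is_final = multi["position"] == multi.groupby("sequence_id", sort=False)["position"].transform("max")
    finals = rel[is_final].groupby(multi.loc[is_final, "sequence_id"], sort=False).first()
    nonfinals = rel[~is_final].groupby(multi.loc[~is_final, "sequence_id"], sort=False).mean()
    finals, nonfinals = finals.align(nonfinals, join="inner")
    diffs = (finals - nonfinals).to_numpy()
    n = diffs.size

    if np.allclose(diffs, 0.0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(finals.to_numpy(), nonfinals.to_numpy())
    return FinalLengtheningResult(
        mean_relative_final=float(finals.mean()),
        mean_relative_nonfinal=float(nonfinals.mean()),
        t_statistic=float(t_stat),
        df=n - 1,
        p_value=float(p),
        n_sequences=n,
    )
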