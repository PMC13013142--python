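"""Monte-Carlo null models for the compression and position slopes.

Two chance models bracket the observed slopes:

* **shuffle** — permute call durations among all calls of the same
  individual, leaving the sequence/position scaffold untouched.  Destroys
  any duration-size association, so the null slopes center on zero.
* **production_constraint** — rebuild every sequence by sampling call
  durations (with replacement) from the individual's pooled distribution
  until the cumulative duration strictly exceeds the real sequence's
  total; if the overshoot exceeds half the last sampled call, that call
  is removed.  The pseudo-sequences match the real total-duration
  distribution while their sizes float, so a negative slope under this
  null reflects duration-matching alone.

Each iteration refits the identical model specification used for the
observed fit.  Empirical p-values use the (r+1)/(n+1) finite-sample
correction, two-sided around zero: r counts null slopes whose magnitude
reaches the observed magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CallTable
from .lmm import LmmSpec, fit_menzerath

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Monte-Carlo slope samples from one null model."""

    model: str
    slopes_size: np.ndarray
    slopes_position: np.ndarray
    observed_size: float
    observed_position: float
    n_iter: int
    seed: int
    empirical_p_size: float = field(init=False)
    empirical_p_position: float = field(init=False)

    def __post_init__(self):
        self.slopes_size = np.asarray(self.slopes_size, dtype=float)
        self.slopes_position = np.asarray(self.slopes_position, dtype=float)
        if len(self.slopes_size) != self.n_iter or len(self.slopes_position) != self.n_iter:
            raise ValueError("slope arrays must have length n_iter")
        self.empirical_p_size = empirical_p(self.slopes_size, self.observed_size)
        self.empirical_p_position = empirical_p(self.slopes_position, self.observed_position)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "slopes_size": self.slopes_size.tolist(),
            "slopes_position": self.slopes_position.tolist(),
            "observed_size": self.observed_size,
            "observed_position": self.observed_position,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "empirical_p_size": self.empirical_p_size,
            "empirical_p_position": self.empirical_p_position,
        }


def empirical_p(null_slopes: np.ndarray, observed: float) -> float:
    """Two-sided empirical p with the (r+1)/(n+1) correction.

    Extremeness is measured as |slope| >= |observed| (two-sided around
    zero), so p is monotone non-increasing in the observed magnitude.
    """
    null_slopes = np.asarray(null_slopes, dtype=float)
    r = int((np.abs(null_slopes) >= abs(observed)).sum())
    return (r + 1) / (null_slopes.size + 1)


def _observed(table: CallTable, spec: LmmSpec):
    res = fit_menzerath(table, spec)
    theta0 = None
    if res.residual_var > 0 and res.variance_components:
        theta0 = np.array(
            [res.variance_components.get(n, 0.0) / res.residual_var
             for n in ("sequence", "individual", "position_cat")]
        )
    return res, theta0


def shuffle_null(
    table: CallTable,
    n_iter: int = 1000,
    seed: int = 0,
    spec: LmmSpec | None = None,
) -> NullDistribution:
    """Within-individual duration-shuffle null distribution of the slopes.

    Per iteration the duration values are permuted among all calls of the
    same individual (sequence sizes and positions unchanged) and the
    model is refit.  Individuals with a single call keep their duration
    (no-op permutation).  Deterministic given ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    spec = spec or LmmSpec()
    observed, theta0 = _observed(table, spec)
    rng = np.random.default_rng(seed)

    df = table.df
    groups = [idx.to_numpy() for _, idx in df.groupby("individual_id", sort=False).groups.items()]
    singletons = [g for g in groups if len(g) == 1]
    if singletons:
        logger.info("%d individuals have a single call; their durations are fixed", len(singletons))

    base = df["duration_s"].to_numpy()
    b1 = np.empty(n_iter)
    b2 = np.empty(n_iter)
    for it in range(n_iter):
        dur = base.copy()
        for g in groups:
            if len(g) > 1:
                dur[g] = dur[rng.permutation(g)]
        shuffled = df.copy()
        shuffled["duration_s"] = dur
        shuffled["onset_s"] = pd.NA  # stale after shuffling
        shuffled["offset_s"] = pd.NA
        res = fit_menzerath(CallTable(shuffled), spec, theta0=theta0)
        b1[it] = res.coef("log_seq_size")
        b2[it] = res.coef("position")
    return NullDistribution(
        model="shuffle",
        slopes_size=b1,
        slopes_position=b2,
        observed_size=observed.coef("log_seq_size"),
        observed_position=observed.coef("position"),
        n_iter=n_iter,
        seed=seed,
    )


def generate_pseudo_sequence(
    real_total: float,
    pool: np.ndarray,
    rng: np.random.Generator,
) -> list[float]:
    """Sample one duration-matched pseudo-sequence.

    Durations are drawn with replacement from ``pool`` until the running
    total strictly exceeds ``real_total``.  If the overshoot exceeds 50%
    of the last sampled duration, the last sample is dropped (an exact
    50% overshoot is kept).  The rule is applied verbatim even when it
    empties the sequence (a first draw overshooting by more than half its
    own duration); callers drop such empty pseudo-sequences.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise ValueError("duration pool is empty")
    if real_total <= 0:
        raise ValueError("real_total must be positive")
    out: list[float] = []
    total = 0.0
    while total <= real_total:
        d = float(pool[rng.integers(pool.size)])
        out.append(d)
        total += d
    overshoot = total - real_total
    if overshoot > 0.5 * out[-1]:
        out.pop()
    return out


def production_constraint_null(
    table: CallTable,
    n_iter: int = 1000,
    seed: int = 0,
    spec: LmmSpec | None = None,
) -> NullDistribution:
    """Duration-matched pseudo-sequence null distribution of the slopes.

    Per iteration, every real sequence is replaced by one pseudo-sequence
    sampled from its individual's pooled duration distribution (see
    :func:`generate_pseudo_sequence`); the pseudo table keeps the
    individual IDs, assigns fresh sequence IDs and positions 1..m, and
    the model is refit on it.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    spec = spec or LmmSpec()
    observed, theta0 = _observed(table, spec)
    rng = np.random.default_rng(seed)

    df = table.df
    pools = {ind: grp["duration_s"].to_numpy() for ind, grp in df.groupby("individual_id", sort=False)}
    seq_meta = (
        df.groupby("sequence_id", sort=False)
        .agg(individual_id=("individual_id", "first"),
             context=("context", "first"),
             total=("duration_s", "sum"))
        .reset_index()
    )

    b1 = np.empty(n_iter)
    b2 = np.empty(n_iter)
    n_empty = 0
    for it in range(n_iter):
        cols = {k: [] for k in ("context", "individual_id", "sequence_id", "position", "duration_s")}
        for i, row in enumerate(seq_meta.itertuples(index=False)):
            durs = generate_pseudo_sequence(row.total, pools[row.individual_id], rng)
            m = len(durs)
            if m == 0:
                n_empty += 1
                continue
            cols["context"].extend([row.context] * m)
            cols["individual_id"].extend([row.individual_id] * m)
            cols["sequence_id"].extend([f"pseudo{it:04d}_{i:06d}"] * m)
            cols["position"].extend(range(1, m + 1))
            cols["duration_s"].extend(durs)
        pseudo = CallTable(pd.DataFrame(cols))
        res = fit_menzerath(pseudo, spec, theta0=theta0)
        b1[it] = res.coef("log_seq_size")
        b2[it] = res.coef("position")
    if n_empty:
        logger.info("dropped %d empty pseudo-sequences (50%% rule removed a lone overshooting call)", n_empty)
    return NullDistribution(
        model="production_constraint",
        slopes_size=b1,
        slopes_position=b2,
        observed_size=observed.coef("log_seq_size"),
        observed_position=observed.coef("position"),
        n_iter=n_iter,
        seed=seed,
    )
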