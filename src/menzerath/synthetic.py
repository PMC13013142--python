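"""Synthetic call sequences and cued-number trials.

The generator is the exact inverse of the fitted duration model: for each
sequence j of individual k with size n, call i gets

    log(duration) = beta0 + beta1 * log(n) + beta2 * i + u_j + v_k + w_i + eps

with independent Gaussian random intercepts for sequence (u), individual
(v) and position category (w, drawn once per ordinal position and shared
across all sequences — the crossed structure the estimator assumes) and
i.i.d. Gaussian residuals.  Durations are therefore log-normal.

Trial outcomes are Bernoulli with a linear (clipped) success-probability
model in the cued number, with per-participant random intercepts and
slopes — matching the linear accuracy model fitted downstream.

Presets mirror the three study conditions: cued crows (sizes 1–4, weak
compression with positive position drift), cued humans (sizes 1–8,
anti-compression), and wild-style bouts (truncated-geometric sizes, strong
compression).  The wild size distribution is a plausible stand-in, not an
estimate, and carries no quantitative weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import CallTable

logger = logging.getLogger(__name__)


# -- size distributions ----------------------------------------------------


@dataclass(frozen=True)
class SizeDistribution:
    """Distribution of sequence sizes on the positive integers.

    kind:
      * ``uniform``: discrete uniform on ``a..b`` inclusive.
      * ``categorical``: ``probs[i]`` is the probability of size ``i+1``.
      * ``geometric``: geometric with the given ``mean`` (support 1, 2, ...),
        optionally truncated at ``max_size``.
    """

    kind: str = "uniform"
    a: int = 1
    b: int = 4
    probs: tuple[float, ...] | None = None
    mean: float = 3.0
    max_size: int | None = None

    def __post_init__(self):
        if self.kind == "uniform":
            if not (1 <= self.a <= self.b):
                raise ValueError(f"uniform size range must satisfy 1 <= a <= b, got {self.a}..{self.b}")
        elif self.kind == "categorical":
            p = np.asarray(self.probs, dtype=float)
            if p.ndim != 1 or p.size == 0 or (p < 0).any() or p.sum() <= 0:
                raise ValueError("categorical size probabilities must be a nonnegative vector with positive sum")
        elif self.kind == "geometric":
            if self.mean <= 1:
                raise ValueError("geometric size mean must exceed 1")
        else:
            raise ValueError(f"unknown size distribution kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "uniform":
            return rng.integers(self.a, self.b + 1, size=n)
        if self.kind == "categorical":
            p = np.asarray(self.probs, dtype=float)
            p = p / p.sum()
            return rng.choice(np.arange(1, p.size + 1), size=n, p=p)
        # geometric with mean m => success prob 1/m, support {1, 2, ...}
        sizes = rng.geometric(1.0 / self.mean, size=n)
        if self.max_size is not None:
            sizes = np.minimum(sizes, self.max_size)
        return sizes


# -- call-table generation -------------------------------------------------


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for :func:`simulate_call_table`.

    ``beta0`` is the intercept in log-seconds; ``beta1`` the log-size slope
    (negative under compression); ``beta2`` the per-position slope.  The
    four ``sigma_*`` are the SDs of the sequence, individual and position
    intercepts and of the residual, all on the log-duration scale.
    """

    beta0: float = math.log(0.2)
    beta1: float = -0.022
    beta2: float = 0.034
    sigma_seq: float = 0.1
    sigma_ind: float = 0.1
    sigma_pos: float = 0.02
    sigma_eps: float = 0.3
    n_individuals: int = 3
    sequences_per_individual: int = 1500
    size_distribution: SizeDistribution = field(default_factory=SizeDistribution)
    context: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma_seq", "sigma_ind", "sigma_pos", "sigma_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_individuals < 1 or self.sequences_per_individual < 1:
            raise ValueError("need at least one individual and one sequence per individual")


def trained_crow_preset(**overrides) -> SyntheticConfig:
    """Cued-crow-like condition: sizes 1-4, weak compression, final drift up."""
    cfg = SyntheticConfig(
        beta0=math.log(0.2), beta1=-0.022, beta2=0.034,
        size_distribution=SizeDistribution("uniform", a=1, b=4),
        context="trained_crow",
    )
    return replace(cfg, **overrides)


def human_preset(**overrides) -> SyntheticConfig:
    """Cued-human-like condition: sizes 1-8, anti-compression, final shortening."""
    cfg = SyntheticConfig(
        beta0=math.log(0.35), beta1=0.033, beta2=-0.023,
        n_individuals=26, sequences_per_individual=156,
        size_distribution=SizeDistribution("uniform", a=1, b=8),
        context="human",
    )
    return replace(cfg, **overrides)


def wild_crow_preset(**overrides) -> SyntheticConfig:
    """Wild-bout-like condition: truncated-geometric sizes, strong compression.

    The size distribution is a stand-in (not estimated from recordings) and
    must not be used for quantitative claims.
    """
    cfg = SyntheticConfig(
        beta0=math.log(0.25), beta1=-0.164, beta2=0.003,
        n_individuals=30, sequences_per_individual=40,
        size_distribution=SizeDistribution("geometric", mean=3.0, max_size=12),
        context="wild_crow",
    )
    return replace(cfg, **overrides)


def simulate_call_table(config: SyntheticConfig) -> CallTable:
    """Generate a call table under the crossed random-intercept model.

    Fully reproducible from ``config.seed``.  With all SDs zero the
    durations equal the deterministic fixed-effect prediction exactly.
    """
    rng = np.random.default_rng(config.seed)
    n_ind = config.n_individuals
    n_seq = config.sequences_per_individual

    v = rng.normal(0.0, config.sigma_ind, size=n_ind) if config.sigma_ind > 0 else np.zeros(n_ind)

    sizes = config.size_distribution.sample(rng, n_ind * n_seq).reshape(n_ind, n_seq)
    if (sizes < 1).any():
        raise ValueError("size distribution produced a sequence of size 0")
    max_pos = int(sizes.max())
    w = rng.normal(0.0, config.sigma_pos, size=max_pos) if config.sigma_pos > 0 else np.zeros(max_pos)

    rows: dict[str, list] = {k: [] for k in ("context", "individual_id", "sequence_id", "position", "duration_s", "cue_number")}
    for k in range(n_ind):
        ind_id = f"{config.context}_ind{k + 1:02d}"
        u = rng.normal(0.0, config.sigma_seq, size=n_seq) if config.sigma_seq > 0 else np.zeros(n_seq)
        for j in range(n_seq):
            n = int(sizes[k, j])
            pos = np.arange(1, n + 1)
            eps = rng.normal(0.0, config.sigma_eps, size=n) if config.sigma_eps > 0 else np.zeros(n)
            logdur = config.beta0 + config.beta1 * math.log(n) + config.beta2 * pos + u[j] + v[k] + w[pos - 1] + eps
            rows["context"].extend([config.context] * n)
            rows["individual_id"].extend([ind_id] * n)
            rows["sequence_id"].extend([f"{ind_id}_seq{j + 1:05d}"] * n)
            rows["position"].extend(pos.tolist())
            rows["duration_s"].extend(np.exp(logdur).tolist())
            rows["cue_number"].extend([n] * n)
    return CallTable(pd.DataFrame(rows))


# -- trial generation ------------------------------------------------------


@dataclass(frozen=True)
class TrialConfig:
    """Generative parameters for :func:`simulate_trials`.

    Success probability for participant p at cue c is
    ``clip(intercept_p + slope_p * c, 0, 1)`` with
    ``intercept_p ~ N(accuracy_intercept, participant_intercept_sd)`` and
    ``slope_p ~ N(accuracy_slope, participant_slope_sd)`` — a linear
    probability model, matching the downstream accuracy fit.
    """

    accuracy_intercept: float = 1.0
    accuracy_slope: float = -0.007
    cue_min: int = 1
    cue_max: int = 8
    trials_per_participant: int = 160
    n_participants: int = 26
    participant_intercept_sd: float = 0.01
    participant_slope_sd: float = 0.003
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.accuracy_intercept <= 1):
            raise ValueError("accuracy_intercept must lie in (0, 1]")
        if self.cue_min < 1 or self.cue_max < self.cue_min:
            raise ValueError("cue range must satisfy 1 <= cue_min <= cue_max")
        if self.participant_intercept_sd < 0 or self.participant_slope_sd < 0:
            raise ValueError("random-effect SDs must be >= 0")


def simulate_trials(config: TrialConfig) -> pd.DataFrame:
    """Generate a trial table (participant_id, cue_number, correct).

    Cues are balanced across the range per participant, presented in
    random order.  Probabilities falling outside [0, 1] after the random
    effects are clipped; the number of clipped trials is logged.
    """
    rng = np.random.default_rng(config.seed)
    cues = np.arange(config.cue_min, config.cue_max + 1)
    n_clipped = 0
    rows = {"participant_id": [], "cue_number": [], "correct": []}
    for p in range(config.n_participants):
        pid = f"participant{p + 1:02d}"
        intercept = config.accuracy_intercept + rng.normal(0.0, config.participant_intercept_sd)
        slope = config.accuracy_slope + rng.normal(0.0, config.participant_slope_sd)
        reps = int(np.ceil(config.trials_per_participant / cues.size))
        trial_cues = np.tile(cues, reps)[: config.trials_per_participant]
        rng.shuffle(trial_cues)
        prob = intercept + slope * trial_cues
        n_clipped += int(((prob < 0) | (prob > 1)).sum())
        prob = np.clip(prob, 0.0, 1.0)
        correct = rng.random(prob.size) < prob
        rows["participant_id"].extend([pid] * trial_cues.size)
        rows["cue_number"].extend(trial_cues.tolist())
        rows["correct"].extend(correct.tolist())
    if n_clipped:
        logger.warning("clipped success probability to [0, 1] on %d trials", n_clipped)
    df = pd.DataFrame(rows)
    df["cue_number"] = df["cue_number"].astype(np.int64)
    df["correct"] = df["correct"].astype(bool)
    return df
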