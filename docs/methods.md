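# Methods

## The duration model

The core quantity is the compression slope β₁ of the crossed
random-intercept model

    log(d_ijk) = β₀ + β₁·log(n_j) + β₂·pos_i + u_j + v_k + w_l + ε_ijk

with u_j ~ N(0, σ²_seq) per sequence, v_k ~ N(0, σ²_ind) per individual,
w_l ~ N(0, σ²_pos) per ordinal-position category, and ε i.i.d. N(0, σ²).
Durations are log-normal under this model; the log transform is applied
at fit time, never at I/O.  **Natural logarithms** are used for both the
response and sequence size; a different base would rescale β₀ and the
response-side slopes by a constant, so the choice matters when comparing
against coefficients computed elsewhere.

Position enters twice by design: as a numeric fixed effect (the drift
β₂) and as a categorical random intercept (w_l) absorbing idiosyncratic
associations of calls with particular positions.  The two are
identifiable jointly because the random intercepts are shrunk toward
zero, but see "known limitations" below for the inferential cost.

Singleton sequences contribute log(1) = 0 to the size term and position
1; they are included by default and removed by `include_singles=False`
(both variants are part of a standard report, since single-element
sequences can drive or mask compression).

## Estimation

REML by default, ML optional; the choice affects variance components far
more than the slopes.  The solver profiles β and σ² out of the (restricted)
likelihood and optimizes only the variance ratios θ_m = σ²_m/σ², through
the sparse Henderson mixed-model equations: one sparse LU factorization
per candidate θ yields the penalized residual sum of squares and both log
determinants of the criterion

    -2·l_R(θ) = log|I + ΛZ'ZΛ| + log|X'V₀⁻¹X| + (n-p)·log r²(θ) + const.

Optimization is over s_m = √θ_m ∈ [0, 100] so that degenerate components
sit on the search boundary at 0.  The path is L-BFGS-B (finite-difference
step 1e-5, chosen well above factorization noise) from s = 0.3 and, when
available, from the warm start of a previous fit; cold fits and aborted
gradient runs get a derivative-free Powell polish, which handles the flat
ridge that appears when a variance component approaches the boundary.
Results were verified against R lme4 on crossed fixtures (estimates, SEs,
variance components and ML log-likelihood agree to six decimals; frozen
reference values live in the test suite) and against statsmodels MixedLM
on a single-intercept submodel.

Degrees of freedom for t/p use the residual approximation df = n − p and
the result records `df_method="residual"`.  Exact t/p replication against
other tools is not guaranteed (df conventions differ); interpretation
should key on estimates and SEs.  A response that is an exact linear
function of the fixed effects (noise-free synthetic data, constant
tables) short-circuits to the exact OLS solution with all variance
components zero.  Random terms with a single level (e.g. one individual)
are dropped with a warning — their variance is inestimable.

The cued-number accuracy model regresses per-participant percent-correct
(0–1 scale) per cue number on the cue number, with uncorrelated
per-participant random intercepts and random slopes.  A linear (not
logistic) probability model is used deliberately: accuracies sit near
ceiling and the quantity of interest is the per-cue decline on the
percentage scale.

## Null models

Both nulls refit the identical model specification per iteration and are
deterministic given a seed.

**Shuffle null.**  Durations are permuted among all calls of the same
individual; sequence sizes and positions are untouched, so per individual
the duration multiset is conserved exactly.  Any size–duration or
position–duration association is destroyed by construction; the null
slopes center on zero (checked at Monte-Carlo precision).

**Production-constraint null.**  For each real sequence, durations are
sampled with replacement from the individual's pooled duration
distribution until the cumulative total strictly exceeds the real
sequence's total; if the overshoot exceeds 50% of the last sample, that
sample is removed (an exact 50% overshoot is kept — removal requires
*more than* half).  Pseudo-sequences keep the individual ID, get fresh
sequence IDs and positions 1..m in sampling order.  Pools are per
individual, not per trial type.  Sampling with replacement matches the
"distribution" reading and leaves pools unchanged across sequences.  The
rule is applied verbatim even in the corner where it empties a
pseudo-sequence (a lone first draw overshooting by more than half its own
duration); empty pseudo-sequences are dropped from the pseudo table with
a log message.  Under this null, sequences that happen to sample shorter
calls need more of them to reach the same total, which by itself induces
a negative size slope — the point of the comparison.

Empirical p-values use the finite-sample correction p = (r+1)/(n+1),
two-sided around zero: r counts null slopes with |slope| ≥ |observed|.
This makes p monotone non-increasing in the observed magnitude and never
exactly zero.  Default n_iter is 1000; the test suite and acceptance
script use 200 (shuffle) and 10–200 (production constraint) — sizes
chosen so the Monte-Carlo error is far smaller than the effects being
tested.

## Boundary statistics

First/last-call correlations are plain Pearson r/p on one
(duration, size) point per sequence.  Singleton sequences count as both
first and last by default (`include_singles=False` drops them); degenerate
inputs (zero variance, too few sizes) raise a typed error instead of
propagating NaN.

Final lengthening: within each sequence with ≥ 2 calls, relative
duration = duration ÷ sequence mean (so per-sequence relative durations
average to 1 and the statistic is invariant to global rescaling); the
paired t-test compares the final call's relative duration with the mean
relative duration of the non-final calls, sequences as the unit,
df = n_sequences − 1.  Singletons are necessarily excluded (no non-final
partner).  All paired differences exactly zero is reported as t = 0,
p = 1 rather than 0/0.

## Audio pre-screening and segmentation

The screen metrics use conventional bioacoustics definitions, since only
the thresholds (flatness > 0.05, temporal entropy > 0.85) and their
interpretations (broadband noise; temporally uniform power) are fixed by
the analysis design:

* spectral flatness — per-frame geometric/arithmetic mean ratio of the
  STFT power spectrum (Hann window, 512 samples, 50% overlap), averaged
  over non-silent frames; ∈ [0,1], ~0.56 in expectation for white noise
  (exp(−γ) for exponential periodogram bins), → 0 for tonal signals.
* temporal entropy — Shannon entropy of energy across non-overlapping
  512-sample frames (incomplete tail dropped), normalized by
  log(n_frames); exactly 1 for constant amplitude, 0 for a single
  energetic frame.

Both are amplitude-scale invariant; all-zero signals raise a typed error.
Window/frame sizes are configurable; pass/fail on real-world recordings
is parameter-sensitive and should not be treated as a calibrated
instrument.

Call detection: Hilbert-magnitude envelope, 10 ms moving-average
smoothing, threshold = 3 × the 10th percentile of the envelope,
supra-threshold runs merged when closer than 30 ms and dropped when
shorter than 20 ms — all configurable, defaults chosen as ordinary
starting points for lab recordings with a stable noise floor.  On tapered
synthetic bursts at ~40 dB SNR, ≥ 95% of boundaries are recovered within
the 10 ms smoothing window (the acceptance script measures ~100%).  With
an extremely quiet floor (60+ dB SNR) and hard-edged bursts, the analytic
envelope's spectral leakage can advance onsets by ~10–20 ms; segment
boundaries should be manually verified when precise onsets matter, which
is also why segments-to-sequence grouping is left to the caller.

## Synthetic data

The generator is the exact inverse of the estimator: Gaussian random
effects on the log-duration scale, position effects drawn once per
category and shared across sequences (crossed, not nested), i.i.d.
log-scale residuals.  Presets encode the three study conditions:

* `trained_crow_preset` — 3 individuals × 1500 sequences, sizes uniform
  1–4, β₁ = −0.022, β₂ = +0.034, β₀ = log 0.2 s.
* `human_preset` — 26 × 156, sizes uniform 1–8, β₁ = +0.033,
  β₂ = −0.023, β₀ = log 0.35 s.
* `wild_crow_preset` — 30 × 40, truncated-geometric sizes (mean 3,
  max 12), β₁ = −0.164, β₂ = +0.003.  The wild size distribution is a
  plausible stand-in, not an estimate; it must not ground quantitative
  claims.

Variance components default to σ_seq = 0.1, σ_ind = 0.1, σ_pos = 0.02,
σ_eps = 0.3 (log scale) — magnitudes that give realistic within- and
between-individual duration spread for short calls.  Trial outcomes are
Bernoulli under a clipped linear probability model (intercept 1.0, slope
−0.007 per cue, cues 1–8, 26 participants), with per-participant random
intercept (SD 0.01) and slope (SD 0.003); clipping events are counted and
logged.

What the generator does *not* emulate: non-Gaussian duration tails,
serial correlation within sequences, call-type mixtures, duration-
dependent sequence termination, or recording/segmentation noise.  Passing
parameter-recovery tests therefore shows the estimator is correct *under
its own assumptions*, not that those assumptions hold for any particular
recording corpus.

## Known limitations

* The position slope β₂ is identified through few ordinal-position
  categories (four, when sizes run 1–4) that simultaneously carry a
  random intercept.  REML then estimates σ²_pos from roughly three
  effective observations; when the estimate shrinks to the boundary, the
  conditional-Wald CI for β₂ omits the realized category-effect
  uncertainty and undercovers (~80% rather than 95% in the replicate
  study the acceptance script runs; lme4 yields the identical intervals).
  The size-slope CI does not suffer from this and covers at the nominal
  rate.  Treat β₂ inference at few position levels as approximate, or
  widen the size range.
* Monte-Carlo nulls inherit the model specification; a misspecified
  duration model biases observed and null slopes alike, which the
  comparison partially — not fully — absorbs.
* The accuracy model is linear in probability; it is not meant for
  accuracies far from ceiling.
* The interaction fit namespaces random-effect levels by group, i.e. it
  assumes no individual appears in both groups.
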