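# menzerath

Statistical toolkit for testing **Menzerath's law** — "the longer the
whole, the shorter its parts" — in animal and human vocal sequences, with
Monte-Carlo null models, boundary-prosody statistics, audio pre-screening,
and a synthetic call-sequence generator so the entire pipeline runs
without any external data.

The package targets the analysis of numerically-cued vocal production
(crows and humans instructed to produce a specific number of
vocalizations) and of wild corvid call bouts, but applies to any tidy
call table: one row per vocalization with its sequence, individual,
ordinal position and duration.

## The model

Compression is measured by a linear mixed model on the log scale,

```
log(d_ijk) = β₀ + β₁·log(n_j) + β₂·pos_i + u_j + v_k + w_l + ε_ijk
```

where `d_ijk` is the duration of the call at position `pos_i` of sequence
`j` produced by individual `k`, and `n_j` is the sequence size (number of
calls).  `u_j`, `v_k`, `w_l` are crossed Gaussian random intercepts for
sequence, individual, and position-as-category; `ε` is i.i.d. Gaussian
noise.  β₁ < 0 is Menzerath-style compression; β₂ captures duration drift
along the sequence (β₂ > 0 together with longer final calls indicates
final lengthening).  Natural logarithms are used throughout.

Because the sequence factor has thousands of levels and the null models
refit the model hundreds of times, estimation uses a sparse profiled
REML/ML solver built on the Henderson mixed-model equations
(`scipy.sparse`); it reproduces lme4-style estimates, standard
errors and variance components (checked against lme4 to six decimals in
the test suite).

Two Monte-Carlo chance models bracket the observed slopes:

* **shuffle null** — permute durations within each individual, keeping
  the sequence/position scaffold; slope distribution centers on zero.
* **production-constraint null** — rebuild each sequence by sampling
  durations from the individual's pool until the real sequence's total
  duration is strictly exceeded, dropping the last sample if the
  overshoot exceeds half of it.  Sizes float while total durations are
  matched, so this null shows how much "compression" duration-matching
  alone produces.

Boundary statistics: Pearson correlations of first-/last-call duration
with sequence size, and a paired t-test of relative (sequence-mean
normalized) final vs non-final durations.  Audio pre-screening: spectral
flatness (Wiener entropy, exclude > 0.05) and temporal entropy (exclude
> 0.85), plus an amplitude-envelope onset/offset detector.

## Worked example

```python
from menzerath import (trained_crow_preset, simulate_call_table, fit_menzerath,
                       shuffle_null, final_lengthening_test)

table = simulate_call_table(trained_crow_preset(seed=7))
print(f"{table.n_calls} calls, {table.n_sequences} sequences, {table.n_individuals} individuals")

res = fit_menzerath(table)
for name in ("log_seq_size", "position"):
    fe = res.fixed_effects[name]
    print(f"{name}: beta = {fe.estimate:+.3f} +/- {fe.se:.3f}, t = {fe.t:.2f}, p = {fe.p:.2g}")

nd = shuffle_null(table, n_iter=200, seed=7)
print(f"shuffle null: mean slope {nd.slopes_size.mean():+.4f}, empirical p = {nd.empirical_p_size:.4f}")

fl = final_lengthening_test(table)
print(f"final lengthening: t({fl.df}) = {fl.t_statistic:.2f}, p = {fl.p_value:.2g}")
```

prints

```
11311 calls, 4500 sequences, 3 individuals
log_seq_size: beta = -0.028 +/- 0.008, t = -3.36, p = 0.00079
position: beta = +0.033 +/- 0.014, t = 2.37, p = 0.018
shuffle null: mean slope -0.0001, empirical p = 0.0050
final lengthening: t(3417) = 6.99, p = 3.3e-12
```

The preset simulates a cued-crow-like condition (sizes 1–4, weak
compression β₁ = −0.022, positive position drift β₂ = +0.034).  The refit
recovers both signs and magnitudes within sampling error; the shuffled
null centers on zero so the observed compression slope is extreme against
it (empirical p = 0.005 at 200 iterations); and final calls are
significantly longer than non-final calls (final lengthening).

The same analyses run from the shell:

```bash
menzerath simulate --preset trained_crow --seed 7 --out calls.csv
menzerath fit --input calls.csv --out fit.json
menzerath nulls --input calls.csv --model shuffle --iters 200 --seed 7 --out null.json
menzerath boundary --input calls.csv --out boundary.json
menzerath run-all --config analysis.yaml --out report.json --figures figs/
```

## Call-table format

CSV, UTF-8, header required.  Columns: `context`, `individual_id`,
`sequence_id`, `position` (1-based, contiguous within a sequence),
`duration_s` (seconds, > 0), and optionally `cue_number`, `correct`,
`onset_s`, `offset_s`.  Validation reports offending rows/sequences.

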