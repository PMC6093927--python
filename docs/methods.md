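# Methods

## Scope and model

The package analyses epoched multichannel EEG (microvolts) organised as a
`channels × timebins × trials` tensor with a trial-label table (category,
exemplar, variation type and level, repetition, subject). The reference
configuration is 31 analysis channels of the 10–20 montage, 201 bins of
5 ms spanning −198…802 ms, and 576 trials per subject (three repetitions
of a 192-image factorial design: 4 categories × 4 exemplars × 4 variation
types × 3 levels, one variation manipulated per image — the only
factorization consistent with 192 images, 16 objects and 48 images per
category).

## Projection d′

Decodability between two trial clusters is measured by projecting all
trials onto the line joining the cluster means and forming
d′ = (μ₁−μ₂)/√((σ₁²+σ₂²)/2) with **sample** variances (n−1); the cluster
with the larger projected mean is cluster 1, so d′ ≥ 0. Choices:

- **Equal means** return d′ = 0 rather than erroring: it is the
  information-free limit and occurs routinely in permutation nulls.
- **Zero projected variance with distinct means** raises — the statistic
  is undefined and silent infinities would corrupt averages.
- d′ is invariant to rotation, translation and positive scaling of the
  feature space, and reduces to the classic univariate sensitivity index
  in one dimension; both are asserted by tests.
- Because the projection direction is estimated from the same data, the
  null distribution of d′ has a positive bias that grows with
  dimensionality and shrinks with trials. All group inference therefore
  compares post-stimulus values against each subject's own pre-stimulus
  values, where the same bias is present and cancels.

**Schemes.** Pooled decoding uses all trials of each condition (144 per
category; 48 per variation level). Per-condition decoding isolates one
dimension from the other: category d′ is computed within each of the 12
variation conditions (12 trials per cluster) and averaged; variation d′
is computed between two levels within each of the 16 objects (3 trials
per cluster) and averaged. Strata averaging is unweighted (the design is
balanced); strata with fewer than 2 trials per cluster are skipped with a
warning.

**Baseline.** Curves subtract the mean d′ over the pre-stimulus window
(default −200…0 ms of the binned axis) per subject; scalp maps apply the
same per electrode. Significance testing uses the *uncorrected* values
against the subjects' pre-stimulus averages.

## Group statistics

Per post-stimulus bin, a two-sided Wilcoxon signed-rank test (scipy,
exact where possible; all-zero differences give p = 1) compares subjects'
values with their pre-stimulus averages; p-values are FDR-corrected
across bins. Benjamini–Hochberg is the default (deterministic,
parameter-free); Storey's pFDR with a λ = 0.5 null-proportion estimate is
available as `method="storey"` for comparability with Matlab `mafdr`-based
pipelines, whose default it is — the two corrections can differ slightly.

**Latency and peak.** The peak is the argmax of the group-mean curve over
post-stimulus bins (ties to the earliest). Latency is the first
post-stimulus bin opening a run of at least `min_run = 2` consecutive
significant bins. A single-bin rule was tried first and proved unreliable:
when a curve contains many strongly significant bins, the FDR step-up
threshold relaxes and isolated false-positive bins appear at a
non-trivial per-study rate (≈13% of simulated 10-subject studies showed a
spurious pre-onset latency), whereas two consecutive false positives are
rare. `min_run=1` restores the plain rule.

**Sliding correlation.** Pearson r of two curves within trailing 50 ms
(10-bin) windows ending at each bin — trailing so no future samples enter.
With group curves, correlations are computed per subject and group-tested
(signed-rank against zero, FDR across bins); the correlation of
group-mean curves is reported alongside.

## Information selectivity

Aspects are one-vs-rest: each category against the other three (mean of
the three pairwise per-electrode d′ values) and each variation level
against the other two levels, 16 aspects total, computed univariately per
electrode on pooled trials (pooling keeps the 31-entry vectors stable;
per-condition strata would be far noisier). The selectivity matrix holds
pairwise Pearson correlations of these vectors at one bin; the index is
the mean within-dimension off-diagonal correlation minus the mean
between-dimension correlation (diagonal excluded, missing entries dropped
and logged). Vectors are correlated raw by default; a baseline-corrected
variant is available (`baseline=True`) since correlation is invariant to
a per-vector shift but not to per-electrode baseline structure.

## Information flow

Representations are single-presentation 9-electrode voltage vectors
(never repetition-averaged — a 48×48 matrix for 16 objects × 3
presentations requires it). Similarity matrices are Pearson correlations
across all presentation pairs; the diagonal and upper triangle are
excluded by lower-triangle vectorization (1128 entries at n = 48).
FF/FB are first-order partial correlations as in the README; the past
term averages the 11 matrices in t−130…t−80 ms. Curves are computed per
subject (and per stimulus subset — default: the 12 single-variation-
condition subsets for category flow, averaged) and then averaged;
flows are reported only where the full past window is inside the epoch.

**Permutation null.** Each permutation shuffles the vectorized entries of
the time-t matrix only — this destroys the tested dependence while
preserving the conditioning structure — and recomputes the partial
correlation; with several subjects/subsets the permuted values are
averaged across them slot-wise, mirroring the true value. The threshold
is the value at rank ⌈0.95·n⌉ of the sorted null (950 of 1000); the
difference FF−FB gets two-sided 5th/95th-percentile bounds from the same
nulls. Degenerate conditioning (|r| = 1 within 1e−12) yields missing
values, logged.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, not
real EEG physiology:

- **Noise.** Per-channel AR(1) at 1 kHz (coefficient 0.5 by default,
  innovation sd 5 µV), stationarised by an adaptive burn-in, with an
  optional variance fraction shared across channels. Temporal
  autocorrelation matters: white noise would make the binned-time
  permutation and baseline machinery trivially calibrated.
- **Effects.** Each planted effect is `amplitude × spatial pattern ×
  Gaussian(t; onset, width)` added to the raw traces of all trials
  matching its condition. `onset_ms` is the *center* of the transient and
  `width_ms` its standard deviation; the default width of 5 ms models a
  rapid transient so that onset, detection latency and peak stay tightly
  coupled — real evoked components are broader, so latencies on real data
  will precede a component's center by more than they do here. An
  optional copy delayed by `lag_ms` on a second spatial pattern plants a
  known cross-region propagation for the flow analyses.
- **Binning.** Raw 1 ms traces pass through a 5-sample non-overlapping
  moving average; bin time = first raw sample time + 2 ms. The raw epoch
  is −200…+804 ms inclusive (1005 samples) so that binning yields exactly
  201 bins; a −200…800 ms span does not divide evenly and the choice of
  the extra 4 ms is documented here as the package's reading.
- **Determinism.** Identical (design, config, subject id) produce
  bit-identical datasets; the per-subject stream is seeded by
  (config seed, subject id).

What the generator does **not** emulate: 1/f spectra, alpha rhythms,
volume-conduction correlation structure, artifacts, inter-subject
amplitude/latency variability, or overlapping multi-component responses.
Passing recovery tests therefore shows the *analysis machinery* is
correct and calibrated, not that effect sizes or latencies on real
recordings will match.

## Problem sizes used in tests and the acceptance script

Null calibration uses 200 simulated group studies (10 subjects each) on a
60-bin (−100…199 ms) epoch; effect recovery uses 100 studies (10
subjects, 80-bin epochs) for latency/scalp checks and 100 + 20 runs of 3
subjects for the forward/reversed flow-direction checks with 200
permutations over the transfer window. The acceptance script reruns the
same computations at smaller replicate counts (30/20/15) so a full
reproduction completes in minutes on one CPU; all sizes are the package's
own choices for a desk-scale study.

## Known limitations

- Pre-stimulus baseline comparisons assume the pre-stimulus d′ is
  signal-free; paradigms with anticipatory activity violate this.
- BH-FDR assumes positive dependence across bins; strongly negatively
  correlated bins are outside its guarantee.
- The selectivity index inherits the sign ambiguity of correlating
  noisy d′ vectors: with weak effects it is biased toward 0.
- The flow statistic is a *simplified* Granger causality on
  representational geometry: it is directional evidence, not a full
  multivariate autoregressive model, and common input with differing
  lags can masquerade as flow.
- Electrode-to-scalp interpolation/plotting is intentionally out of
  scope; scalp maps are per-electrode values only.
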