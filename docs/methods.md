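# Methods

This note documents the models, estimators, default parameters and numerical
choices behind `srcnet`, and what the synthetic-cohort tests do and do not
establish.

## Synthetic cohorts

### Signal model

Each subject is an (epochs × nodes × samples) array in microvolts:

- background: i.i.d. Gaussian noise per node, `noise_sd` (default 5 µV);
- coupling: for every edge (i, j, σ) of a `CouplingSpec`, both nodes receive
  `osc_amplitude · cos(2πf₀t + φ₀ + θ(t))` (default 10 µV) with a shared
  per-epoch random carrier phase φ₀ and independent phase-jitter processes
  θᵢ, θⱼ of variance σ²/2 each, so the pairwise phase difference is Gaussian
  with variance σ²;
- artifacts (optional): with probability `artifact_rate` per epoch, a 50 ms
  square pulse of `artifact_amplitude` (default 150 µV, deliberately beyond
  the ±100 µV rejection limit) is added at a random node and onset.

Because `E[e^{iΔθ}] = e^{−σ²/2}` for Gaussian Δθ, the asymptotic PLV of a
coupled pair is exactly `exp(−σ²/2)`: σ = 0 gives PLV 1, σ = 1 gives 0.607,
σ = 2 gives 0.135. This closed form is what makes the generator usable as a
ground-truth oracle for the whole pipeline.

### Why the jitter is smooth, not block-wise

The jitter is white Gaussian noise circularly convolved with a Gaussian
kernel (width `jitter_smooth_seconds`, default 0.1 s) and rescaled by the
kernel's exact noise gain, so every sample is marginally N(0, σ²) — the
expectation above is exact — while the signal stays narrowband. A
piecewise-constant ("per block") jitter has the same marginal law but
injects a broadband transient at every block boundary, which corrupts
analytic-signal (Hilbert) phase estimates precisely where the generator is
supposed to provide clean ground truth. The smoothing width only determines
how many effectively independent phase samples a finite window contains.

### Finite-sample PLV bias

The PLV estimator over B effectively independent phase samples satisfies
`E[PLV_B] ≈ sqrt(R² + (1 − R²)/B)` where R is the asymptotic value. Two
consequences:

- per-epoch PLV (2 s epochs, B ≈ 6–20) is noticeably upward-biased for
  weakly coupled pairs, and uncoupled pairs sit on a floor of roughly
  `sqrt(π)/(2·sqrt(B))` rather than 0; the floor is the same for all groups,
  so group contrasts are unaffected;
- calibration tests that check the closed form to Monte-Carlo precision use
  long single realizations (or `plv_matrix(..., mode="concatenate")`, which
  pools all epochs' samples) so that B is large and the bias is far below
  the tolerance.

### PANSS items

Item scores are `clip(round(N(baseline + shift, item_sd)), 1, 7)` with
baseline 3.0 and item_sd 1.5 — the simplest ordinal model with a
controllable per-group mean shift. Baseline 3 keeps items away from both
clip boundaries so configured group shifts move means approximately
linearly.

### Determinism

All randomness descends from one `numpy.random.SeedSequence(seed)`; each
subject receives two spawned child streams (signals, PANSS items) in a fixed
group-major order, so cohorts are bit-identical across runs and independent
of how many downstream consumers draw random numbers.

## Preprocessing

- Epoching: non-overlapping 2 s windows, trailing remainder discarded.
- Amplitude rule: an epoch is removed if any sample at any node strictly
  exceeds ±100 µV ("exceeding" is strict; a sample exactly at the limit is
  kept; limit configurable).
- Spectral rule: theta (4–8 Hz) and alpha (8–12 Hz) powers are integrated
  from the per-epoch boxcar periodogram by the rectangle rule over bins
  strictly inside the band edges, averaged over nodes, and the epoch is
  removed if theta/alpha > 1. The comparison carries a 1e−9 relative
  epsilon so an exact power tie (ratio = 1 up to float rounding) stays on
  the "kept" side, matching the strict-inequality rule. A zero-alpha epoch
  has an undefined ratio and is removed with a warning. Averaging over nodes
  (rather than per-node exclusion) is a choice the protocol leaves open; it
  yields one scalar criterion per epoch.
- Epoch selection: k = 30 by default, uniform without replacement, seeded,
  temporal order preserved; `allow_fewer` downgrades the shortage to a
  warning.
- Band-pass: 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`, zero phase). In-band sinusoid gain is within [0.9, 1.1]
  and attenuation one octave outside the edges exceeds 20 dB. No notch or
  acquisition filter is re-applied: synthetic data is generated clean.

Note that on pure white-noise epochs the theta/alpha ratio fluctuates around
1 (both bands are 4 Hz wide), so roughly half of such epochs are rejected;
realistic resting-state signals, and the generator's alpha-band coupled
cohorts, are alpha-dominant and pass.

## Connectivity

Phase comes from the analytic signal (FFT-based Hilbert transform); PLV is
computed within each epoch over every unordered node pair — vectorized as
`|Z Z^H|/T` on the unit-phasor matrix — and averaged across epochs (epochs
are the unit of artifact control; a concatenated mode pools samples
instead). 10 % of samples at each epoch edge are discarded first to suppress
filter and Hilbert edge effects (configurable). The matrix is symmetrized,
its diagonal set to 1, and clipped to [0, 1].

## Graph metrics

- Local clustering coefficient (weighted, geometric-mean triangle form):
  weights are rescaled by the global maximum; `c_u = Σ_{v,w}
  (ŵ_uv ŵ_uw ŵ_vw)^{1/3} / (k_u(k_u−1))` with k_u the count of nonzero-weight
  neighbours; degree < 2 scores 0. Values lie in [0, 1] and are invariant to
  uniform weight scaling.
- Global clustering = arithmetic mean of local values.
- Characteristic path length: edge length 1/weight, Dijkstra shortest paths,
  mean over unordered pairs (a literal-sum mode exists for comparison, but
  the mean is the standard definition and the only one comparable across
  network sizes). Disconnected pairs are excluded with a warning.
- The diagonal is excluded and the full weighted matrix is used without
  thresholding.

Feature order, fixed and documented: for each band, local CCs in node order,
then global CC, then path length. Tests verify both metrics against
exhaustive triangle enumeration and Floyd–Warshall relaxation, and against
`networkx`'s weighted clustering (same convention).

## PANSS scoring and subtyping

Five-factor item lists: positive (P1, P3, P5, P6), negative (N1, N2, N3, N4,
N6, G7, G16), cognitive/disorganization (P2, N5, G9, G10, G11, G13, G15),
excitement (P4, P7, G8, G12, G14), depression/anxiety (G2, G3, G4, G6);
standard subscales are the sums of P1–P7, N1–N7 and G1–G16. The median split
labels a subject "high" strictly above the cohort median by default; whether
median-valued subjects belong to the high or low group is a convention
choice, so the rule is exposed as a parameter (`>` or `>=`). A constant cohort is all-"low" with a warning.

## Classification

- LDA: class means and pooled within-class covariance with ridge
  `1e−6 · trace(Σ)/d` added to the diagonal (handles duplicated or collinear
  features); empirical class priors. Implemented directly in numpy because
  the SFS wrapper makes 10⁴–10⁵ tiny fits per run; agreement with sklearn's
  LDA is covered by a test.
- CV: 10 repetitions of stratified 10-fold CV with distinct seeded shuffles;
  accuracy, sensitivity (recall of the designated positive class) and
  specificity averaged over all 100 held-out folds. If the smaller class has
  fewer members than folds, the fold count is reduced with a warning.
- SFS: greedy forward selection; the cost of a candidate set is its mean
  stratified 10-fold LDA accuracy on fixed, seeded folds (wrapper costs are
  conventionally a k-fold accuracy; 10-fold is the default here and is
  recorded in the report). Ties break toward the lowest
  feature index; the search stops at no-improvement or at the 30-feature
  cap; the returned set is the trace prefix with the best cost.
- Modes: `paper` (select on all data, then cross-validate the selected set)
  is the select-then-validate protocol widespread in applied decoding work
  and the default; `nested` (selection re-run inside every training fold) is
  the unbiased protocol. The difference matters: on pure-noise features with
  permuted labels, `paper` mode exceeds the 95 % binomial threshold in a
  large fraction of runs while `nested` stays at the nominal rate — this
  selection-bias demonstration is part of the acceptance suite.
- ROC: per-fold empirical ROC staircases are evaluated on a fixed
  101-point false-positive grid by step interpolation (highest TPR attained
  at each FPR) and averaged vertically; AUC is the trapezoidal area of the
  mean curve.

## Significance thresholds

`binom_inv(q, n, p)` is the smallest k with Binomial(n, p) CDF(k) ≥ q,
delegated to `scipy.stats.binom.ppf` with two guards: q = 1 returns n
(p > 0), and a 1e−10 tolerance step resolves exact CDF ties that float
arithmetic misses (e.g. CDF = q exactly at p = 1/2 with odd n). A
brute-force exact-rational CDF oracle cross-checks the routine in tests.
The threshold is `binom_inv(1−α, n, 1/c)·100/n`, rounded to 2 decimals for
reporting.

## Scale-downs in the test suite

Two acceptance properties run at reduced scale to fit a single-CPU budget,
fixed before any outcomes were measured: the effect-recovery cohort uses 12
epochs/subject (default 30; 20 repeated end-to-end runs), and the null
calibration uses 40 subjects × 12 noise features with SFS capped at 5 and a
5-fold inner cost CV (50 permutation runs per mode). Neither changes the
effect sizes or thresholds being tested.

## What a green suite establishes — and what it does not

The tests establish that every stage implements its stated contract: the
rejection rules fire exactly, PLV recovers the closed-form coupling within
Monte-Carlo error, graph metrics match exhaustive oracles to 1e−10, the
classifier detects a planted coupling difference above the binomial
threshold, and nested selection is calibrated under the null. They do not
establish anything about real EEG: the generator has no volume conduction,
no source leakage, no 1/f background, no non-stationarity, and no realistic
artifact morphology beyond amplitude pulses. Accuracies on synthetic cohorts
characterize the pipeline, not any clinical population.
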