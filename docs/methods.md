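# Methods

This document records the modeling assumptions, parameter defaults and
numerical design decisions behind `hrvarousal`. The target setting is
emergence from propofol–remifentanil anaesthesia: the question is whether
periods in which the Bispectral Index (BIS) is at or above 60 — "pre-arousal"
periods in which awareness becomes possible — can be recognised from
heart-rate-variability (HRV) features computed from the electrocardiogram
alone.

## Measurement design

T0 is the first BIS sample at or above 60 at or after the time anaesthetic
drugs are stopped. Measurements are taken at seven time points relative to
T0: −30, −20, −10, −5, 0, +2 and +5 minutes. Every row is labeled
`BIS>=60` (positive) or `BIS<60` (negative) from the BIS value at that time
point; by construction the T0 row is always positive. BIS is read
instantaneously by default; a trailing-60 s-median mode (`median60`) is
available for noisy traces. A reference design of 34 cases has availability
34/34/34/34/34/23/15 across the seven time points (208 measurements, 70
positive, 138 negative), the truncation at +2/+5 min reflecting electrode
removal after awakening; `simulate_study_table` reproduces exactly this
layout.

## Preprocessing

RR intervals (ms, sinus beats) are validated for positivity and plausible
range. Artifact/ectopic detection flags any beat deviating more than 20% from
the running median of the surrounding 11 beats; flagged beats are replaced by
linear interpolation between the nearest clean neighbours, and beat times are
rebuilt by cumulative summation. The cleaned tachogram is resampled to a
uniform rate by linear interpolation: 4 Hz for the epoch-based features,
8 Hz for the spectral features.

## HRV features

All eight features are computed on trailing windows ending at time *t*,
re-evaluated on a 1 s grid, and smoothed with a trailing 180 s moving
average (so a feature value at *t* summarises the preceding 3 minutes):

- **HR** — 60 000 / mean RR over the trailing 100 beats.
- **SDNN** — sample standard deviation of the trailing 100 RR intervals.
- **RMSSD** — root mean square of successive differences over the same window.
- **STV / LTV** — the trailing 60 s of the 4 Hz tachogram is split into 16
  epochs of 3.75 s; STV is the mean absolute successive difference of the 16
  epoch means, LTV their max − min range. STV ≤ LTV always holds.
- **LF / HF** — band energies of the trailing 64 s of the 8 Hz tachogram
  (512 samples) in [0.05, 0.15] Hz and [0.15, 0.4] Hz respectively (see
  "Wavelet band energies" below).
- **ANI** — the 512-sample window is mean-centred, normalized to unit energy,
  band-pass filtered to the HF band, and the area between the upper and lower
  envelopes (linear interpolation through local extrema) is measured on four
  16 s sub-windows. The minimum area AUCmin maps to
  `100 · (5.1 · AUCmin + 1.2) / 12.8`, clamped to [0, 100]; a flat window
  yields the floor score 9.375.

### Wavelet band energies

Band energies are computed with a depth-6 wavelet packet decomposition of the
centred 512-sample window (Daubechies `db8`, symmetric signal extension).
The 64 leaves are frequency-ordered (the natural packet order is
Gray-code-permuted), each leaf covering 0.0625 Hz at an 8 Hz rate. A band is
extracted by reconstructing from the leaves it overlaps, each leaf scaled by
the square root of its fractional overlap with the band, and the band energy
is the mean square of the reconstruction (≈ A²/2 for an in-band sinusoid of
amplitude A). The same reconstruction serves as ANI's band-pass filter.

Rationale: a plain discrete-wavelet-transform level-energy scheme cannot
separate these two bands by the required margin, because the dyadic level
edges at an 8 Hz rate (…, 0.125, 0.25, …) straddle the 0.15 Hz band boundary —
a 0.25 Hz tone leaks heavily into any level covering [0.125, 0.25] Hz. The
depth-6 packet basis has leaf edges every 0.0625 Hz, so the [0.15, 0.4] /
[0.05, 0.15] split is resolved up to one leaf's overlap. `db8` (16-tap
filters) keeps the leaf frequency responses sharp enough that a 0.25 Hz tone
carries ≈ 170× more HF than LF energy and a 0.10 Hz tone ≈ 12× more LF than
HF energy; an independent FFT periodogram oracle agrees on the dominant band
across the spectrum (tested away from the 0.15 Hz boundary itself, where any
finite filter splits energy).

## Variable selection

Pearson correlations and a PCA of the correlation matrix with
Kaiser-normalized varimax rotation (components retained by the Kaiser
eigenvalue > 1 rule unless a count is given) attribute the eight variables to
factors (|loading| > 0.6). Within a factor, for each pair correlated above
0.70 only one variable is kept, chosen by a declared domain-preference order;
a variable loading on no factor is kept with a warning. On study-shaped
tables this yields the uncorrelated set {SDNN, RMSSD, LF, HR, ANI}, dropping
LTV, STV and HF. Variance inflation factors of the kept set are reported.

## Logistic model

For each candidate, log-linearity in the logit is tested by a likelihood-ratio
test of a restricted-cubic-spline model (4 knots at the 5/35/65/95
percentiles) against the linear model; p < 0.05 triggers a log transform
(candidates are positive-valued). Tests that cannot be computed (singular
Hessian or separation on small tables) are reported as inconclusive with the
identity transform.

Selection is bootstrap backward-stepwise: B = 500 case-level bootstrap
resamples; in each, a full logistic model is fitted and the variable with the
largest Wald p is removed until all p ≤ 0.05; variables kept in ≥ 70% of
replicates form the final set. Single-class or non-estimable replicates are
redrawn; more than 20% redraws aborts the analysis as degenerate. The final
model reports odds ratios with 95% CIs, an AUROC with a DeLong CI (midrank
implementation), and a confusion report at the default probability threshold
0.39 (the Youden-optimal threshold is also reported). Univariate AUROCs use
the fitted single-variable model scores; for a perfectly separating variable
the AUROC is computed from the raw values (it is invariant to the monotone
link) and the odds ratio is reported as non-estimable.

## CART

A Gini-impurity decision tree, grown greedily with midpoint thresholds:
minimum 20 cases to split a node, minimum leaf size 7, and a split accepted
only if its root-share-weighted impurity decrease is at least 1% of the root
impurity (the usual complexity-parameter convention). Ties are broken by
declared variable order, then smaller threshold. No surrogate splits: a
missing value on a split variable is an error. Reports use the same
confusion/per-time-point structure as the logistic model.

## Synthetic data generator

The RR generator is an additive model: baseline RR (default 926 ms) plus an
LF sinusoid (0.1 Hz, 22 ms), an HF sinusoid (0.25 Hz, 12 ms) and white
Gaussian noise (16 ms), sampled at the running RR interval. A pre-arousal
state multiplies the three amplitudes by 1.3, cross-fading over 120 s around
the drug-stop time. The BIS trace is a sigmoid rising from deep-anaesthesia
to awake levels, calibrated to cross 60 exactly at the requested T0.
Artifacts are injected as doubled/halved/perturbed beats at a configurable
rate. `simulate_feature_table` instead draws measurement rows directly:
correlated latent normals with class-conditional shifts calibrated to the
study's summary statistics (log-normal marginals for the skewed variability
features, normal for HR and ANI) and a stated logistic truth, which supports
parameter-recovery tests.

Fidelity limits: the generator produces stationary sinusoid-plus-noise
tachograms, not real autonomic dynamics — no respiratory variation, no trends
within a state, no drug pharmacokinetics; BIS is a clean sigmoid with no
artifact. Effect sizes at the ±30 to ±5 min time points are weaker than in
clinical data (the pre-arousal shift is concentrated near T0), so synthetic
classification metrics should not be read as estimates of clinical
performance. Small cohorts (fewer than ~10 cases) are often near-separable
and can legitimately trigger the degenerate-bootstrap abort.

## Determinism and reporting

All randomness flows from a single root seed split per stage; two runs with
the same seed produce byte-identical report CSVs (timestamps are excluded
from reports). Every report header records a hash of the full configuration.
Reported metrics are rounded to 2 decimals for display; raw values are kept
in the result objects.

## Limitations

- The ANI computation follows the published envelope-area description, not
  the proprietary monitor implementation; absolute scores are comparable only
  within this package.
- The wavelet band energy is a filter-bank approximation; within one leaf
  width (0.0625 Hz) of a band edge, energy attribution is necessarily split.
- Complete-case handling only: rows with missing values are dropped per
  analysis; the CART has no surrogate splits.
- The bootstrap-stepwise procedure inherits the instability of stepwise
  selection; retention frequencies, not single fits, are the primary output.
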