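# hrvarousal

Heart-rate-variability (HRV) based prediction of pre-arousal periods during
emergence from general anaesthesia.

During recovery from anaesthesia, the Bispectral Index (BIS, an EEG-derived
depth-of-hypnosis score on 0–100) rising to 60 or above marks periods in which
a patient may become aware. This package implements an analysis chain that
asks whether such "BIS ≥ 60" periods can be recognised from the
electrocardiogram alone: eight HRV features are computed from the RR-interval
series on sliding windows, measurements are anchored to T0 (the first BIS ≥ 60
after anaesthetic drugs are stopped) at seven time points (−30, −20, −10, −5,
0, +2, +5 min), redundant features are removed by PCA/varimax plus correlation
screening, and two classifiers — a bootstrap-stepwise logistic model and a
CART decision tree — are fitted and reported with
sensitivity/specificity/PPV/NPV and AUROC. A synthetic-data generator makes
the full chain runnable without clinical recordings.

## The analysis chain

1. **Preprocess** (`hrvarousal.preprocess`) — validate an RR-interval series,
   detect artifacts/ectopic beats by deviation from a running median, replace
   them by interpolation, and resample the tachogram to a uniform rate.
2. **Features** (`hrvarousal.features`) — HR, RMSSD and SDNN on trailing
   100-beat windows; STV and LTV from 16 epoch means of the trailing minute;
   LF ([0.05–0.15] Hz) and HF ([0.15–0.4] Hz) band energies and the ANI
   (Analgesia Nociception Index, an envelope-area score of HF oscillations)
   on trailing 64 s spectral windows — all re-evaluated every second and
   smoothed with a trailing 3-minute moving average.
3. **Epoching** (`hrvarousal.epoching`) — detect T0 from the BIS trace, read
   the feature tracks at the seven time points, and label each measurement
   "BIS>=60" or "BIS<60".
4. **Selection** (`hrvarousal.selection`) — PCA on the correlation matrix with
   varimax rotation attributes variables to factors; within a factor, of any
   pair correlated above 0.70 only one is kept.
5. **Modeling** (`hrvarousal.modeling`) — restricted-cubic-spline
   log-linearity checks (with log transforms where indicated), bootstrap
   backward-stepwise logistic selection (retention ≥ 70% of 500 replicates),
   a final logistic model with odds ratios and AUROC, and a Gini-impurity
   CART; both report confusion metrics overall and per time point.
6. **Simulation** (`hrvarousal.simulate`) — an additive sinusoid-plus-noise RR
   generator with a pre-arousal autonomic shift, a BIS trace generator, and a
   study-shaped measurement-table generator.

## Worked example

```python
from hrvarousal import AnalysisConfig, analyze_table, simulate_study_table

table = simulate_study_table(seed=0)          # 208 rows, 34 synthetic cases
res = analyze_table(table, AnalysisConfig(bootstrap_replicates=200), seed=0)
print(res.summary())
```

Output (abridged):

```
Selected variables: HR, ANI, SDNN, RMSSD, LF

Bootstrap-stepwise logistic model of BIS>=60 periods
...
univariate AUROCs:
  HR: 0.55 [0.47-0.64]
  ANI: 0.68 [0.60-0.76]
  SDNN: 0.58 [0.50-0.67]
  RMSSD: 0.53 [0.44-0.62]
  LF: 0.60 [0.52-0.68]

bootstrap retention (B=200, threshold 0.7):
 * ANI: 0.99
   HR: 0.07
   LF: 0.20
   RMSSD: 0.12
   SDNN: 0.62

final model odds ratios:
  ANI: OR 0.96 [0.94-0.98] p=1.21e-05

TP=36  FP=34  TN=104  FN=34
Se=0.51  Sp=0.75  PPV=0.51  NPV=0.75
AUROC=0.68 [0.60-0.76]
...
CART model of BIS>=60 periods

ANI < 61.7409 (70 | 138)
  yes: ANI < 34.4428 (42 | 39)
...
TP=48  FP=17  TN=121  FN=22
Se=0.69  Sp=0.88  PPV=0.74  NPV=0.85
```

Signal-level usage:

```python
import numpy as np
from hrvarousal import RRSeries, sliding_features
from hrvarousal.preprocess import clean

rr = RRSeries.from_intervals(900 + 20 * np.random.default_rng(0).standard_normal(700))
rr_clean, mask = clean(rr)
tracks = sliding_features(rr_clean)   # per-second HR/ANI/STV/SDNN/LTV/RMSSD/LF/HF
```

## Command-line interface

```sh
hrvarousal simulate --cases 34 --seed 7 --out-dir cohort/   # synthetic cohort
hrvarousal run --out-dir results/ --seed 7 --cases 34       # end-to-end run
hrvarousal run --from-table table.csv --out-dir results/    # skip signal stages
hrvarousal analyze --from-table table.csv --out-dir out/ --exclude-t0
hrvarousal validate table.csv                               # schema/range checks
hrvarousal preprocess rr.csv --out clean.csv --report artifacts.csv
hrvarousal features clean.csv --out tracks.csv
hrvarousal epoch tracks.csv bis.csv --drug-stop 1800 --out rows.csv
```

All randomness flows from one root seed; two runs with the same seed produce
byte-identical report CSVs. Config files are flat YAML key–value maps
(`hrvarousal run --config fast.yaml`, e.g. `bootstrap_replicates: 100`), and
every report header records the config hash.

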