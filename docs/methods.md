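# Methods

`gaitfall` implements a fall-risk screening pipeline for tri-axial
acceleration recorded at the waist during a short walk at a self-chosen
pace. One recording per subject — vertical (V), mediolateral (ML) and
anterior-posterior (AP) axes in g units, with a binary faller/non-faller
label — is reduced to 168 gait features; ReliefF ranks the features; a
small multilayer perceptron, evaluated by stratified 10-fold
cross-validation, classifies subjects from the top-ranked subset.

## Preprocessing

Each axis passes through, in order:

1. **3-sample median filter** — suppresses single-sample spikes. Edge
   samples pass through unchanged (the shrunken-window convention), which
   touches only the first and last sample.
2. **Gravity removal** — the gravity component is estimated as the output
   of a zero-phase 4th-order Butterworth low-pass at 0.25 Hz and
   subtracted; the small residual offset left by filter edge transients is
   removed so body acceleration is exactly zero-mean over the record. The
   0.25 Hz cut-off sits well below the slowest plausible step frequency,
   so posture changes are tracked while gait content is untouched.
3. **Two band-passes** (zero-phase 4th-order Butterworth, applied
   forward-backward): 0.5-3 Hz for step-period detection only, and
   0.5-15 Hz for every feature — nearly all walking signal energy lies
   below 15 Hz. Zero-phase filtering keeps step-peak timing unbiased; a
   symmetric pulse's maximum moves by at most one sample.
4. **Max-normalization** — each axis of each version is divided by its
   maximum absolute value, making amplitude-sensitive features comparable
   across subjects and devices. The operation is idempotent and rejects
   all-zero axes with an error naming the axis.

## Step detection

Steps are local maxima of the normalized 0.5-3 Hz vertical signal with
minimum height 0.2 and minimum separation 0.25 s (supports cadences to
240 steps/min and prevents double counts on multi-lobed peaks). A step is
a peak-to-peak interval; a stride is two consecutive steps, paired without
overlap starting at the first accepted interval. Intervals outside
(0.25 s, 2.5 s) are dropped from the duration statistics — tolerating an
occasional missed peak — while their peak indices are retained for
slicing; consequently the identity "number of durations = number of peaks
− 1" holds exactly only when nothing is discarded. Fewer than 8 plausible
peaks (or fewer than 7 accepted intervals) raises a no-steps error and the
subject is excluded from the cohort matrix with a logged reason, not
imputed.

## Feature inventory (168 = 3 + 6 + 3 × 53)

* **Gait cycle (3, V only):** mean step duration, mean stride duration,
  cadence = 60 / mean step duration (steps/min).
* **Cross-axis (6):** Pearson correlation and sample covariance
  (n − 1 denominator) for V-ML, AP-ML and V-AP, computed on the
  full-length 0.5-15 Hz signals (correlation/covariance sit outside the
  per-step path).
* **Time domain (21 per axis):** per-step statistics — mean, SD, skewness,
  kurtosis (Pearson, non-excess), RMS, range, median, IQR, first-half and
  last-half means and SDs (odd-length slices give the midpoint sample to
  the first half), zero-crossing rate, energy, mean absolute value, mean
  absolute deviation — each evaluated on every step slice and averaged
  across steps; plus five whole-signal measures: the coefficient of
  variation of per-step peak amplitudes, step regularity (StpReg), stride
  regularity (StrReg), their ratio, and the mean trend. Regularity is the
  unbiased autocovariance (mean removed, normalized by lag 0) evaluated at
  the mean step/stride lag, maximized over integer lags within ±10% of the
  nominal lag — the lag grid rarely contains the mean period exactly — and
  clipped to [−1, 1]. Mean trend is the mean absolute value of a moving
  average whose window is the mean step duration; it vanishes for
  stationary zero-mean gait and grows with slow drift.
* **Frequency domain (32 per axis):** from a single whole-record
  periodogram with a Tukey taper (cosine fraction 0.5), density scaling,
  no detrending; every feature reads only the 0.5-15 Hz band. The two most
  prominent in-band peaks give F1/F2, amplitudes, widths at half
  prominence and prominences (a missing second peak falls back to zeros;
  a spectrum with no interior maximum contributes its global maximum with
  zero width/prominence). Shape descriptors use the audio conventions:
  centroid Σf·P/ΣP; spread the corresponding root variance; spectral
  skewness/kurtosis the standardized 3rd/4th weighted moments; flatness
  geometric/arithmetic mean (0 if any bin is zero); crest max/mean;
  decrease Σ_{k≥2}(P_k − P_1)/(k − 1) / Σ_{k≥2}P_k; slope the
  least-squares slope of P against f; 95% rolloff; normalized Shannon
  entropy. Band statistics cover mean/median/SD/max of the band, means and
  medians of its first (0.5-7.75 Hz) and last (7.75-15 Hz) halves, relative
  powers of 0.5-3, 3-8 and 8-15 Hz, total band power, the AmpF2/AmpF1
  ratio, and the median frequency. The "half-band" split at 7.75 Hz is the
  midpoint of the analysis band.

The per-axis registries are single fixed tuples
(`features_time.TIME_FEATURES`, `features_freq.FREQ_FEATURES`): the one
place to amend should an item need to change. The 168-name column order is
asserted at registry construction.

## Feature scaling

Columns are min-max scaled to [0, 1]; constant columns map to 0. Scaling
is fold-aware everywhere it matters: inside cross-validation the
parameters are fit on the training folds and applied to the held-out fold,
avoiding leakage. ReliefF receives a full-matrix scaling, which is what
its range-normalized difference assumes.

## ReliefF

Authored from scratch (`relieff.py`); scikit-learn plays no part in it.
The variant is deterministic all-instances ReliefF for two classes: for
every instance R, the K nearest same-class neighbors (hits) and K nearest
other-class neighbors (misses) under Manhattan distance over all features;
per feature f,

    W[f] -= Σ_hits |R_f − H_f| / (mK)
    W[f] += [P(miss) / (1 − P(class(R)))] · Σ_misses |R_f − M_f| / (mK)

with m the number of instances. On [0, 1]-scaled features every weight
lies in [−1, 1]; a constant feature scores exactly 0. Neighbor-distance
ties break by ascending subject index and ranking ties by registry order,
so results are permutation-invariant to 1e-12. K requires more than K
members in each class (each instance needs K hits besides itself); a K too
large for the cohort marks its grid row as skipped rather than failing the
sweep. The test suite checks the implementation against an independently
coded exhaustive oracle on all small datasets (n ≤ 12) to 1e-12.

The selection sweep computes one weighting per K (default 1..40) and
evaluates the top-N subset for every N (default 5..40) — the prefix
property `top_n(N) ⊂ top_n(N+1)` holds by construction — yielding a 40×36
grid of evaluation reports. The evaluation callback is injected, so the
sweep's structure is independent of the classifier's cost.

## Classifier and evaluation

A single-hidden-layer perceptron (scikit-learn `MLPClassifier`): ReLU
activation, SGD solver, L2 alpha 1e-4, at most 200 epochs, seeded
initialization; remaining hyper-parameters are the library defaults.
Hidden size is swept 10..200 in steps of 10 by default (analysis drivers
default to the single size 50 to keep the grid tractable; the sweep flag
restores the full range). One hidden layer is used: the hidden sweep is a
single neuron count, which is what a single-layer topology sweeps.

Evaluation is stratified 10-fold cross-validation (folds reduce to the
smallest class size with a warning when a class is smaller than 10). The
out-of-fold predictions of all folds are pooled into one confusion matrix
(positive class = faller) — integer counts that sum to the class totals —
from which accuracy, sensitivity and specificity are computed; AUC comes
from the pooled continuous scores (0.5 classification threshold plays no
role in it). Model selection over the (K, N, hidden) grid is
lexicographic: max accuracy, then max sensitivity, then min N, then min
hidden units, then min K. Preferring sensitivity on ties reflects the
screening use: missing a faller is the costly error.

Seeding: one global seed fans out deterministically — fold assignment from
the seed itself, per-fold MLP seeds from `seed·1000003 + fold`, per-cell
seeds from the (K, N) coordinates — so grid results are identical
regardless of execution order.

## Synthetic cohort generator

The generator (`synthetic.py`) emulates a one-minute walk: per axis,
harmonics 1..4 of a base frequency with fixed phases, modulated by
per-step amplitude scales, plus white noise, with 1 g added to V. V and AP
oscillate at the step frequency; ML at the stride frequency (half the step
frequency), reflecting left/right alternation. Step periods are
T0·(1 + σ_t·ε) with standard-normal ε clipped to [0.5, 1.5]·T0, and the
instantaneous phase advances linearly through each step, so timing jitter
widens spectral peaks and lowers autocovariance regularity exactly as it
does in real gait.

Class regimes: non-fallers σ_t = 2%, σ_a = 5%; fallers σ_t = 8%,
σ_a = 15% — a deliberately wide separation so end-to-end checks are
reliable. A "hard" regime (3%/6% vs 5%/9%) overlaps and exists for
robustness studies. Cohort subjects draw step frequency from U[1.6, 2.1] Hz
and jitters within ±20% of the class value; per-subject seeds are spawned
from the cohort seed, so cohorts are bitwise reproducible.

What the generator does **not** emulate: turns, stops, asymmetric left/
right dynamics, sensor tilt or drift, non-Gaussian artifacts, and the
correlation structure of real inter-subject variation. Passing tests
therefore demonstrate that the pipeline recovers planted structure under
controlled conditions — not that the reported study-level accuracies
transfer to a given clinical cohort.

## Problem sizes and numerical choices

* Test cohorts are 20-40 subjects of 20-60 s at 100 Hz; the acceptance
  script uses 41 subjects per class (so every K in 1..40 is valid) with
  30 s records, a coarsened subset-size grid {5, 10, ..., 40}, and hidden
  size 50. These sizes are the package's own choices for routine runs;
  the full study-scale sweep is available through the flags.
* A 20-subject cohort (10 per class) supports K ≤ 9 only; higher-K rows
  appear as skipped cells, preserving the 40×36 grid shape.
* Degenerate inputs fail loudly and early: all-zero axes, too-short
  records, single-class cohorts, constant-feature training sets and
  empty-class confusion matrices each raise a dedicated error.
* The permutation-null check runs at a fixed configuration rather than
  through model selection: selection maximizes accuracy and would bias
  the null estimate upward; the fixed-configuration estimate is centred
  on chance.
* Floating-point ties in ReliefF ranking and neighbor search are broken
  deterministically (registry order / subject index); autocovariance
  values are clipped to [−1, 1] since the unbiased estimator can exceed 1
  by rounding.

## Known limitations

* The 21-item time-domain and 32-item frequency-domain registries realize
  the stated category counts; item-level choices within those categories
  are this package's own and are centralized for amendment.
* Real recordings are accepted as CSV plus a manifest; the PhysioNet-style
  reader needs the optional `wfdb` package and is best-effort.
* No resampling or gap-filling: corrupted recordings are excluded, not
  repaired. No orientation auto-correction of mislabeled axes.
* With 10-fold CV on small cohorts the pooled counts have high variance;
  reported metrics on synthetic cohorts of n ≤ 40 should be read as
  demonstrations, not estimates with useful confidence intervals.
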