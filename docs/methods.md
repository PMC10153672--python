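# Methods

This note documents the models, conventions and design choices behind
`vidradiomics`, in the order of the pipeline.

## Synthetic video cohorts

The generator exists because lesion ultrasound videos cannot be shipped; it
plants the minimal statistical structure the pipeline claims to exploit —
class-dependent spatial texture, class-dependent temporal dynamics, and
class-shifted clinical covariates — without attempting physical beam
simulation (no point-spread function, attenuation, shadowing, Doppler or 3-D
geometry).

Each frame is a multiplicative-speckle image around a constant background
level `b = 180` (8-bit gray scale). The elliptical lesion interior has mean

```
m(t) = b · (1 − c · (1 + a · sin(2π f t)))
```

with contrast `c` (`0.35` negative class, `0.45` positive class — hypoechoic
lesions, the positive class slightly darker), relative modulation amplitude
`a = 0.3`, and temporal frequency `f` (`0.05` vs `0.20` cycles/frame). One
frame is one time unit; no physical frame rate is assumed, so all
frequencies are in cycles/frame and must lie below the Nyquist limit 0.5.
Tying the modulation to the contrast makes `c = 0` a true null case (the
lesion vanishes at every `t`), and with `noise_sigma = 0` the rendered
interior equals `m(t)` exactly — both are tested. Speckle is
gamma-distributed with mean 1 and per-pixel shape `(m/σ)²`, so the pixel
standard deviation is `noise_sigma` gray levels (default 8). The lesion
center drifts sinusoidally by ±1.5 px to keep the tracking stage honestly
exercised. Frames are float32 in [0, 255] in memory; the PNG writer rounds
to uint8.

Clinical covariates approximate a mid-size breast-cancer cohort: age
~N(52, 10.6²) clipped to [26, 83] years, lesion size ~N(2.36, 1.1²) cm
(+0.4 cm mean for the positive class), menopause Bernoulli(0.58), and
ordinal stage codes cN/cT/cTNM with the positive class receiving +0.15
probability of nodal involvement. Only size and cN are class-informative, so
the clinical branch is deliberately weak (test AUC typically 0.55–0.70 at
n = 200) — mirroring the usual situation where imaging carries most of the
signal. Labels: exactly `round(n · positive_fraction)` positives
(default fraction 0.32), shuffled by the seed. The same config and seed give
a bit-identical cohort.

What passing tests on these cohorts do **not** show: robustness to probe
motion, out-of-plane lesion loss, heterogeneous echotexture, multiple
lesions, or any claim that real HER2 classes differ by a sinusoidal
intensity modulation — the planted signal is a recoverable stand-in, not
biology.

## Tracking

The detector is a deliberately naive stand-in for a learned lesion detector:
threshold at 25 gray levels below (configurable; `bright` polarity
available) the frame median, take the largest connected component of at
least 25 px, return its bounding box; otherwise the frame is flagged
missing. ROIs are rectangular boxes (not pixel segmentations) throughout;
supplied truth masks can bypass the detector, in which case their tight
bounding boxes are used.

Cleanup: a box whose IoU with the element-wise median box of its centered
5-frame window (gaps skipped, window truncated at the edges) is below 0.3 is
rejected; rejected/missing frames are filled by coordinate-wise linear
interpolation between the nearest kept frames, with leading/trailing gaps
copying the nearest kept box. The window length, IoU threshold and linear
fill are package choices — the cleanup steps are standard but no canonical
thresholds exist. Decisions are made against a snapshot of the track, so
rejection is order-independent, and rejection followed by interpolation is
idempotent on coherent tracks. Coordinates are 0-based with both box
endpoints inclusive (a box (0,0)–(1,1) covers 4 pixels); interpolated
coordinates stay fractional until rasterization, which rounds to the
nearest pixel and clips to the frame with a warning.

## Static features (91 per frame)

Three families, concatenated in registry order; the registry is config-driven
but 91 = 19 + 28 + 44 is the tested default:

* **First-order (19)** — mean, median, min, max, range, variance, std,
  skewness, kurtosis (non-excess), energy Σx², RMS, histogram entropy
  (32 bins, log₂), uniformity Σp², 10th/90th percentiles, IQR, mean absolute
  deviation, robust MAD (within the 10–90th percentile band), coefficient of
  variation. Population (n) denominators everywhere; skewness, kurtosis and
  CV of a constant region are 0 by convention.
* **LBP (28)** — uniform rotation-invariant local binary patterns with
  bilinear-interpolated neighbors (tie convention: neighbor ≥ center → 1),
  at (P=8, R=1) → 10 bins and (P=16, R=2) → 18 bins. "Binary texture" is
  interpreted as LBP, the standard binary texture descriptor. Codes are
  computed on the full frame but histogrammed only over pixels whose
  complete neighborhood lies inside the ROI; an ROI too small for any such
  pixel yields an all-zero histogram.
* **GLCM (44)** — symmetric, normalized co-occurrence matrices at the four
  distance-1 offsets (0°, 45°, 90°, 135°), both pixels inside the ROI;
  11 statistics each: contrast, dissimilarity, homogeneity, angular second
  moment, energy (=√ASM), correlation (0 for zero-variance matrices),
  entropy (log₂), cluster shade, cluster prominence, maximum probability,
  sum average. Gray levels are quantized to 32 uniform bins over the
  **per-video** global ROI intensity range — per-frame ranges would inject
  artificial temporal variation into the feature curves. An offset with no
  valid pixel pair emits zeros.

All 91 outputs are finite on any nonempty ROI; the degenerate conventions
are exercised by tests on constant and single-pixel ROIs. The first-order,
GLCM and LBP implementations are validated against direct-definition,
pair-enumeration and closed-form oracles.

## Dynamic features (24 per curve, 2184 per video)

Per static-feature curve (≥ 8 frames required):

* **Time domain (14)** — mean, absolute mean, RMS, square-root amplitude
  `(Σ√|x|/N)²`, std, variance, max, min, peak-to-peak, skewness, kurtosis,
  waveform factor (RMS/abs-mean), crest factor (max|x|/RMS), impulse factor
  (max|x|/abs-mean). This is the standard condition-monitoring feature set;
  zero denominators give 0.
* **Frequency domain (10)** — from the one-sided FFT magnitude spectrum
  `P_k = |X_k|`, `k = 1..⌊N/2⌋`, `f_k = k/N` cycles/frame: dc (`|X₀|/N`),
  mean spectrum, center-of-gravity frequency fc, mean-square frequency msf,
  rmsf = √msf, frequency variance vf about fc, rvf = √vf, spectral skewness
  and kurtosis (moments about fc normalized by rvf³ and rvf⁴), and spectral
  entropy normalized by log₂K to [0, 1].

No windowing or detrending is applied by default (a linear-detrend flag
exists): the signal level lives in dc and the spectral moments exclude bin
0, so the moments are invariant to level shifts and to positive scaling of
the curve (tested, together with Parseval's identity and time-reversal
invariance). fc and rmsf lie in [0, 0.5]; msf ≥ fc² by Jensen's inequality.

## Modeling

* Split: unstratified uniform random, |train| = round(n · ratio), default
  ratio 0.8; a stratified option uses largest-remainder per-class quotas. An
  explicit seed makes the partition reproducible.
* Imaging branch: StandardScaler (train statistics) → PCA keeping the
  smallest component count with cumulative explained variance ≥ 0.95 →
  classifier. Standardization before PCA is necessary because the dynamic
  features span ~10 orders of magnitude (energy of an intensity curve vs a
  spectral entropy); without it the PCA would be dominated by raw scale.
* Clinical branch: age and size standardized with training statistics; the
  ordinal codes meno/cN/cT/cTNM enter as integers; classifier on top.
* Base classifiers (seeded, fixed documented defaults, no tuning):
  SVM (RBF, C=1, probability via internal CV), random forest
  (200 trees), logistic regression (C=1, lbfgs), XGBoost (200 trees,
  depth 3, learning rate 0.1). Probabilities are class-1
  `predict_proba`.
* Fusion: element-wise `w·p_imaging + (1−w)·p_clinical`, default w = 0.5 —
  chosen for transparency over stacking; a weighted average keeps each
  branch auditable and makes the no-fusion cases (w ∈ {0, 1}) exact
  identities. Decision threshold τ = 0.5, ties called positive.
* The 4×4 grid fits all four kinds per branch once, evaluates the 16 fused
  pairs and the 8 single-branch models on train and test, and reports the
  best fused pair by test AUC (ties: higher test Youden index, then
  lexicographic kind names).

Leakage control: every fitted statistic (scaler, PCA, classifiers) is a
function of training rows only; a test asserts that perturbing test rows
and refitting leaves all artifacts bit-identical. Feature matrices are
copied to C-contiguous layout on entry so fitted statistics do not depend
on the caller's array memory layout.

## Evaluation

AUC is the Mann–Whitney concordance (ties count ½), validated against an
all-pairs oracle; SEN/SPC/ACC/YI come from the confusion table at τ with
the identities YI = SEN + SPC − 1 and ACC = (TP+TN)/n enforced exactly.
Confidence intervals are percentile bootstrap (B = 1000, size-n resamples
with replacement, level 0.95); a resample lacking a class is redrawn up to
10 times then skipped with a warning. The multi-model comparison draws R
(default 1000) resamples of size m (default: the test-set size) **once per
repetition**, evaluates every model on the same indices (paired), and
reports two-sided paired t-tests on AUC, ACC and YI. With-replacement
resampling was chosen over repeated subsampling; a flag is not exposed
because the paired structure is what matters for the comparison.

## Problem sizes

The default validation cohort is 200 cases of 64 frames at 128×128 px
(~2–3 minutes to featurize on one CPU); unit tests use 6–12-case cohorts at
96×96/16 frames. The acceptance script runs the 200-case pipeline once.

## Known limitations

* The naive detector assumes a single, roughly convex, hypo- or
  hyper-echoic lesion; it is a placeholder for a learned detector, and real
  ultrasound would need one.
* The 19/28/44 allocation of the 91 static features and the 14+10 dynamic
  set are canonical choices from the radiomics and signal-condition-
  monitoring literature; other registries are possible and the code is
  registry-driven.
* Synthetic cohorts are easy by design at the default settings (the imaging
  branch saturates near AUC 1.0); they validate correctness and wiring, not
  clinical performance.
* No calibration, DeLong variance, decision-curve analysis, or
  hyperparameter search beyond the 4×4 kind grid.
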