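# Methods

## Problem and pipeline

The package classifies solitary pulmonary nodules (SPNs) on CT as benign or
malignant from texture plus clinical covariates, and tracks how texture
changes over follow-up. The pipeline is: ROI segmentation → 3-scale
curvelet decomposition → co-occurrence texture features → SMOTE balancing →
RBF-SVM → patient-level ROC; plus a first-vs-last-scan texture-change
analysis. Every stage is deterministic given its seed.

## Curvelet tight frame

The decomposition partitions the 2-D frequency plane of a zero-padded
square image (default 64 × 64; inputs are padded, never resampled) into

* a low-pass **coarse** window `L(r)`,
* 32 **detail** wedges `M(r)·A_w(φ)` at the middle scale, and
* a high-pass **fine** window `H(r)`,

for a total of 1 + 32 + 1 = **34 sub-bands**. Radially, `L` and `H` use
Meyer-polynomial cosine/sine transitions over |f| ∈ [0.08, 0.16] and
[0.25, 0.45] cycles/pixel, and `M = √(1 − L² − H²)`, so the squared radial
windows sum to one exactly. Angularly, smooth cosine bumps of width two
wedge spacings are centred at `(w + ½)·π/32` on the angle **mod π** and
normalized by `√(Σ_w A_w²)`, making the squared angular partition exact and
every window centro-symmetric. Consequences:

* coefficients of a real image are real (each wedge covers both antipodal
  half-wedges);
* `Σ_b ‖c_b‖² = ‖x‖²` (Parseval) and the adjoint reconstructs `x` to
  machine precision — both are asserted at 1e-6 in the tests, far above the
  observed ~1e-15 error;
* sub-band order is fixed: coarse, detail wedges counter-clockwise from
  angle 0, fine.

Wedge coefficients are kept at full grid size (no wedge wrapping); feature
code nevertheless treats sub-band shape as opaque. Images smaller than
32 × 32 are rejected — three radial scales need that much bandwidth.

## Texture features

Per sub-band, raw real coefficients (an optional magnitude mode exists) are
quantized into `N_g = 64` equal-width bins over the band's own min–max
range (a constant band maps to level 1). A symmetric co-occurrence matrix
is counted at each of the four unit offsets and the 14 statistics are
computed per offset and averaged. Definitions follow the standard
co-occurrence forms with base-2 logarithms and `0·log 0 = 0`; Correlation
is defined as 0 when a marginal variance vanishes (determinism over
convention). "Mean"/"Standard Deviation" are co-occurrence marginal
moments, applied uniformly, not first-order sub-band statistics. The
resulting 476-entry block is named `s{scale}_w{wedge}_{feature}`; appending
age, sex, smoking and the nine morphology covariates gives the 488-entry
model input.

Every feature is validated against an independent brute-force double-loop
oracle at 1e-10, and the co-occurrence counting against scikit-image's
`graycomatrix`.

## Segmentation

Region growing is 4-connected breadth-first search from a seed (default:
foreground centroid), FIFO frontier with neighbours visited in row-major
order, accepting a pixel when its intensity is within `tol` of the running
region mean (updated after every acceptance). 8-connectivity is available.
The criterion and connectivity are package choices — documented, not
inherited. The pipeline default `tol = 60` accepts the full nodule texture
range while excluding zero background at the default intensities.

## Synthetic cohorts

The generator stands in for an undeposited clinical archive; its texture
mechanism (elliptical mask, Gaussian-smoothed noise, radial spicule ridges)
is chosen for controllability, not CT physics.

* **Default class recipes** (chosen once as the study conditions): benign —
  base 120, noise sd 6, smoothing σ 0.5 px, 2 spicules, drift
  +0.8/month; malignant — base 140, noise sd 14, smoothing σ 0.7 px,
  8 spicules, drift 0. The benign smoothing is deliberately light so that
  the drifting noise component carries energy at the detail scale, where
  the longitudinal StdDev analysis reads it; heavier smoothing would
  low-pass the drift out of the measured band.
* **Demographics** reproduce the reference cohort's class-conditional
  marginals: age N(50.8, 13.26²) benign / N(62, 11.54²) malignant, clamped
  to [18, 95] (clamps logged); smoking 39.62% / 49.53%; male 54.72% /
  59.91%. Morphology covariates are Bernoulli — (0.2, 0.6) for
  spicule/lobulation/vacuole, 0.5 otherwise, all configurable; their
  real-world coding is unknown, so binary placeholders are used.
* **Follow-up**: each patient's total follow-up is lognormal with
  μ = ln(median), σ = √(2 ln(mean/median)), matching the configured mean
  6.9 and median 2.0 months; scans are evenly spaced over it. All scans of
  a patient reuse the same per-nodule seed: a follow-up scan images the
  same lesion (same shape, spicules, noise realization), and only the noise
  amplitude changes with `drift_per_month`. Malignant deltas are therefore
  exactly zero under the default drift of 0.
* **Overlap scenario** (`OVERLAP_BENIGN/`, `OVERLAP_MALIGNANT`): classes
  share geometry and differ only in noise sd (8 vs 11) — used for the
  imbalance/recall experiments, where single-ROI classification must be
  genuinely error-prone.

What passing tests on these cohorts show: the pipeline detects texture
differences and longitudinal drift of the kind it was built for, with
correct bookkeeping and statistics. What they do not show: performance on
real CT, where noise is structured, nodule appearance is far richer, and
class differences are much subtler.

## Balancing

SMOTE is implemented directly (neighbour search delegated to
scikit-learn's `NearestNeighbors`): per minority row, `rate/100` synthetic
rows on the segment to one of its k = 5 nearest same-class neighbours;
`|synthetic| = (rate/100)·m` exactly. `balance_dataset` reaches an
arbitrary per-class target by over-sampling at the next multiple of 100%
and uniformly subsampling the surplus (seeded). The published row counts
this package reproduces grew *both* classes (3131 benign and 6977 malignant
ROIs both reaching 9393), which standard minority-only SMOTE cannot do;
the explicit-target mechanism covers it without asserting how the original
analysis was run. Binary covariates are interpolated as continuous by
default; a `round_binary` option exists. Distances are computed on raw
features by default (z-scored optional).

## Classifier and evaluation

* The SVM dual is solved by scikit-learn's `SVC` (solver tolerance 1e-7);
  the package stores support vectors, signed weights, bias, γ and the
  z-scoring parameters, and evaluates the kernel-sum decision function
  itself. Tests compare this evaluation against both a brute-force loop and
  `SVC.decision_function`.
* Defaults `C = 1`, `γ = 1/(d·var)` on z-scored features are package
  choices; only the kernel family is inherited from the analysis being
  reproduced. Scaling statistics are learned on training folds only.
* Cross-validation is stratified; the default `patient` grouping keeps all
  ROIs of a patient in one fold (no leakage), with `roi` mode available.
  When `k` exceeds the smallest class count (e.g. leave-one-out),
  stratification is infeasible and plain shuffled folds are used — folds of
  size ≲ 1 per class satisfy the proportion contract trivially.
* **Malignance rate** = (# ROIs predicted malignant)/(# ROIs). The source
  analysis's formula for this quantity is not printed in the available
  text; this reading is an assumption, stated here prominently. Patient
  benign/malignant calls, where needed, threshold the rate at 0.5.
* ROC: threshold sweep over unique scores (predict positive at
  score ≥ threshold); AUC by trapezoid, equal to Mann–Whitney
  `U/(n₊n₋)` with half credit for ties; p-value from the tie-corrected
  normal approximation of U against AUC = 0.5.
* 2 × 2 contingency tests use Pearson chi-square **without** continuity
  correction — the convention that reproduces the reference statistics
  (2.79 for smoking, 0.78 for sex); Yates-corrected values (≈2.41, ≈0.62)
  do not match. The reference age statistic (46.37) is not reproduced: the
  test behind it is unstated and the raw ages are unavailable.
* Longitudinal analysis tracks the mean of the 32 detail-band StdDev
  features, averaged over each scan's ROIs; delta = last − first per
  patient, summarized per class with a normal 95% CI. Single-scan patients
  are excluded with a logged warning.

## Problem sizes

Defaults were sized for quick, repeatable desk runs: demo cohorts of 40
patients (3–5 ROIs each), follow-up cohorts of 10–20 patients per class
with 2 scans, 64 × 64 ROIs, 100-image frame checks, 50-matrix and
200-score-set oracles, and 5-seed paired recall experiments. A full demo
run completes in seconds on one CPU.

## Known limitations

* The synthetic texture model is a stand-in; no claim is made about CT
  acquisition physics, 3-D structure, or DICOM handling.
* The curvelet construction fixes one specific wedge layout (1 + 32 + 1);
  only the total of 34 sub-bands is externally constrained.
* Real-data headline performance (AUC ≈ 0.95, 80% → 97% balanced-accuracy
  gain) is not reproducible without the original images and is not
  attempted; the corresponding properties are demonstrated qualitatively on
  synthetic cohorts instead.
* SMOTE interpolates categorical covariates as if continuous unless
  `round_binary` is requested.
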