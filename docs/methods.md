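# Methods

## The diagnostic question and the unit of analysis

The pipeline decides, per *lesion*, whether a pigmented skin lesion already
selected for biopsy should actually be excised. Several Raman measurements
are taken per lesion (at least two, more on larger lesions), because a
single point can miss the cancerous part; the clinical decision rule is the
OR rule — recommend biopsy if *any* measurement looks malignant. All
cross-validation, ROC construction and screening metrics therefore operate
on lesions, with the lesion posterior defined as the maximum of its
measurements' probabilities. Thresholding that maximum is exactly
equivalent to the OR rule at every threshold (property-tested).

## Synthetic cohort generator

No raw dataset of this design is deposited, so every stage runs against a
generator whose defaults encode the study conditions: 53 pigmented lesions
on 51–53 patients and 7 melanomas, 52 patients in total (a few carry two
lesions), expected measurement totals ≈158 and ≈27 (per-class means 158/53
and 27/7, realized as 2 + Binomial(4, p)), and 1980 grid points on
800–1790 cm⁻¹.

A measurement is rendered as

    y(ν) = Σ_c w_c B_c(ν) + b(ν) + ε(ν) + spikes

* **Constituent bases** `B_c`: eight unit-area sums of Gaussian bands at
  standard skin Raman shifts (CH2/CH3 deformation ~1440–1450 for lipids,
  Amide III ~1245–1270 and 855/940 cm⁻¹ for collagen, 1003 phenylalanine,
  Amide I ~1650–1665, broad melanin 1380/1580 and water ~1640 bands). Band
  coordinates live in config, not code.
* **Class effect**: melanoma mean weights raise collagen (1.0→1.2) and
  lower triolein (1.0→0.7), with smaller melanin/ceramide/DNA changes and a
  +10 cm⁻¹ shift of the collagen Amide III band. At the default lesion-level
  dispersion (CV 0.25) these are 0.8–2 standard-deviation shifts —
  overlapping class distributions, i.e. a moderate effect. Note that the
  *best-over-9,948-subsets* AUROC on such cohorts is still typically ≈1.0:
  exhaustive selection over thousands of models ranks 60 lesions very
  easily. That optimism is itself part of the phenomenon under study and is
  what the randomization null quantifies.
* **Hierarchy**: weights are drawn once per lesion (Gaussian around the
  class mean, CV 0.25, truncated at 0) and jittered per measurement
  (CV 0.10), so measurements of one lesion co-vary.
* **Artifacts**: an order-5 polynomial fluorescence baseline in the
  wavenumber coordinate rescaled to [−1, 1] (constant term 0.02–0.05,
  several-fold above the ~0.005 mean Raman signal of a unit-area mixture;
  shifted to be non-negative), i.i.d. Gaussian noise (sd 4·10⁻⁴, ~1–2% of
  peak height), and Poisson(0.3) single-point cosmic spikes of 5–20× the
  spectrum maximum.
* **Randomness**: one seed per cohort; each lesion uses a deterministic
  sub-stream keyed by its index, so a single lesion can be regenerated
  without replaying the cohort.

What the generator does *not* emulate: instrument line-shape and wavenumber
miscalibration, detector etaloning, patient-level covariance beyond lesion
identity, melanin fluorescence saturation, and any real biochemical
inverse model. Passing tests therefore demonstrate the machinery is
correct and calibrated on data with this structure — not clinical
performance.

A `null_config()` sets both class means equal and the Amide shift to zero,
making labels independent of spectra by construction.

## Preprocessing

Stages in order (each per spectrum; order fixed and tested):
dark subtraction → cosmic-ray removal → Savitzky–Golay smoothing →
modified-polynomial baseline subtraction → intensity-response correction →
crop to [800, 1790] cm⁻¹ inclusive → area normalization (trapezoid area 1).
The whole chain is positively homogeneous before normalization, so scaling
a raw spectrum by any positive constant leaves the preprocessed spectrum
unchanged (tested to 1e-10).

* **Cosmic rays**: a point is flagged when its residual against a running
  median (window 5, reflect padding so edge spikes cannot become their own
  median) exceeds 8 robust standard deviations (1.4826·MAD) *and* 5% of the
  spectrum's intensity range. The amplitude floor is deliberate: in
  noiseless smooth spectra the MAD is set by curvature and the bare k·MAD
  rule would flag peak tops; genuine spikes (5–20× max) clear the floor by
  orders of magnitude. Flagged points are repaired by linear interpolation
  across unflagged neighbours; if more than 5% of points flag, the spectrum
  is returned unchanged with a QC warning.
* **Smoothing**: Savitzky–Golay, window 11, polynomial order 3 (window 1
  disables). Endpoints use the fit on the truncated window, so polynomials
  up to the filter order pass through exactly.
* **Fluorescence baseline**: iterative modified polynomial fit of order 5.
  Each iteration clips the *original* spectrum against the current fit
  (intensities above the fit are replaced by it) and refits; iteration
  stops when the maximum change of the fit, relative to its maximum
  magnitude, drops below 1e-4 (cap 100 iterations; non-convergence is
  flagged, not raised). Clipping against the original rather than the
  cumulatively clipped spectrum was chosen because cumulative clipping
  locks in early downward excursions and roughly doubles the recovery
  error on ground-truth baselines (3.1% → 1.5% pooled relative RMS over
  100 seeded peaks-over-polynomial spectra). The fit uses a QR-factorized
  Vandermonde design on the [−1, 1]-rescaled abscissa, factorized once per
  spectrum.
  Any baseline estimator necessarily absorbs the smooth part of the
  signal: on artifact-free mixtures the preprocessed spectrum equals the
  pure mixture only up to an additive order-5 polynomial (tested as such,
  residual < 2% RMS).
* **Response correction**: division by the lamp-calibrated relative
  sensitivity curve normalized to unit mean (scale-free). Wavenumber
  calibration is reduced to the affine grid the files carry; no
  calibration-standard fitting is performed.

## Classification

* **PCA** per LOLO-CV fold, mean-centering only (no variance scaling —
  spectra are already area-normalized and share units), thin SVD, sign
  convention "largest-magnitude loading positive", components ordered by
  explained variance. The held-out lesion never enters the mean or the
  rotation (leakage-tested). Because PCA ignores labels, per-fold
  projections are computed once and reused across all candidate subsets
  and all label permutations; equality with naive per-subset refitting is
  asserted to 1e-10.
* **Candidate models**: every subset of ≤ 6 of the first 15 PCs (9,948),
  the one-in-ten rule at 60 lesions. Subsets are ordered by (size,
  lexicographic); ties in AUROC (within 1e-12) are broken toward the
  smallest, lexicographically first subset.
* **Logistic regression**: ridge-penalized maximum likelihood,
  λ = 10⁻⁴ on the coefficients (intercept free). The tiny ridge guarantees
  a finite optimum under separation — common at n = 60 — while leaving the
  ranking essentially untouched. The solver is a damped Newton iteration
  batched across all folds simultaneously (the subset search performs
  ~600,000 fits of ≤ 7 parameters; per-fit library overhead would dominate
  otherwise), with per-fold step halving and convergence declared at
  gradient max-norm < 1e-11; increases below the float resolution of the
  objective are accepted during backtracking, otherwise quadratic
  convergence stalls one ulp from the optimum. The fit is verified against
  scikit-learn (C = 1/(2λ)) and a coarse-to-fine grid optimizer.
* **Known small-sample artifact**: with very few positive lesions, leaving
  out a melanoma lowers the training prevalence and hence the intercept, so
  on *uninformative* features held-out melanomas score systematically low
  — null-cohort AUROCs sit below 0.5 rather than at it. This biases the
  null conservative (downward), not the real-effect estimate.

## Evaluation

ROC thresholds are the unique posterior values in descending order with a
+∞ sentinel; "positive" means posterior ≥ threshold, so exact ties are
biopsied — the conservative policy for a cancer screen. AUROC is computed
by the trapezoid rule and equals the tie-corrected Mann–Whitney statistic
(property-tested to 1e-12). The reported operating point is the minimum
melanoma posterior: the most specific threshold with sensitivity 1.
Screening metrics: NNT_before = N/(TP+FN), NNT_after = (TP+FP)/TP,
biopsies avoided = TN/(TN+FP); stored at full precision, displayed at one
decimal. The ROC confidence band is a stratified percentile bootstrap over
lesions (resampling within class, default 2000 replicates, seeded),
evaluated as the sensitivity envelope on a fixed specificity grid.

## Randomization null

Each replicate assigns the melanoma label to n_positive (default 7)
uniformly random lesions — drawn against the sorted lesion-id list, so
results do not depend on storage order — and reruns the *entire*
best-over-subsets search, giving the null the same selection advantage as
the real analysis. Cached fold projections are reused (labels only enter
the logistic stage; asserted against a from-scratch replicate). The
exceedance at a cutoff is the fraction of replicates strictly above it.
Degenerate replicates (a fold left single-class) are redrawn, capped at 3×
the replicate count. The default pipeline run scales the null to 20
replicates over subsets of ≤ 2 of the first 5 PCs; the full space is a
config option.

## Pipeline and reproducibility

One root seed drives named sub-streams (simulate / bootstrap / randomize),
so stages can be rerun independently; every artifact records a hash of the
resolved configuration, and rerunning a configuration reproduces
`metrics.json` byte-for-byte (no timestamps in artifacts; timing goes to
the log). `report.md` is regenerated purely from on-disk artifacts and
verifies the posteriors file against its recorded checksum. Configuration
files are YAML; validation is explicit per-field with named errors.

## Problem sizes used in the test suite

Unit tests run on coarse-grid cohorts (300–1200 points, 6–18 lesions);
the end-to-end recovery checks use the full study-scale cohort (60
lesions, 1980 points, all 9,948 subsets) and a 20-replicate reduced-space
null. The full suite completes in about two minutes on one core.

## Limitations

* Best-subset AUROC is reported without shrinkage; it is optimistically
  biased by construction, and the package's own null shows by how much.
* The generator's Gaussian-band, linear-mixture world is far simpler than
  tissue; calibration results transfer to real spectra only qualitatively.
* No patient-level stratification: permutations and bootstrap treat
  lesions as exchangeable, matching the analysed design (60 lesions, a few
  shared patients) but not a per-patient sampling model.
* Grids must match exactly across a cohort; resampling between grids is
  out of scope.
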