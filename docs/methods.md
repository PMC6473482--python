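# Methods

This note records the models behind `ramancell`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer should know about.

## 1. The synthetic single-cell Raman model

A live single-cell Raman spectrum is modelled, per acquisition window, as

I(ν̃) = Σ_b A_b exp(−(ν̃ − c_b)² / 2σ_b²) + f·B(ν̃) + a·Q(ν̃) + ε(ν̃) + spikes

* **Bands.** 35 Gaussian bands (`catalog.BAND_CATALOG`) with standard
  literature assignments spanning the fingerprint (748–1725 cm⁻¹) and
  CH-stretch (2850–3060 cm⁻¹) regions.  Pure Gaussians are used throughout
  (the band decomposition downstream fits Gaussians, so generator and
  analysis share one band shape); Lorentzian/Voigt profiles are deliberately
  out of scope.
* **Per-cell amplitudes.** A_b is log-normal around the cell-line profile
  mean with coefficient of variation 0.36 (0.12 for the four Amide I
  sub-bands, which act as the per-cell protein anchor that normalisation
  divides by).  Three band families fluctuate around a shared latent factor
  (weight 0.65) so their amplitudes correlate across cells the way
  resonance/composition families do in real data: the cytochrome C series
  (748, 1128, 1175, 1310, 1585 cm⁻¹), a nucleic-acid/phosphate series (782,
  810, 828, 1095, 1338 cm⁻¹) and a lipid CH series (1438, 2850, 2885 cm⁻¹).
  The resulting within-family sample correlations exceed the 0.3 reporting
  threshold of the correlation analysis at n = 300; cross-family
  correlations stay below it.
* **Class profiles.** Per-class multipliers on the base amplitudes encode
  the qualitative biochemistry of the five lines: nucleic-acid/phosphate
  intensity ordered HL60 > HCT116 > SW620 > HT29 > SW480; lactate
  (1725 cm⁻¹) rising and CH₂ stretch (2850 cm⁻¹) / CH-stretch above
  2900 cm⁻¹ falling with adenocarcinoma stage (SW480 → HT29 → SW620);
  SW620 richer in β-sheet, α-helix, saccharides and double bonds, SW480 in
  disordered protein structure and overall CH intensity; HCT116 with low
  CH₂-symmetric and cytochrome intensity but the highest lactate.  The
  numeric values are **calibration constants**: the magnitudes of the
  between-class contrasts and the amplitude CV were fixed once so that the
  default datasets reproduce the study-scale classification accuracies
  (~99 % two-class PCA/LDA, ~94–95 % five-class), and are versioned in
  `catalog.py`, not derived from first principles.  Per-class spectral
  variance is not published for the real system; 36 % per-band CV is a
  realistic single-cell heterogeneity level and is what the calibration
  settled on.
* **Instrument.** 1 cm⁻¹ grid over two windows (300–1800, 1800–3200 cm⁻¹)
  sharing exactly one channel at 1800 cm⁻¹; additive Gaussian noise
  (sd 0.02 in units of the Amide I height); Poisson cosmic-ray spikes
  (rate 0.5 per window, single channel, 10–50× the local signal); a
  2nd-order polynomial fluorescence baseline with a per-cell log-normal
  scale; a broad quartz substrate band (centre 480 cm⁻¹, σ = 45) mixed with
  the per-cell coefficient *a* that the preprocessing must recover; and a
  per-experiment wavenumber mis-calibration (sd 1.5 cm⁻¹, clipped at
  ±5 cm⁻¹) shared by all spectra of an experiment and encoded in that
  experiment's silicon reference.
* **Experiment structure.** Cells are grouped into experiments of ≤ 82
  cells, each with five cell-free background spectra per window and one
  silicon spectrum, mirroring how such data are acquired session by
  session.  Default per-class counts are 163/167/89/190/71 (680 cells).
* **Truth records.** Latent amplitudes, baseline scales, spike channels and
  background coefficients are stored per cell for parameter-recovery tests.

What the generator does **not** emulate: confocal depth profiles, laser
power and photobleaching kinetics, cell size/morphology, detector
non-linearity, peak-position shifts between classes (class information is
purely amplitude-borne), and non-Gaussian band shapes.  Passing tests on
synthetic data therefore demonstrate that the *pipeline* is correct and
well-calibrated, not that real cells are classifiable at these accuracies.

## 2. Preprocessing chain

Fixed order (recorded in each spectrum's provenance): despike → calibrate →
zero-offset → background subtraction → Savitzky–Golay smoothing → stitch →
truncate [730, 3100] → baseline correction → excise (1750, 2800) →
Amide-I normalisation; the chemometrics branch additionally truncates the
CH window at 3000 cm⁻¹ and applies SNV.  Interval endpoints are closed:
channels at exactly 730, 1750, 2800, 3100 cm⁻¹ are retained (1322 channels
on the band-analysis grid, 1222 on the chemometrics grid).

* **Despiking.** A channel is replaced by its 5-point running median when
  (i) the modified z-score of its second difference exceeds 8, (ii) its
  residual against the running median exceeds 8 robust sd, and (iii) that
  residual dominates both neighbours' residuals by 3×.  Criterion (iii)
  distinguishes single-channel cosmic rays from sharp genuine bands (e.g.
  phenylalanine at 1001 cm⁻¹, σ = 4 cm⁻¹), which elevate adjacent channels
  too.  Robust scales are floored at 10⁻³ of the intensity range so
  noise-free spectra are left untouched.
* **Calibration.** δ = 520.5 − argmax_parabolic(silicon), the same δ for
  both windows of every cell in the experiment.  3-point parabolic
  interpolation of a σ ≈ 3 cm⁻¹ line sampled at 1 cm⁻¹ recovers shifts to
  well within 0.01 cm⁻¹.
* **Background subtraction.** The five per-experiment backgrounds are
  despiked, zero-offset and averaged; the scale *a* is fitted by least
  squares on 430–530 cm⁻¹ **jointly with a local linear term**.  The linear
  term absorbs residual fluorescence and the vertical translation applied
  earlier, which would otherwise bias *a* by 10–20 %; with it, recovery of
  the true mixing coefficient has < 2 % mean absolute error at default
  noise (the contract is < 5 %).  The same *a* is applied to the CH window,
  whose grid does not cover the quartz band.
* **Baseline.** Iterative asymmetric penalized least squares
  (second-difference penalty, banded Cholesky solve), λ = 10⁵,
  p = 0.01, ≤ 50 iterations, stopping when the asymmetric weights converge
  (mean change < 10⁻⁶); non-convergence yields a warning and the best
  estimate.  The published description of the original baseline routine
  does not include its parameters, so this standard algorithm with
  truth-recovery acceptance (fitted baseline within 5 % RMS of the known
  generator baseline over band-free channels) stands in its place.
* **Stitching.** The CH window is offset so both windows agree in mean
  intensity on their overlap (one shared channel at 1800 cm⁻¹ by default),
  then overlap channels are averaged; abutting windows are concatenated; a
  gap wider than 2 channels is an error.
* **Resampling.** Truncation interpolates onto the canonical integer grid,
  because calibration leaves each experiment's axis offset by a sub-channel
  amount and the feature matrix needs common columns.
* **Normalisation.** Amide I = max of the corrected intensity on
  1600–1690 cm⁻¹ (peak height, not fitted area — robust and
  order-independent); SNV uses the sample standard deviation (ddof = 1)
  per spectrum, the conventional per-spectrum reading of SNV.
* **Failures.** Any stage error skips that cell with a logged reason; the
  dataset proceeds.

## 3. Classifiers and evaluation

* **PCA/LDA.** Mean-centred PCA (full SVD), 25 components, sign-fixed so
  each loading's largest-magnitude element is positive.  For every
  unordered class pair a Fisher discriminant is built from the pooled
  within-class covariance of the PC scores (ridge 10⁻⁶ × trace/p on the
  diagonal); prediction is one-vs-one majority vote, ties broken by the
  largest summed margin.  Five classes give exactly 10 pairwise
  discriminants.
* **Trees.** Single CART (Gini) on raw channel intensities, split
  wavenumbers reported.  The small-tree ensemble is AdaBoost over depth-≤2
  CART trees (50 rounds) with a per-wavenumber selection-frequency table —
  a transparent stand-in for proprietary rule-boosting implementations,
  chosen because the quantity of scientific interest is which wavenumbers
  the small trees keep choosing, not the exact boosting variant.
* **SVM.** Linear kernel, C = 1, one-vs-one for k > 2 (other kernels were
  reported to perform equivalently on this problem, so only linear is
  implemented).
* **Cross-validation.** Stratified 10-fold, 5 repetitions with
  re-randomised folds; *everything* data-dependent, PCA included, is fitted
  inside training folds (SNV is per-spectrum and therefore exempt).
  Accuracy is reported as mean ± σ/√N over the N = 50 fold estimates.
  Stratification is used because the smallest class has 71 cells.  A
  `leaky_pca` flag reproduces the variant that computes PCA once on the
  full data — only to quantify the leakage bias, never as a default.
* **Learning curve.** Mean ± SE accuracy over 100 random stratified
  resamples per training size with a 50-cell test group, fitted with a
  saturating Weibull sigmoid whose saturation parameter is bounded at 100 %.

## 4. Stage-trend PLSR

Spectra of the colorectal adenocarcinoma lines are regressed on ordinal
Duke-stage codes (SW480 → 1, HT29 → 2, SW620 → 3) with SIMPLS-style PLS
(10 components by default).  Components are oriented so scores increase
with stage.  A component is *selected* when unpaired one-tailed two-sample
t-tests show its scores increasing across **both adjacent stage pairs**
(1 < 2 and 2 < 3) at p < 0.01; the 1-vs-3 comparison is implied by the
chain, and an `all_pairs` flag enables the exhaustive variant.

Two deliberate choices:

* **Input scale.** PLSR runs on the Amide-I-normalised matrix rather than
  the SNV matrix.  SNV divides each spectrum by its own standard deviation,
  which is dominated by the CH-stretch region; a line with globally low CH
  content (SW620) gets its CH channels inflated, masking exactly the
  common-mode lipid decrease the analysis is meant to detect.  On the
  normalised scale the component-1 weights carry the expected signs
  (positive at 1725 cm⁻¹, negative at 2850 cm⁻¹).
* **Cross-fitted selection.** PLS scores are constructed to covary with the
  response, so t-tests on in-sample scores are drastically anti-conservative
  (on stage-null data the first component would be "selected" in over half
  of replicates).  Selection p-values are therefore computed on split-half
  cross-fitted scores: each half is scored by the PLS fitted on the other
  half, with component orientation fixed on the training half.  This
  restores type-I control (null selection rate ≈ 2α² ≤ α, verified by
  simulation) while the reported scores and weight vectors remain those of
  the full-data fit.  Component identity across the two folds is matched by
  index; at very small n (< 4 cells in a class) the test falls back to
  in-sample scores with a warning.

## 5. Band analysis

Region fits use lmfit least squares with non-negative amplitudes; when
fitting several class means at once, peak centres and widths are shared
global parameters (box-constrained to ±10 cm⁻¹ and 0.3–3× the initial
width) and only amplitudes are per class.  Default regions: Amide III
1200–1320 cm⁻¹ (4 peaks: β-sheet 1230, disordered 1248, α+β 1270, α-helix
1300), Amide I 1600–1700 cm⁻¹ (4 peaks), CH stretch 2800–3100 cm⁻¹
(5 peaks).  Fits are performed on class mean spectra by default; per-cell
fitting is available but off.

The correlation analysis computes Pearson r between all channel pairs with
p-values from the t transform (no multiple-testing correction — the raw
p < 10⁻⁴ cut *is* the filter), zeroes entries with p > 10⁻⁴, and reports
pairs with |r| > 0.3; constant channels are flagged and zeroed.  The
reported pair list can be restricted to the catalogue band centres, since
neighbouring channels of a smooth spectrum are trivially correlated.

## 6. Problem sizes used in the test suite

Unit tests run on 24–60-cell datasets; the acceptance tests and
`scripts/acceptance.py` regenerate the full-size datasets (330 and 680
cells) and run the complete 10-fold × 5 protocol, which takes a few minutes
on one CPU.  Null-distribution checks use 300–1000 replicates at reduced
dimensionality (they exercise the selection logic, whose type-I behaviour
does not depend on the spectral grid size).

## 7. Known limitations

* Class information in the generator is amplitude-only; real cell lines
  also differ in peak positions/widths, which the shared-parameter region
  fits would partially absorb.
* The despiker targets single-channel spikes; multi-channel detector
  artefacts would need a wider template.
* Cross-fold component matching in the PLSR selection uses index order;
  with many weak components and small n the matching can scramble, which
  costs power (never type-I control).
* The boosted ensemble is an AdaBoost stand-in, not a reimplementation of
  any proprietary rule-boosting algorithm; selection-frequency tables, not
  boosting details, are the supported output.
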