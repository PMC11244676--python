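# Methods

## The measurement problem

A titanium implant in the thorax corrupts CT reconstructions in three
recognisable ways: attenuation bias in nearby tissue (bright/dark shading),
streaks radiating from the metal, and blooming — the apparent enlargement
of the implant at any fixed display/segmentation threshold. Different
acquisition and reconstruction settings trade these artifacts against each
other, and reader studies grade the result on ordinal scales. This package
implements one objective metric per artifact mechanism plus the statistical
layer that links the metrics to reader grades.

## Artifact metrics

**ROI metrics.** Diff_HU is the signed difference of mean HU, artifact ROI
minus reference ROI; the sign is informative (artifact shading can bias HU
down in aerated lung and up in contrast-filled tissue). SD_ARTIFACT is the
sample (n−1) standard deviation inside the artifact ROI. ROIs are circles
or rectangles in voxel units on a single slice; a voxel belongs to an ROI
when its centre lies inside the shape, and an ROI must contain at least two
voxels so the SD is defined. ROI placement is caller-supplied: the
reconstruction geometry of any given study fixes the physical ROI size, and
placement "where the artifact is most pronounced" is a judgement call this
package does not automate.

**Fourier streak metric.** The in-slice metal mask is the largest connected
region above the metal threshold (by default the same lower threshold used
for blooming segmentation, so one metal definition serves both metrics). It
is dilated by a disk of `offset_voxels` (default 3) so the contour runs a
fixed distance outside the metal edge — outside partial-volume metal
voxels, but still inside the streak field. The iso-level-0.5 boundary of
the dilated mask is extracted at sub-voxel precision (marching squares),
resampled by arc length to exactly N = 141 points, oriented
counter-clockwise (positive shoelace area in the (row, col) plane) and
rotated to start at the minimal-row, then minimal-column point, which makes
the trace fully deterministic. HU is sampled by bilinear interpolation. The
statistic is |X₁| + |X₂| of the unnormalised DFT — with N = 141, bin 2
sits at 2/141 ≈ 0.0142 cycles per sample, so "low frequency" is the band
0–0.0142 regardless of implant size (that band is what fixes N; the
arc-length resampling is what makes it size-invariant). The metric is
computed per slice on three sequential slices with the contour
re-delineated on each, averaged, and reported with the coefficient of
variation (sample SD / mean × 100). Because bins 1–2 exclude DC, the
statistic is invariant to a constant HU shift and to the contour's
starting point.

**Blooming volume.** Voxels within [lower, upper] HU are segmented, the
largest 26-connected 3-D component is kept (ties broken toward the lowest
label of the deterministic raster-order labelling), and the volume is the
voxel count times the voxel volume. Defaults: lower 800 HU for phantom-type
data, 2500 HU for contrast-enhanced in-vivo data (iodine-filled chambers
approach 800 HU), upper 32 762 HU (the extended-scale ceiling). The
volume is monotone non-increasing in the lower threshold by construction.

## Reader-study statistics

**Tallies.** For each case and question, the number of readers scoring
≥ 3 ("sufficient" or better) is counted; VG_SUM is the sum over the six
questions. Missing reader entries are counted over the available readers
and flagged.

**ICC.** Inter-reader reliability uses the two-way random-effects,
average-measures consistency form ICC(C,k) = (MS_R − MS_E)/MS_R; a
constant per-reader shift does not lower it. Intra-reader reliability uses
the absolute-agreement form ICC(A,k) = (MS_R − MS_E)/(MS_R +
(MS_C − MS_E)/n), which does penalise a systematic shift between reading
occasions. (The agreement form is sometimes printed with a garbled
denominator in secondary sources; the form above is the standard
McGraw–Wong definition and is what this package computes.) Significance is
F = MS_R/MS_E on (n−1, (n−1)(k−1)) df; confidence intervals use the
F-inversion construction for ICC(C,k) and the Satterthwaite-based
construction for ICC(A,k), both verified against pingouin to 1e−10 on the
point estimates. A matrix with zero between-subject variance returns
ICC = 0 with a degeneracy flag rather than 0/0.

**Ordinal score model.** Scores are modelled with a baseline-category
multinomial logit: ln P(score = j)/P(score = 1) per non-reference category
j, with kVp, IQ and slice thickness numeric and keV, iMAR and kernel as
unordered factors (treatment coding; references keV = 40, iMAR = None,
kernel = Qr36f). Each reader × case score is one observation with no
reader effect — the pragmatic pooling choice when the unit of analysis is
not otherwise fixed; a reader term would be a mixed-model extension out of
scope here. Zero-variance predictors are dropped with a warning,
unobserved response categories are flagged, and complete separation
surfaces as a non-convergence flag with the unbounded coefficients left
visible rather than silently truncated. Newton fitting falls back to BFGS
on singular Hessians (aliased designs).

**Spearman matrices.** Tie-corrected (average-rank) Spearman rho per pair
with pairwise-complete deletion, so a single missing BloomVol costs only
its own pairs; two-sided p-values from the t approximation on n − 2 df, no
multiplicity correction (per-cell raw p-values are the convention in the
source tables). A column constant within a pair's complete sample yields
NaN with a flag.

**Metric regressions.** OLS on the (optionally log-transformed) metric.
Under the log link the numeric covariates enter as logs, giving the
power-law form metric = kVp^β₁·keV^β₂·…·e^(β₀+ε); factor coefficients are
then log fold-changes and are reported as percent changes
(e^β − 1)·100. A signed response (phantom Diff_HU is negative) is fitted
on its absolute value under the log link, with the transform recorded in
the result; a linear link is available and is the default reproduction
choice for phantom Diff_HU. keV enters numerically, which forces exclusion
of cases reconstructed poly-energetically (T3D) or with spectral
post-processing (SPP-70): those levels have no defensible numeric energy,
so the numeric-mode fits use the VMI-only subset and the package does not
claim to reproduce published adequacy values that depended on some
unstated encoding of those levels (the factor-coded ordinal model keeps
them as levels instead). Stepwise selection is bidirectional on AIC
starting from the main-effects model; an interaction is eligible only
while both parents are in the model, parents of a retained interaction are
not dropped, and AIC ties resolve toward the smaller model.

## The synthetic phantom

The generator composes, additively: a −1000 HU air background, a soft-
tissue body ellipse (+40 HU) with two lateral lung ellipses (−700 HU)
placed clear of the contour ring, an optional contrast disk, a metal
cylinder along the slice axis (plateau 8000 HU, radius 10 mm, height
24 mm by default — giving a true volume πr²h known exactly), a streak
field A·cos(mθ + φ)·e^(−d/decay) outside the implant, and white Gaussian
noise. Blooming is modelled by Gaussian-blurring the implant before
compositing: at a segmentation threshold far below the metal plateau the
apparent volume then grows with the blur scale, which reproduces the
threshold-dependent enlargement with a single interpretable parameter.
Streaks are modelled spectrally rather than physically: the Fourier metric
senses only angular frequency content along the contour, so a
low-angular-order sinusoid is the minimal faithful stimulus, and orders
≥ 5 serve as a negative control that must leave bins 1–2 untouched.

What the generator does **not** emulate: beam hardening and scatter
physics, correlated reconstruction noise, kernel-dependent resolution,
anatomy. Passing the synthetic battery therefore demonstrates that the
metrics measure what they claim (volumes, angular spectral content,
variance components) — not that any particular scanner setting is well or
poorly corrected.

Reader scores are simulated as score = cut(latent_quality(case) + ε),
ε ~ N(0, reader_sd²) i.i.d. per reader × case, with fixed cutpoints
(1.5, 2.5, 3.5, 4.5). Discretisation onto five levels attenuates the ICC
of the observed scores relative to the latent scale (≈ 0.78 observed for a
latent 0.8 at the default settings), so recovery checks target the
population ICC of the *discretised* model, computed independently by
Gauss–Hermite quadrature over the latent distribution — not the latent
value, and not a Monte-Carlo rerun of the estimator under test.

## Numerical and design choices

- Voxel indexing is 0-based, axis order (slice, row, column) everywhere;
  spacings in mm. NIfTI I/O transposes to and from the (x, y, z) disk
  order; DICOM series are sorted along the slice normal, must share one
  frame of reference and orientation, and are rescaled to HU exactly once
  (volumes carry a calibration flag).
- Sample (n−1) standard deviations throughout, including the CV of the
  Fourier metric.
- A missing BloomVol (one phantom case) is an explicit missing value, never
  zero; all downstream statistics use pairwise deletion.
- The packaged study tables store iMAR presets under full names expanded
  from the printed abbreviations (Pa → Pacemaker, Th/Tc → ThoracicCoils,
  Hi → HipImplants, Ex/Ei → ExtremityImplants); unicode minus and thin
  spaces in the source were normalised to ASCII. SPP-70 is kept as its own
  keV factor level, distinct from 70. Files are pinned by SHA-256.
- All randomness flows through explicit integer seeds; battery cases
  derive per-case seeds from the base seed by offset.
- Problem sizes used by the validation battery: 32×128×128 voxel volumes
  (0.5 mm in-plane), 5-point sweeps for monotonicity/linearity, 100
  replicates of n = 100 cases × 6 readers for ICC recovery, 500
  observations for multinomial recovery — sizes at which every oracle
  comparison is stable at its stated tolerance while the whole battery
  runs in seconds.

## Known limitations

- The Fourier metric's contour-to-metal distance and interpolation are
  conventions (offset 3 voxels, bilinear); published values from other
  implementations may differ by a scale factor, so comparisons should be
  within-study.
- The numeric-keV regression mode cannot include T3D/SPP-70 cases (above).
- ICC on 5-level ordinal data is a linear-model statistic applied to
  discrete scores; the quadrature target quantifies, rather than removes,
  the discretisation effect.
- The in-vivo arm of the packaged data is a single subject's
  reconstruction series; correlations there describe that series, not a
  population.
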