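# Methods

## Scope and data model

The package implements the computational chain for detecting band-limited
disturbances of spontaneous BOLD fluctuation amplitude in a four-group
disease-severity cohort, together with a synthetic cohort generator that
makes every stage testable without clinical data. All images live on a
regular voxel grid (`VoxelGrid`: dims, voxel size, 4×4 world affine);
BOLD data are 4-D arrays with a repetition time; motion is a per-volume
6-parameter rigid-body trace (translations in mm, rotations in radians).

Spatial registration and slice-timing correction are deliberately absent:
synthetic data are generated directly on a common grid, so the pipeline
starts from aligned volumes.

## Synthetic cohort generator

The generator emulates a cohort of NC / SCD / aMCI / dAD analogues
(defaults: 4×8 subjects on a 24×24×18 grid of 3 mm voxels, 239 volumes at
TR 2 s, i.e. a 478 s scan).

**Geometry.** The foreground is a central ellipsoid (semi-axes 0.45×dims).
Compartments are defined on the normalized ellipsoidal radius ρ: a CSF
core (ρ < 0.3), a WM outer ring (ρ ≥ 0.85) and GM between them. The
parcellation is a nearest-seed (Voronoi) partition of the whole foreground
into 116 parcels; the shipped lookup borrows the public AAL-116
nomenclature purely as names for synthetic parcels.

**Signal model.** Each region × band contributes an amplitude times a
unit-variance mixture of 5 sinusoids at distinct random in-band
frequencies with random phases. Sinusoid mixtures (rather than filtered
noise) make band power analytically controlled, so amplitude-recovery
tests are sharp. Frequencies are snapped to DFT bins of the default
analysis length (229 volumes) to avoid spectral leakage blurring those
tests. On top of the band signals, every voxel receives a shared
low-frequency global component, WM/CSF voxels their compartment
components (smooth random series, gain 0.2), a linear drift (slope
uniform in ±0.002 per volume), and white noise (SD 0.5). With these
settings the expected ratio of measured region ALFF between amplitude
multipliers 2.0 and 1.0 is ≈1.9 (the noise floor in non-signal band bins
dilutes the ratio slightly below 2); the noise level was chosen once as a
realistic signal-to-noise compromise that keeps planted effects
detectable but non-trivial.

**Motion.** A mean-reverting (AR(1), coefficient 0.98) random walk with
per-volume steps of 0.06 mm / 0.0007 rad at severity 1, giving a mean
framewise displacement near 0.23 mm — in the range reported for elderly
cohorts. An optional spike adds a persistent translation step mid-scan,
used to exercise the 3 mm exclusion rule. Per-group severities and the
per-group covariate/score means and SDs (age, education, GM volume,
AVLT-I/D/R, MMSE, MoCA, sex ratio) default to values mirroring a
published four-group Alzheimer-spectrum cohort; draws are truncated to
the admissible score ranges by clipping.

**Planted effects.** Defaults plant monotone severity-graded amplitude
decreases in a precuneus analogue (slow-5), mid-cingulate analogue
(slow-4) and posterior-cerebellar analogue (slow-4/slow-5), and a graded
increase in a hippocampal analogue (classic band). These effect sizes are
calibration choices of the generator, not measured values.

**What the generator does not emulate:** hemodynamic response shapes,
cardiac/respiratory aliasing, scanner drift nonlinearity, spatial
inhomogeneity of noise, registration error. Passing tests therefore
demonstrate correctness of the computational chain under a controlled,
stationary, Gaussian-noise regime — not robustness to real-scanner
artefacts.

## Preprocessing

Order: drop the first 10 volumes → motion QC → Gaussian smoothing (4 mm
FWHM) → linear detrending → nuisance regression. The numbered order of
the pipeline's stages is kept as published even though some toolchains
swap smoothing and detrending; the two commute for the statistics that
matter here only approximately, so the order is part of the contract.

- **FD** uses the Power convention: sum of absolute frame-to-frame changes
  of the 3 translations plus 50 mm × the 3 rotation changes. FD is
  invariant to constant offsets of the trace.
- **QC** excludes subjects with max |translation| > 3 mm or max rotation
  > 3° (rotations stored in radians, converted for the comparison).
- **Smoothing** uses normalized (mask-weighted) convolution inside the
  brain mask so edge voxels are not diluted by the zero background;
  without a mask, nearest-edge replication handles array boundaries.
- **Nuisance regression** removes, per voxel, the least-squares fit of an
  intercept, the global / WM / CSF mean signals, and the 24 Friston
  motion regressors (parameters, one-volume lags zero-padded at the first
  row, and both squared). Zero-variance or linearly redundant columns are
  dropped with a logged warning. Because the global/WM/CSF signals are
  in-mask means, the re-extracted nuisance signals of the residuals are
  exactly zero, making the detrend→regress tail of the chain idempotent;
  smoothing is inherently non-idempotent, so "run the chain twice"
  equivalence is only asserted from detrending onward.

## Spectral metrics

One-sided amplitudes are `(2/N)|X_k|` for k = 1..⌊N/2⌋ (DC always
excluded; for even N the Nyquist bin has no conjugate partner and its
scaling is halved). ALFF is the *mean* band amplitude — the convention of
the REST-family toolboxes; the choice washes out of mALFF but matters for
raw values. fALFF's denominator spans all non-DC bins up to Nyquist
(0.25 Hz at TR 2 s). Band edges are closed intervals. No taper is applied
before the transform. Zero-variance voxels yield ALFF = fALFF = 0 and are
excluded from the normalization mean. Metrics require a frequency
resolution 1/(N·TR) ≤ 0.01 Hz (enforced).

Region features are means over each parcel within the whole-brain mask
(the GM mask restricts only the voxelwise ANCOVA), yielding
116 regions × 3 bands × {mALFF, mfALFF} = 696 features per subject with a
deterministic metric→band→region column order.

## Group statistics

The voxelwise ANCOVA fits, per voxel, y = intercept + group dummies
(reference coding, first group as reference; the F statistic is invariant
to that choice) + 5 covariates, and tests the group block with
F = [(SSE_reduced − SSE_full)/df1]/[SSE_full/df2]. One model is fitted
per metric-band map (6 analyses).

**Smoothness.** Per-axis FWHM comes from the variance of spatial first
differences of the standardized full-model residuals, pooled over
subjects and in-mask neighbour pairs and taken relative to the field's
own variance. Two analytic corrections are applied: (1) the raw
plug-in `FWHM = voxel·sqrt(4ln2/v)` overestimates FWHM at realistic
smoothness because forward differences underestimate the gradient
variance of a smooth field; for a Gaussian-shaped autocorrelation the
lag-one correlation ρ = 1 − v/2 inverts exactly to σ² = −1/(4 ln ρ).
(2) Standardizing residuals by noisy per-voxel SDs attenuates
neighbour correlation by the factor (1 − (1 − ρ²)/(2·df)); the measured
value is inverted accordingly. The estimate is floored at the white-noise
lattice value voxel·sqrt(2 ln 2) ≈ 1.18 voxels (also the value returned
for fields at or beyond white-noise roughness). Recovery of a known 6 mm
kernel on the default grid is accurate to within 1%; the acceptance
tolerance is 20%.

**Cluster correction.** Voxels with F tail probability < 0.001 are kept
and grouped under 26-neighbour connectivity. The expected suprathreshold
cluster count is RESELs × the 3-D Euler-characteristic density of an
*F field* at the threshold (Worsley's unified result; validated against
the Gaussian density in the F(1, ∞) limit). Cluster extents use the
classical exponential approximation P(n ≥ k) = exp(−βk^{2/3}) with
β = (Γ(5/2)/E[n])^{2/3}, E[n] = E[N]/E[m], and the corrected p is
1 − exp(−E[m]·P(n ≥ k)). Treating the F map as a Gaussianized z map with
component-field smoothness — a common toolbox shortcut — proved badly
conservative in null simulation (family-wise error ≈ 0.00 instead of
0.05) because an F statistic map is rougher than its component fields;
the F-field density fixes this, and the measured null family-wise error
rate of the full chain is ≈ 0.04 (500 simulations at the default
geometry, 6 mm smoothing, 4×8 subjects).

**ROI statistics.** Post-hoc pairwise group contrasts use t statistics
from the full covariate-adjusted linear model over all groups, Bonferroni
multiplied by the number of pairs (6 for four groups) within each ROI
(not across ROIs). Partial correlations residualize the ROI value and the
score on an intercept plus covariates (including group dummies when the
analysis spans diagnoses) and use df = n − 2 − n_covariates; the
score-correlation family gate is P < 0.05/5.

## Kernel fusion classifier

Two feature views (mALFF and mfALFF region features) with labels
+1 = patient, −1 = control. Per modality, features are standardized with
training-fold statistics and reduced by elastic-net selection (nonzero
coefficients of a penalized linear regression of the labels; if the
penalty kills everything, the single best univariately correlated feature
is kept so the set is never empty). Linear Gram matrices per modality are
fused as a convex combination with weights β on a 0.1-step grid; a
maximal-margin SVM (libsvm dual solver, precomputed kernel) is trained on
the fused kernel. Dual feasibility (Σα_m y_m = 0, 0 ≤ α_m ≤ C) is
asserted on every fit.

Nested CV protocol (defaults: 10 outer / 5 inner stratified folds, 10
repeats): inside each outer training set, the inner CV first picks the
elastic-net penalty and mixing per modality by single-modality SVM
accuracy at C = 1, then jointly picks (C, β) for the fused kernel; ties
prefer smaller C, then larger β₁. Selection runs per modality on its own
view. Metrics (accuracy, sensitivity = patient recall, specificity,
rank-based AUC with midranks) are computed on the pooled outer-fold
decision values of each repeat and reported as means and SDs over
repeats; ROC points pool all repeats. The whole procedure is
deterministic given the master seed. A validation-only switch deliberately
fits feature selection on all rows to demonstrate (in a regression test)
how leakage inflates permuted-label accuracy.

Fold counts are reduced in tests (5 outer / 3 inner at n = 40) so the
suite runs in minutes; the protocol is identical at any fold count.

## Orchestration

`simulate → metrics → groupstats → classify` subcommands read/write
NIfTI-1 images, TSV tables and JSON results under one output directory,
each stage writing a JSON manifest (stage, version, seed, full config
echo) sufficient to reproduce its outputs bit-identically. Voxel indices
are 0-based internally; reports print world-mm coordinates derived from
the NIfTI affine. Configs are TOML; exit codes are 0 (success),
2 (config error), 3 (data error).

## Known limitations

- Cluster-level inference relies on stationary random-field assumptions;
  permutation inference is documented as the robust alternative but not
  implemented.
- The generator's noise is white and spatially homogeneous; the FWER
  calibration result is specific to that regime.
- Anatomical labels on reports name synthetic parcels, not anatomy.
- Classifier runtimes grow linearly in repeats × outer folds × the
  hyperparameter grid; the default grids are modest and configurable.
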