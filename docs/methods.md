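# Methods

## The problem this package models

Jacobian CT-ventilation maps estimate regional lung function from the
determinant of a deformable registration between exhale and inhale CT
volumes: J(x) > 1 marks local tissue expansion, a surrogate for
ventilation. Because CT noise rises as the tube current–time product
(mAs) falls — approximately `noise ∝ mAs^(-1/2)` — the clinically
important question is whether these biomarkers survive dose reduction.
The package rebuilds the whole measurement chain on synthetic data with
known ground truth: a calibration phantom for the noise–mAs law, a
deforming digital lung for the biomarkers, and the agreement battery
(local 3D gamma, voxel-wise Spearman, Jacobian-ratio CoV) that quantifies
robustness across noise levels.

## Noise model and calibration

Image noise is additive white Gaussian in HU; its SD follows
`A·mAs^(-B)` with separate constants per acquisition mode (4DCT is
reconstructed from a limited projection angle and is noisier than helical
breath-hold CT at equal mAs). Defaults are the fitted constants
A=405.4, B=0.487 (4DCT) and A=325.5, B=0.497 (BHCT). Iterative
reconstruction is modelled as a single multiplicative noise factor
(default 0.6); reconstructing one simulated acquisition with and without
IR reuses the same noise realisation scaled by that factor, as a real
reconstruction of the same raw data would. No spatial noise correlation
or kernel texture is modelled: every quantity downstream depends on the
HU SD only.

Noise is measured as the sample SD in a centred circular ROI (40% of the
phantom diameter, pooled over central slices), the power law is fitted by
ordinary least squares in log–log space, and the noise-equivalent BHCT
mAs solves `A_BH·x^(-B_BH) = A_4D·mAs^(-B_4D)`, rounded half-up to an
integer and clamped at the 10 mAs scanner floor. Percent noise increases
are computed on unrounded model evaluations and rounded once for
reporting. Dose scales linearly with mAs through a CTDI_vol anchor pair
per mode (10 mAs ↔ 6.07 mGy for 4DCT; 59 mAs ↔ 7.9 mGy for BHCT).

## The digital subject

A capped soft-tissue cylinder (HU 50) contains two ellipsoidal lungs
(exhale HU −750, i.e. air fraction 0.762). The default grid is 96³ at
3 mm isotropic spacing: a 288 mm field of view is the smallest that holds
~2 L of exhale lung, which a 1000 cc tidal volume inflates to a mean
Jacobian of ≈1.5 — the physiological range. Lungs carry a seeded,
band-limited parenchymal density texture (sum of 48 cosine modes,
wavelengths ~20–36 mm, air-fraction SD 0.06): real parenchyma is not
homogeneous, and without interior structure a tissue-volume similarity
cannot pin down correspondence inside the lung.

The ground-truth deformation is a superposition of per-lung
Gaussian-windowed inflation lobes,
`u_d(x) = f·α·g_d·(x_d−c_d)·exp(−ρ²/2σ²)` with lung-normalised radius ρ,
window width σ=0.95 and diaphragm-dominant gains g=(0.55, 0.55, 1.0).
The window decays smoothly rather than vanishing at a compact boundary:
expansion then fills the lung and the compensating compression spreads
over the surrounding body at low amplitude, keeping det(∇(x+u)) > 0 with
a wide margin at all phases (a compactly supported lobe would have to
absorb the full 1000 cc in a thin shell and folds). The spatial gradient
is closed-form; the analytic determinant agrees with central differences
of the sampled field to ≤1e-3 RMS at 3 mm spacing.

The amplitude α is calibrated by bracketing so the integral of (J−1) over
the exhale lung equals the requested tidal volume; per-scan effort jitter
(SD 4 cc, matching the few-cc scan-to-scan variability of mechanical
ventilation) and, for repeated breath-holds, a linear volume drift per
scan index (default 6 cc/scan in the experiment plan) shift that target.
An out-of-phase sub-region — 7.6% of lung volume, the reported average
for mechanically ventilated swine — is driven by a broader Gaussian lobe
on its own phase schedule peaking at 60IN; inside the labelled ellipsoid
the true expansion peaks off-phase for the majority of voxels, which is
what LER-N exists to capture.

Phase images are produced through the exact inverse map (Newton
iteration on the closed-form residual, sub-0.01 mm): each phase voxel
takes the HU that conserves per-voxel tissue volume, `t = t₀/J`, so HU
becomes more air-like exactly where the local Jacobian exceeds 1. Total
lung tissue volume is conserved across phases to <0.5% by construction.
The ten 4DCT phase labels (0EX…20EX) and three breath-holds (MEBH,
80%Insp, MIBH) share one amplitude schedule (fraction of full
inspiration).

Not emulated: sinogram physics, limited-angle artifacts, cardiac motion,
airway/vessel trees, partial-volume boundary mixing, spatially correlated
noise. Passing tests therefore demonstrate correctness of the analysis
chain under controlled conditions, not clinical image realism.

## Registration

The transform is a cubic B-spline free-form deformation; displacement,
spatial gradient and Jacobian determinant are evaluated analytically from
the separable basis (dense per-axis collocation matrices, tensor
contractions). The similarity is the sum of squared tissue-volume
differences: with tissue fraction v = clamp(1−a, 0, 1) from HU, the cost
per fixed-mask voxel is `[v_f(x) − J_T(x)·v_m(T(x))]²` (the constant
voxel volume is dropped; it rescales the cost uniformly). The analytic
gradient propagates through both the warped moving image (trilinear) and
the Jacobian factor (cofactor matrix against the derivative bases).

Optimisation is multi-resolution L-BFGS-B (shrink factors 4/2/1, control
spacings 48/24/12 mm, iteration budgets 150/100/50), with the coarse
solution carried to the next level by separable least-squares B-spline
fitting. Two regularisers: squared second differences of the control
coefficients in curvature units (weight 30 — deliberately strong, because
the tissue-volume cost has a gauge ambiguity in smooth regions where a
correspondence drift can be compensated by the Jacobian factor; the
weight was chosen by sweeping against ground-truth displacement recovery
on noiseless phantom pairs), and a quadratic penalty on determinants
below 0.05 (weight 10) that keeps the map fold-free. The tissue-fraction
images are Gaussian-smoothed by one level-voxel at every pyramid level,
standard multi-resolution practice that keeps σ=133 HU voxel noise out of
the finest-level fit. Physical (mm) coordinates throughout; no direction
cosines in v1. No post-hoc smoothing is applied to Jacobian maps.

At the default phantom this recovers the true field to 0.7–1.0 mm RMS
inside the lungs and voxel-wise Spearman 0.99/0.98 against the true
ventilation at 43/133 HU noise; the mean masked Jacobian matches the
lung volume ratio to 1.3% at nominal noise.

## Biomarkers

Lung masks come from thresholding at −400 HU inside the body contour
(Gaussian pre-smoothing of 0.5 voxel, two largest components,
morphological closing) — a stand-in for learned segmentation, adequate on
the phantom (Dice ≥0.99 noiseless, ≥0.97 at 133 HU at default
resolution). Tidal volumes are mask volumes minus the end-exhale volume.
Effort correction selects the inhale-phase pair with the closest tidal
volumes (ties toward the larger volume). Breath-hold maps register the
ETV-selected inspiratory volume to MEBH; LER-N registers every
inspiratory phase up to the ETV phase to 0EX and takes the voxel-wise
maximum Jacobian ("combined to determine maximal expansion" is read as
the per-voxel max; no temporal weighting is assumed). Expiratory-limb
phases are never ETV candidates.

## Comparison battery

Reduced-dose maps are registered into the full-dose exhale frame (mask =
intersection); comparisons refuse to run across acquisition modes or IR
states. The local 3D gamma uses 2 mm DTA and a 6% Jacobian-intensity
criterion normalised by the local reference value; candidates are sampled
on a half-voxel lattice within twice the DTA with trilinear
interpolation, with distance-ordered early termination (the search is
validated against an exhaustive brute-force minimiser at matched
density). Reference voxels with J ≤ 0 are excluded from all metrics and
counted. CoV_JR is the sample SD over mean of J2/J1 (an FWHM-based SD is
available behind a flag but is not the estimator). Scans whose tidal
volumes differ by strictly more than 100 cc are excluded from gamma and
CoV_JR; Spearman is always retained. The with/without-IR effect is a
two-sided paired t-test per metric, paired per comparison row
(subject × date × reduced level); identical groups report p = 1.

## Desk-scale study sizes

The full design (5 subjects × 2 dates × 24 maps) is a configuration away
but computationally heavy; the shipped tests exercise: full-resolution
(96³) self-registration and two-noise-extreme recovery; and a 2 subject ×
2 date 4DCT study at 64³/4.5 mm with LER-N over the last three
inspiratory phases and a two-level pyramid, compared against the same
study with noise disabled (the registration-only floor). At those
settings the mean gamma pass rate across a 3.1× noise difference sits
within 4 points of the floor and every Spearman correlation exceeds 0.98
— the desk-scale analog of the finding that Jacobian ventilation is
noise-invariant.

## Numerical notes and limitations

- Gamma pass uses γ ≤ 1 + 1e-9 so the exact 6%-offset boundary case
  passes as defined.
- Equivalent-mAs rounding is half-up, then clamped at 10 mAs; the
  15 mAs_4D row correctly clamps (raw solution ≈ 9.1).
- The equivalence table from *fitted* (simulated-measurement) models is
  stochastic at the ±1 mAs level at the top entry; the printed-constant
  table is exact.
- Fixed-point/Newton inversion of the ground-truth field assumes the
  field is a diffeomorphism on the grid (guaranteed by the positivity
  check at calibration).
- The threshold masker biases tidal volumes upward on coarse grids;
  biases are common-mode between compared scans, so ETV selection and the
  100 cc exclusion are unaffected in practice.
- Breathing-period variability is represented only through the effort
  jitter; no breathing-trace simulation exists (the respiratory trace and
  phase re-binning are out of scope).
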