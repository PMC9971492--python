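# ctvent

**Jacobian CT-ventilation biomarkers and their robustness to image noise.**

CT-ventilation maps estimate regional lung function from the Jacobian
determinant `J(x) = det(∇T(x))` of a deformable registration `T` between
exhale and inhale CT volumes: `J > 1` marks local tissue expansion, a
surrogate for ventilation used in functional-avoidance radiotherapy and
lung-disease imaging. Because CT image noise grows as the tube
current–time product (mAs) falls — `noise = A·mAs^(−B)` with `B ≈ 0.5` —
the practical question for dose reduction is whether these biomarkers
degrade with noise.

`ctvent` rebuilds that measurement chain end-to-end on synthetic data
with analytic ground truth, for researchers who want a testable,
self-contained reference implementation:

- **`ctvent.phantom`** — a uniformity cylinder for noise calibration and
  a deforming digital lung: two ellipsoidal lungs with parenchymal
  texture, a smooth inflation field with closed-form Jacobian, HU coupled
  to local air content so tissue volume is conserved, 10 breathing phases
  (0EX…20EX) and 3 breath-holds (MEBH/80%Insp/MIBH), out-of-phase
  sub-regions, effort jitter and breath-hold volume drift.
- **`ctvent.noisecal`** — ROI noise measurement, log–log power-law
  fitting, the noise-equivalent mAs solve between 4DCT and breath-hold
  CT, and linear CTDI_vol dose scaling.
- **`ctvent.registration`** — cubic B-spline free-form registration with
  the sum-of-squared-tissue-volume-differences (SSTVD) similarity
  `[v_f(x) − J_T(x)·v_m(T(x))]²`, analytic gradient and Jacobian,
  multi-resolution L-BFGS, bending-energy and folding penalties.
- **`ctvent.ventilation`** — lung masking, tidal volumes, equivalent-
  tidal-volume (ETV) effort correction, two-image breath-hold maps, and
  LER-N (per-voxel maximal expansion over registered phases).
- **`ctvent.compare`** — local 3D gamma (2 mm / 6%), voxel-wise Spearman
  ρ with the ρ ≥ 0.8 "strong" label, Jacobian-ratio CoV, and the
  \>100 cc tidal-volume exclusion rule.
- **`ctvent.pipeline`** — the full study design (per subject-date: two
  4DCT noise levels and ten noise-matched BHCT levels, each with and
  without iterative reconstruction = 24 maps), reduced-vs-full-dose
  comparisons, and the paired t-test for the IR effect.

See `docs/methods.md` for the model, parameter and tolerance choices.

## Worked example

```python
from ctvent import (NOISE_MODEL_4DCT, NOISE_MODEL_BHCT, equivalent_mAs,
                    percent_noise_increase)

# image noise predicted by the two calibrated power laws
print(round(NOISE_MODEL_4DCT.noise_at(100)))   # 43  (HU at 100 mAs, 4DCT)
print(round(NOISE_MODEL_BHCT.noise_at(59)))    # 43  (HU at 59 mAs, BHCT)

# the BHCT mAs whose noise matches a standard-of-care 100 mAs 4DCT
print(equivalent_mAs(NOISE_MODEL_BHCT, NOISE_MODEL_4DCT, 100))   # 59.0

# dropping a BHCT from 59 to 10 mAs raises noise by
print(percent_noise_increase(NOISE_MODEL_BHCT, 10, 59))          # 142.0  (%)
```

A miniature noise-robustness study on the digital lung (one subject, one
scan date, 4DCT at 10 vs 100 mAs, LER-N maps, ~1 minute):

```python
from ctvent import ExperimentPlan, RegistrationConfig, run_experiment

plan = ExperimentPlan(n_subjects=1, n_scan_dates=1,
                      grid_shape=(64, 64, 64), spacing=(4.5, 4.5, 4.5),
                      include_bhct=False, lern_phases=3,
                      ir_variants=(False,), seed=0)
cfg = RegistrationConfig(shrink_factors=(4, 2), iterations=(100, 60),
                         control_spacing=(48.0, 24.0))
reports, summary = run_experiment(plan, registration_config=cfg)
r = reports[0]
print(f"gamma {r.gamma_pass_rate:.1f}%  rho {r.spearman_rho:.3f}  "
      f"CoV_JR {r.cov_jr:.3f}  TV diff {r.tv_difference_cc:.0f} cc")
```

```
gamma 94.8%  rho 0.985  CoV_JR 0.026  TV diff 29 cc
```

Reading: comparing the ventilation map from a 10 mAs scan (133 HU noise)
against the 100 mAs reference (43 HU), 94.8% of lung voxels pass the
2 mm / 6% gamma criterion, the voxel-wise rank correlation is strong
(ρ ≥ 0.8), and the Jacobian ratio varies by only ~2.6% — the biomarker is
essentially noise-invariant, while the tidal-volume difference between
the two simulated scans stayed within the 100 cc inclusion limit.

There is also a CLI (`ctvent calibrate | simulate | ventilate | compare |
report | all`); `ctvent simulate --grid 64 --mas 10` writes a noisy phase
series plus true masks and true Jacobian maps as NIfTI.

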