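"""Study orchestration: calibration, simulation, mapping, comparison.

Reproduces the study design at desk scale: per subject and scan date,
two 4DCT scans (reduced and standard dose) and ten noise-matched BHCT
scan sets are simulated, each reconstructed with and without iterative
reconstruction (24 ventilation maps per subject per scan date).  Every
reduced-dose map is compared to the matching full-dose reference of the
same mode and IR state, and the with/without-IR effect on each agreement
metric is tested with a two-sided paired t-test.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .compare import GammaConfig, compare_maps, to_reference_frame
from .noisecal import (
    NOISE_MODEL_4DCT,
    NOISE_MODEL_BHCT,
    NoiseModel,
    equivalent_mAs,
    fit_power_law,
    measure_noise,
)
from .phantom import (
    AcquisitionSpec,
    BreathingModel,
    GroundTruthField,
    PhantomSpec,
    make_subject_images,
    make_uniformity_phantom,
)
from .registration import RegistrationConfig
from .ventilation import (
    bh_ventilation,
    lern_ventilation,
    segment_lungs,
    select_etv,
    tidal_volumes,
)

__all__ = [
    "ExperimentPlan",
    "MapSpec",
    "SummaryTable",
    "enumerate_maps",
    "enumerate_comparisons",
    "run_calibration",
    "run_experiment",
    "ir_effect_test",
]

log = logging.getLogger("ctvent")


@dataclass(frozen=True)
class ExperimentPlan:
    """The study design plus desk-scale simulation knobs.

    Defaults reproduce the full design (5 subjects x 2 dates; 4DCT at 10
    and 100 mAs; BHCT at ten levels noise-matched to 15-100 mAs 4DCTs; each
    with and without IR = 24 maps per subject-date).  The grid/physics
    knobs let tests run the same pipeline on smaller volumes.
    """

    n_subjects: int = 5
    n_scan_dates: int = 2
    fourdct_mAs: tuple[float, ...] = (10.0, 100.0)
    bhct_equivalent_4d_mAs: tuple[float, ...] = (
        15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 60.0, 70.0, 80.0, 100.0)
    ir_variants: tuple[bool, ...] = (False, True)
    seed: int = 0

    # desk-scale knobs
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tidal_volume_cc: float = 1000.0
    lern_phases: int = 5            # inspiratory phases available to LER-N
    include_4dct: bool = True
    include_bhct: bool = True
    noise_scale: float = 1.0        # 0 disables noise (registration floor)
    bh_drift_cc_per_scan: float = 6.0   # breath-hold volume drift
    effort_sd_cc: float = 4.0
    anatomy_jitter: float = 0.03    # between-subject lung-size variation

    @classmethod
    def from_yaml(cls, path) -> "ExperimentPlan":
        """Load a plan from a structured YAML config file; keys mirror the
        dataclass fields, list values become tuples."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in __import__("dataclasses").fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown plan keys in {path}: {sorted(unknown)}")
        cooked = {k: tuple(v) if isinstance(v, list) else v
                  for k, v in raw.items()}
        return cls(**cooked)

    def base_spec(self) -> PhantomSpec:
        return PhantomSpec(grid_shape=self.grid_shape, spacing=self.spacing)

    def breathing(self, bh: bool = False) -> BreathingModel:
        return BreathingModel(
            tidal_volume_full=self.tidal_volume_cc,
            drift_cc_per_scan=self.bh_drift_cc_per_scan if bh else 0.0,
            effort_sd_cc=self.effort_sd_cc,
        )


@dataclass(frozen=True)
class MapSpec:
    """Identity of one ventilation map in the design."""

    subject: int
    scan_date: int
    mode: str           # "4DCT" or "BHCT"
    mAs: float          # actual tube current-time product of the scan
    equivalent_4d_mAs: float
    ir: bool


def _seed_from(*keys: int) -> int:
    """Deterministic 31-bit seed from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def enumerate_maps(
    plan: ExperimentPlan,
    model_4d: NoiseModel = NOISE_MODEL_4DCT,
    model_bh: NoiseModel = NOISE_MODEL_BHCT,
) -> list[MapSpec]:
    """All ventilation maps the design calls for (24 per subject-date by
    default: 2 x 2 4DCT plus 10 x 2 BHCT)."""
    maps = []
    for s in range(plan.n_subjects):
        for d in range(plan.n_scan_dates):
            for ir in plan.ir_variants:
                if plan.include_4dct:
                    for mAs in plan.fourdct_mAs:
                        maps.append(MapSpec(s, d, "4DCT", float(mAs), float(mAs), ir))
                if plan.include_bhct:
                    for eq in plan.bhct_equivalent_4d_mAs:
                        mas_bh = equivalent_mAs(model_bh, model_4d, eq)
                        maps.append(MapSpec(s, d, "BHCT", mas_bh, float(eq), ir))
    return maps


def enumerate_comparisons(plan: ExperimentPlan,
                          maps: list[MapSpec] | None = None
                          ) -> list[tuple[MapSpec, MapSpec]]:
    """(reduced, reference) pairs: every reduced-dose map against the
    full-dose map of the same subject, date, mode and IR state."""
    maps = maps if maps is not None else enumerate_maps(plan)
    pairs = []
    keyed: dict = {}
    for m in maps:
        keyed.setdefault((m.subject, m.scan_date, m.mode, m.ir), []).append(m)
    for group in keyed.values():
        ref = max(group, key=lambda m: m.mAs)
        pairs.extend((m, ref) for m in group if m is not ref)
    return pairs


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def run_calibration(
    plan: ExperimentPlan,
    mAs_levels: tuple[float, ...] = (10, 15, 20, 25, 30, 40, 50, 60, 80, 100),
    repeats: int = 5,
    true_model_4d: NoiseModel = NOISE_MODEL_4DCT,
    true_model_bh: NoiseModel = NOISE_MODEL_BHCT,
    n_slices: int = 12,
) -> tuple[NoiseModel, NoiseModel, pd.DataFrame]:
    """Simulate uniformity-phantom scans across mAs, fit both noise--mAs
    power laws, and tabulate the noise-equivalent BHCT mAs values.

    Returns the two fitted models and a table with one row per planned
    BHCT level: the 4DCT-equivalent mAs and the (rounded, clamped) mAs_BH
    from the fitted models.
    """
    from .noisecal import NoiseMeasurement

    fitted = {}
    for mode_idx, (mode, model) in enumerate(
        (("4DCT", true_model_4d), ("BHCT", true_model_bh))
    ):
        meas = []
        for i, mAs in enumerate(mAs_levels):
            sds, n_vox = [], 0
            for r in range(repeats):
                seed = _seed_from(plan.seed, mode_idx, i, r)
                img = make_uniformity_phantom(model, mAs, seed=seed)
                m = measure_noise(img, n_slices=n_slices)
                sds.append(m.noise)
                n_vox += m.n_voxels
            # repeated scans at one mAs pool into a single measurement
            meas.append(NoiseMeasurement(
                mAs=float(mAs), noise=float(np.mean(sds)),
                roi_fraction=m.roi_fraction, n_voxels=n_vox))
        fitted[mode] = fit_power_law(meas, mode)
        log.info("calibration %s: A=%.1f B=%.4f R2=%.5f", mode,
                 fitted[mode].A, fitted[mode].B, fitted[mode].r_squared)
    rows = [
        {"equivalent_4d_mAs": eq,
         "mAs_BH": equivalent_mAs(fitted["BHCT"], fitted["4DCT"], eq)}
        for eq in plan.bhct_equivalent_4d_mAs
    ]
    return fitted["4DCT"], fitted["BHCT"], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# experiment
# ---------------------------------------------------------------------------

def _scan_maps_and_series(scan):
    """Estimated lung masks, exhale image, and the tidal-volume series."""
    masks = {ph.label: segment_lungs(ph.image) for ph in scan}
    series = tidal_volumes(masks)
    by_label = {ph.label: ph for ph in scan}
    return masks, series, by_label


def _lern_phase_list(labels_in_order, up_to):
    idx = labels_in_order.index(up_to)
    chosen = labels_in_order[: idx + 1]
    if len(chosen) < 2:  # LER-N needs >= 2 phases
        chosen = labels_in_order[: 2]
    return chosen


def run_experiment(
    plan: ExperimentPlan,
    registration_config: RegistrationConfig | None = None,
    gamma_config: GammaConfig | None = None,
) -> tuple[list, "SummaryTable"]:
    """Run the full desk-scale study and return (reports, summary).

    Every random draw is derived from ``plan.seed``; identical plans give
    identical reports.  Failures in one comparison are logged with their
    subject/date/mAs/IR provenance and skipped.
    """
    reg_cfg = registration_config or RegistrationConfig()
    reports = []
    for s in range(plan.n_subjects):
        spec = plan.base_spec()
        if plan.anatomy_jitter > 0:
            spec = spec.perturbed(_seed_from(plan.seed, s), plan.anatomy_jitter)
        else:
            spec = replace(spec, seed=_seed_from(plan.seed, s))
        br = plan.breathing()
        field = GroundTruthField.build(spec, br)
        for d in range(plan.n_scan_dates):
            if plan.include_4dct:
                reports += _run_4dct(plan, spec, br, field, s, d, reg_cfg,
                                     gamma_config)
            if plan.include_bhct:
                reports += _run_bhct(plan, spec, field, s, d, reg_cfg,
                                     gamma_config)
    return reports, ir_effect_test(reports)


def _run_4dct(plan, spec, br, field, s, d, reg_cfg, gamma_cfg):
    labels = ["0EX"] + list(br.inhale_labels[-plan.lern_phases:])
    inhale_order = [lab for lab in labels if lab != "0EX"]
    scans = {}
    for mAs in plan.fourdct_mAs:
        seed = _seed_from(plan.seed, s, d, 4, int(mAs))
        for ir in plan.ir_variants:
            acq = AcquisitionSpec("4DCT", mAs, ir, noise_scale=plan.noise_scale)
            t0 = time.perf_counter()
            scans[(mAs, ir)] = make_subject_images(
                spec, br, field, acq, labels, seed=seed)
            log.info("subject %d date %d 4DCT %g mAs ir=%s: simulated in %.1fs",
                     s, d, mAs, ir, time.perf_counter() - t0)

    ref_mAs = max(plan.fourdct_mAs)
    out = []
    for ir in plan.ir_variants:
        ref_scan = scans[(ref_mAs, ir)]
        ref_masks, ref_series, ref_by = _scan_maps_and_series(ref_scan)
        for mAs in plan.fourdct_mAs:
            if mAs == ref_mAs:
                continue
            prov = {"subject": s, "scan_date": d, "mode": "4DCT", "ir": ir,
                    "mAs_reduced": mAs, "mAs_reference": ref_mAs}
            try:
                red_scan = scans[(mAs, ir)]
                red_masks, red_series, red_by = _scan_maps_and_series(red_scan)
                p_ref, p_red, tvdiff = select_etv(ref_series, red_series)
                t0 = time.perf_counter()
                map_ref = lern_ventilation(
                    [(lab, ref_by[lab].image, ref_masks[lab])
                     for lab in _lern_phase_list(inhale_order, p_ref)],
                    ref_by["0EX"].image, ref_masks["0EX"], reg_cfg,
                    provenance={**prov, "mAs": ref_mAs, "etv_phase": p_ref})
                map_red = lern_ventilation(
                    [(lab, red_by[lab].image, red_masks[lab])
                     for lab in _lern_phase_list(inhale_order, p_red)],
                    red_by["0EX"].image, red_masks["0EX"], reg_cfg,
                    provenance={**prov, "mAs": mAs, "etv_phase": p_red})
                aligned = to_reference_frame(
                    map_red, red_by["0EX"].image, map_ref, ref_by["0EX"].image,
                    reg_cfg)
                rep = compare_maps(map_ref, aligned, tvdiff, gamma_cfg,
                                   provenance=prov)
                log.info("subject %d date %d 4DCT %g-vs-%g ir=%s: compared in "
                         "%.1fs (TVdiff %.0f cc)", s, d, mAs, ref_mAs, ir,
                         time.perf_counter() - t0, tvdiff)
                out.append(rep)
            except Exception:
                log.exception("4DCT comparison failed (%s); skipping", prov)
    return out


def _run_bhct(plan, spec, field, s, d, reg_cfg, gamma_cfg):
    br = plan.breathing(bh=True)
    model_4d, model_bh = NOISE_MODEL_4DCT, NOISE_MODEL_BHCT
    # scans acquired in decreasing-dose order; drift grows with scan index
    eq_levels = sorted(plan.bhct_equivalent_4d_mAs, reverse=True)
    scans = {}
    for i, eq in enumerate(eq_levels):
        mas_bh = equivalent_mAs(model_bh, model_4d, eq)
        seed = _seed_from(plan.seed, s, d, 5, int(eq))
        for ir in plan.ir_variants:
            acq = AcquisitionSpec("BHCT", mas_bh, ir,
                                  noise_scale=plan.noise_scale)
            scans[(eq, ir)] = make_subject_images(
                spec, br, field, acq, "BH", seed=seed, scan_index=i)
        log.info("subject %d date %d BHCT eq %g mAs (%.0f mAs_BH): simulated",
                 s, d, eq, mas_bh)

    ref_eq = max(eq_levels)
    out = []
    for ir in plan.ir_variants:
        ref_scan = scans[(ref_eq, ir)]
        ref_masks, ref_series, ref_by = _scan_maps_and_series(ref_scan)
        ref_map_cache = {}
        for eq in eq_levels:
            if eq == ref_eq:
                continue
            mas_bh = equivalent_mAs(model_bh, model_4d, eq)
            prov = {"subject": s, "scan_date": d, "mode": "BHCT", "ir": ir,
                    "mAs_reduced": mas_bh, "mAs_reference":
                        equivalent_mAs(model_bh, model_4d, ref_eq),
                    "equivalent_4d_mAs": eq}
            try:
                red_scan = scans[(eq, ir)]
                red_masks, red_series, red_by = _scan_maps_and_series(red_scan)
                p_ref, p_red, tvdiff = select_etv(ref_series, red_series)
                if p_ref not in ref_map_cache:
                    ref_map_cache[p_ref] = bh_ventilation(
                        ref_by["MEBH"].image, ref_masks["MEBH"],
                        ref_by[p_ref].image, ref_masks[p_ref], reg_cfg,
                        provenance={**prov, "etv_phase": p_ref})
                map_ref = ref_map_cache[p_ref]
                map_red = bh_ventilation(
                    red_by["MEBH"].image, red_masks["MEBH"],
                    red_by[p_red].image, red_masks[p_red], reg_cfg,
                    provenance={**prov, "etv_phase": p_red})
                aligned = to_reference_frame(
                    map_red, red_by["MEBH"].image, map_ref,
                    ref_by["MEBH"].image, reg_cfg)
                rep = compare_maps(map_ref, aligned, tvdiff, gamma_cfg,
                                   provenance=prov)
                log.info("subject %d date %d BHCT eq %g-vs-%g ir=%s: TVdiff "
                         "%.0f cc", s, d, eq, ref_eq, ir, tvdiff)
                out.append(rep)
            except Exception:
                log.exception("BHCT comparison failed (%s); skipping", prov)
    return out


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

_METRICS = {"gamma_pass_rate": "gamma", "spearman_rho": "rho",
            "cov_jr": "cov_jr"}


@dataclass
class SummaryTable:
    """Mean +/- SD of each agreement metric with and without IR, and the
    two-sided paired t-test p-value for the IR effect."""

    table: pd.DataFrame = dc_field(default_factory=pd.DataFrame)

    def p_value(self, metric: str, mode: str | None = None) -> float:
        t = self.table
        rows = t[t.metric == metric]
        if mode is not None:
            rows = rows[rows["mode"] == mode]
        return float(rows["p_value"].iloc[0])


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired t-test; identical (zero-variance-difference) groups
    give p = 1 rather than NaN."""
    if len(a) < 2:
        return float("nan")
    if np.allclose(a, b):
        return 1.0
    res = stats.ttest_rel(a, b)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def ir_effect_test(reports: list) -> SummaryTable:
    """Per-metric, per-mode means and the with/without-IR paired t-test.

    Reports are paired by (subject, date, mode, reduced mAs); pairs where a
    metric is excluded (tidal-volume rule) are dropped for that metric.
    """
    if not reports:
        return SummaryTable()
    rows = []
    df = pd.DataFrame([r.as_dict() for r in reports])
    if "prov_ir" not in df:
        raise ValueError("reports lack IR provenance; cannot pair")
    key_cols = ["prov_subject", "prov_scan_date", "prov_mode", "prov_mAs_reduced"]
    for mode, sub in df.groupby("prov_mode"):
        piv = {}
        for metric in _METRICS:
            p = sub.pivot_table(index=key_cols[:2] + ["prov_mAs_reduced"],
                                columns="prov_ir", values=metric, dropna=False)
            piv[metric] = p
        for metric, label in _METRICS.items():
            p = piv[metric]
            no_ir = p[False].to_numpy(dtype=float) if False in p else np.array([])
            with_ir = p[True].to_numpy(dtype=float) if True in p else np.array([])
            ok = ~(np.isnan(no_ir) | np.isnan(with_ir)) if len(no_ir) and len(with_ir) \
                else np.zeros(0, dtype=bool)
            rows.append({
                "mode": mode, "metric": label,
                "mean_no_ir": float(np.nanmean(no_ir)) if len(no_ir) else np.nan,
                "sd_no_ir": float(np.nanstd(no_ir, ddof=1)) if len(no_ir) > 1 else np.nan,
                "mean_ir": float(np.nanmean(with_ir)) if len(with_ir) else np.nan,
                "sd_ir": float(np.nanstd(with_ir, ddof=1)) if len(with_ir) > 1 else np.nan,
                "n_pairs": int(ok.sum()),
                "p_value": _paired_p(no_ir[ok], with_ir[ok]) if ok.any() else np.nan,
            })
    return SummaryTable(pd.DataFrame(rows))
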