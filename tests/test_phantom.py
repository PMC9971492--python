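"""Phantom generators: uniformity cylinder, ground-truth field, subject scans."""

import numpy as np
import pytest

from ctvent.noisecal import NOISE_MODEL_4DCT, measure_noise
from ctvent.phantom import (
    AcquisitionSpec,
    BreathingModel,
    GenerationError,
    PhantomSpec,
    ctdi_for,
    make_subject_images,
    make_uniformity_phantom,
    synthesize_phase,
)
from ctvent.phantom import _grid_point_array


class TestUniformityPhantom:
    def test_deterministic_under_seed(self):
        a = make_uniformity_phantom(NOISE_MODEL_4DCT, 40, seed=3)
        b = make_uniformity_phantom(NOISE_MODEL_4DCT, 40, seed=3)
        assert np.array_equal(a.data, b.data)

    def test_seeds_differ_but_sd_agrees(self):
        a = make_uniformity_phantom(NOISE_MODEL_4DCT, 100, seed=1)
        b = make_uniformity_phantom(NOISE_MODEL_4DCT, 100, seed=2)
        assert not np.array_equal(a.data, b.data)
        ma, mb = measure_noise(a), measure_noise(b)
        sigma = NOISE_MODEL_4DCT.noise_at(100)
        se = sigma / np.sqrt(2 * (ma.n_voxels - 1))
        assert abs(ma.noise - mb.noise) < 3 * np.sqrt(2) * se

    def test_noiseless_limit(self):
        img = make_uniformity_phantom(NOISE_MODEL_4DCT, 100, seed=0,
                                      noise_scale=0.0)
        assert measure_noise(img).noise == 0.0

    def test_below_scanner_minimum_rejected(self):
        with pytest.raises(ValueError, match="scanner minimum"):
            make_uniformity_phantom(NOISE_MODEL_4DCT, 5)


class TestDose:
    def test_anchor_identity(self):
        assert ctdi_for(AcquisitionSpec("4DCT", 10)) == pytest.approx(6.07)

    def test_linear_scaling(self):
        assert ctdi_for(AcquisitionSpec("4DCT", 100)) == pytest.approx(60.7)

    def test_bhct_low_dose(self):
        val = ctdi_for(AcquisitionSpec("BHCT", 10, ctdi_ref=(59.0, 7.9)))
        assert round(val, 1) == 1.3

    def test_acquisition_below_minimum_rejected(self):
        with pytest.raises(ValueError, match="scanner minimum"):
            AcquisitionSpec("4DCT", 9.0)


class TestGroundTruthField:
    def test_zero_fraction_is_identity(self, default_spec, default_field):
        pts = np.array([[100.0, 120.0, 140.0], [50.0, 60.0, 70.0]])
        u = default_field.displacement(pts, 0.0, 0.0)
        assert np.all(u == 0)

    def test_no_folding_across_phases(self, default_spec, default_field, breathing):
        pts = _grid_point_array(default_spec)
        for lab in ("20IN", "60IN", "100IN", "80EX"):
            det = default_field.jacobian_det(
                pts, breathing.fraction(lab), breathing.oop_fraction(lab))
            assert det.min() > 0

    def test_analytic_matches_finite_difference(self, default_spec,
                                                default_field, breathing):
        # central differences of the sampled field vs the closed form
        pts = _grid_point_array(default_spec)
        f, fo = 1.0, breathing.oop_fraction("100IN")
        u = default_field.displacement(pts, f, fo)
        G = np.stack([np.gradient(u, default_spec.spacing[j], axis=j)
                      for j in range(3)], axis=-1) + np.eye(3)
        det_fd = np.linalg.det(G)
        det = default_field.jacobian_det(pts, f, fo)
        assert np.sqrt(np.mean((det_fd - det) ** 2)) <= 1e-3

    def test_out_of_phase_region(self, default_spec, default_field, breathing):
        pts = _grid_point_array(default_spec)
        lung = default_spec.lung_membership(pts)
        oop = default_field.oop_membership(pts)
        frac = oop.sum() / lung.sum()
        assert frac == pytest.approx(0.076, abs=0.01)
        # expansion inside the label peaks at the shifted phase (60IN)
        det60 = default_field.jacobian_det(
            pts[oop], 0.6, breathing.oop_fraction("60IN"))
        det100 = default_field.jacobian_det(
            pts[oop], 1.0, breathing.oop_fraction("100IN"))
        assert np.mean(det60 > det100) >= 0.5

    def test_inverse_roundtrip(self, small_spec, small_field, breathing):
        pts = _grid_point_array(small_spec).reshape(-1, 3)[::11]
        x = small_field.inverse_point(pts, 1.0, 0.4)
        back = x + small_field.displacement(x, 1.0, 0.4)
        assert np.abs(back - pts).max() < 0.05  # mm


class TestSubjectImages:
    def test_exhale_phase_is_pristine_phantom(self, small_spec, small_field,
                                              breathing):
        img, mask, true_map = synthesize_phase(small_spec, small_field, 0.0, 0.0)
        assert np.all(true_map.data == 1.0)
        pts = _grid_point_array(small_spec)
        assert np.array_equal(img.data, small_spec.exhale_hu(pts))

    def test_requested_tidal_volume_realised(self, small_spec, breathing,
                                             small_field, small_pair):
        ex, ins = small_pair
        tv = ins.lung_volume_cc - ex.lung_volume_cc
        # target includes the seeded effort jitter around 1000 cc
        assert tv == pytest.approx(1000.0, rel=0.05)

    def test_tissue_volume_conserved(self, small_spec, small_pair):
        # sum of voxel volume x tissue fraction over the lung, both phases
        vol = small_spec.voxel_volume_cc
        masses = []
        for ph in small_pair:
            m = ph.mask.data > 0
            tissue = 1.0 - small_spec.air_fraction(ph.image.data[m])
            masses.append(np.sum(tissue) * vol)
        assert abs(masses[1] - masses[0]) / masses[0] < 0.005

    def test_deterministic_under_seed(self, small_spec, breathing, small_field):
        acq = AcquisitionSpec("4DCT", 20)
        a = make_subject_images(small_spec, breathing, small_field, acq,
                                ["0EX", "100IN"], seed=4)
        b = make_subject_images(small_spec, breathing, small_field, acq,
                                ["0EX", "100IN"], seed=4)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.image.data, pb.image.data)

    def test_ir_reuses_noise_realisation(self, small_spec, breathing, small_field):
        # same seed, IR on/off: identical noise field scaled by the IR factor
        plain = make_subject_images(
            small_spec, breathing, small_field,
            AcquisitionSpec("4DCT", 10, ir_applied=False), ["0EX"], seed=6)[0]
        ir = make_subject_images(
            small_spec, breathing, small_field,
            AcquisitionSpec("4DCT", 10, ir_applied=True), ["0EX"], seed=6)[0]
        noiseless = make_subject_images(
            small_spec, breathing, small_field,
            AcquisitionSpec("4DCT", 10, noise_scale=0.0), ["0EX"], seed=6)[0]
        n_plain = plain.image.data - noiseless.image.data
        n_ir = ir.image.data - noiseless.image.data
        assert np.allclose(n_ir, 0.6 * n_plain, atol=1e-9)

    def test_breath_hold_drift(self, small_spec, small_field):
        br = BreathingModel(drift_cc_per_scan=50.0, effort_sd_cc=0.0)
        acq = AcquisitionSpec("BHCT", 59, noise_scale=0.0)
        tv = []
        for i in (0, 2):
            scan = make_subject_images(small_spec, br, small_field, acq,
                                       ["MEBH", "MIBH"], seed=7, scan_index=i)
            tv.append(scan[1].lung_volume_cc - scan[0].lung_volume_cc)
        assert tv[1] - tv[0] == pytest.approx(100.0, abs=20.0)

    def test_unreachable_tidal_volume_raises(self, small_spec, small_field):
        br = BreathingModel(tidal_volume_full=30000.0)
        with pytest.raises(GenerationError):
            make_subject_images(small_spec, br, small_field,
                                AcquisitionSpec("4DCT", 100), ["0EX", "100IN"],
                                seed=0)


class TestBreathingModel:
    def test_phase_labels_fixed(self):
        with pytest.raises(ValueError, match="phase labels"):
            BreathingModel(phase_labels=("0EX", "50IN"))

    def test_schedule_endpoints(self, breathing):
        assert breathing.fraction("0EX") == 0.0
        assert breathing.fraction("100IN") == 1.0

    def test_hu_ordering_enforced(self):
        with pytest.raises(ValueError, match="hu_air"):
            PhantomSpec(hu_air=0.0)
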