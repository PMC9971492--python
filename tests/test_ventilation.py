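"""Lung masking, tidal volumes, ETV selection and ventilation mapping."""

import itertools

import numpy as np
import pytest

from ctvent.image import ImageVolume
from ctvent.phantom import AcquisitionSpec, make_subject_images
from ctvent.registration import RegistrationConfig
from ctvent.ventilation import (
    VolumeSeries,
    bh_ventilation,
    lern_ventilation,
    segment_lungs,
    select_etv,
    tidal_volumes,
)

FAST_CFG = RegistrationConfig(shrink_factors=(4, 2), iterations=(60, 40),
                              control_spacing=(48.0, 24.0))


def _dice(a, b):
    a, b = a > 0, b > 0
    return 2 * np.sum(a & b) / (a.sum() + b.sum())


class TestSegmentLungs:
    def test_noiseless_dice_at_full_resolution(self, default_spec):
        from ctvent.phantom import _exhale_image, _grid_point_array

        img = _exhale_image(default_spec)
        truth = default_spec.lung_membership(_grid_point_array(default_spec))
        est = segment_lungs(img)
        assert _dice(est.data, truth) >= 0.99

    def test_high_noise_dice_at_full_resolution(self, default_spec):
        from ctvent.phantom import _exhale_image, _grid_point_array
        from ctvent.noisecal import NOISE_MODEL_4DCT

        img = _exhale_image(default_spec)
        sigma = NOISE_MODEL_4DCT.noise_at(10)  # ~133 HU
        rng = np.random.default_rng(8)
        img.data = img.data + sigma * rng.standard_normal(img.data.shape)
        truth = default_spec.lung_membership(_grid_point_array(default_spec))
        est = segment_lungs(img)
        assert _dice(est.data, truth) >= 0.97

    def test_noisy_dice_coarse_grid(self, small_spec, breathing, small_field):
        acq = AcquisitionSpec("4DCT", 10)  # sigma ~133 HU
        ex = make_subject_images(small_spec, breathing, small_field, acq,
                                 ["0EX"], seed=11)[0]
        est = segment_lungs(ex.image)
        assert _dice(est.data, ex.mask.data) >= 0.95

    def test_all_tissue_image_raises(self):
        img = ImageVolume(np.full((24, 24, 24), 50.0), (4, 4, 4))
        with pytest.raises(ValueError):
            segment_lungs(img)

    def test_at_most_two_components(self, small_pair):
        from scipy import ndimage

        est = segment_lungs(small_pair[0].image)
        _, n = ndimage.label(est.data)
        assert n <= 2


class TestTidalVolumes:
    def test_single_phase_tv_is_zero(self, small_pair):
        series = tidal_volumes({"0EX": small_pair[0].mask})
        assert series.tidal_volume("0EX") == 0.0

    def test_generator_tidal_volume_from_true_masks(self, small_pair):
        ex, ins = small_pair
        series = tidal_volumes({"0EX": ex.mask, "100IN": ins.mask})
        assert series.tidal_volume("100IN") == pytest.approx(1000.0, rel=0.05)

    def test_monotone_over_inspiration(self, small_spec, breathing, small_field):
        acq = AcquisitionSpec("4DCT", 100, noise_scale=0.0)
        labels = ["0EX", "20IN", "60IN", "100IN"]
        scan = make_subject_images(small_spec, breathing, small_field, acq,
                                   labels, seed=11)
        series = tidal_volumes({ph.label: ph.mask for ph in scan})
        tvs = [series.tidal_volume(lab) for lab in labels]
        assert all(a < b for a, b in zip(tvs, tvs[1:]))

    def test_requires_end_exhale(self):
        with pytest.raises(ValueError, match="end-exhale"):
            VolumeSeries({"100IN": 3000.0})


class TestSelectEtv:
    def _series(self, tvs, exhale=2000.0):
        vols = {"0EX": exhale}
        vols.update({lab: exhale + tv for lab, tv in tvs.items()})
        return VolumeSeries(vols)

    def test_identical_series_pick_full_inhale(self):
        tvs = {"20IN": 200.0, "80IN": 800.0, "100IN": 1000.0}
        a = self._series(tvs)
        pa, pb, diff = select_etv(a, self._series(tvs))
        assert (pa, pb, diff) == ("100IN", "100IN", 0.0)

    def test_inflated_second_scan_drops_full_inhale(self):
        # scan B inhales 300 cc deeper; its 80IN matches A's 100IN
        a = self._series({"80IN": 800.0, "100IN": 1000.0})
        b = self._series({"80IN": 1000.0, "100IN": 1300.0})
        pa, pb, diff = select_etv(a, b)
        assert (pa, pb) == ("100IN", "80IN")
        assert diff == 0.0

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(3)
        labels = ["20IN", "40IN", "60IN", "80IN", "100IN"]
        for _ in range(25):
            a = self._series(dict(zip(labels, np.sort(rng.uniform(100, 1200, 5)))))
            b = self._series(dict(zip(labels, np.sort(rng.uniform(100, 1200, 5)))))
            pa, pb, diff = select_etv(a, b)
            brute = min(
                (abs(a.tidal_volume(x) - b.tidal_volume(y)) for x, y in
                 itertools.product(labels, labels)))
            assert diff == pytest.approx(brute)


@pytest.fixture(scope="module")
def lern_inputs(small_spec, breathing, small_field):
    acq = AcquisitionSpec("4DCT", 100, noise_scale=0.0)
    labels = ["0EX", "60IN", "80IN", "100IN"]
    scan = make_subject_images(small_spec, breathing, small_field, acq,
                               labels, seed=11)
    by = {ph.label: ph for ph in scan}
    masks = {lab: by[lab].mask for lab in labels}
    return by, masks


class TestVentilationMaps:
    def test_bh_map_mean_matches_volume_ratio(self, lern_inputs):
        by, masks = lern_inputs
        vmap = bh_ventilation(by["0EX"].image, masks["0EX"],
                              by["100IN"].image, masks["100IN"], FAST_CFG)
        ratio = (by["100IN"].lung_volume_cc / by["0EX"].lung_volume_cc)
        assert vmap.masked_values().mean() == pytest.approx(ratio, rel=0.08)
        assert (vmap.masked_values() > 0).all()

    def test_lern_is_voxelwise_max_of_phase_maps(self, lern_inputs):
        by, masks = lern_inputs
        phases = [(lab, by[lab].image, masks[lab])
                  for lab in ("60IN", "80IN", "100IN")]
        lern = lern_ventilation(phases, by["0EX"].image, masks["0EX"], FAST_CFG)
        singles = [bh_ventilation(by["0EX"].image, masks["0EX"], img, msk,
                                  FAST_CFG).values
                   for _, img, msk in phases]
        assert np.allclose(lern.values, np.maximum.reduce(singles), atol=1e-9)
        assert lern.provenance["phases"] == ["60IN", "80IN", "100IN"]

    def test_lern_phase_order_invariant(self, lern_inputs):
        by, masks = lern_inputs
        phases = [(lab, by[lab].image, masks[lab]) for lab in ("80IN", "100IN")]
        a = lern_ventilation(phases, by["0EX"].image, masks["0EX"], FAST_CFG)
        b = lern_ventilation(phases[::-1], by["0EX"].image, masks["0EX"],
                             FAST_CFG)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_lern_exceeds_single_phase_in_out_of_phase_region(
            self, small_spec, breathing, small_field, lern_inputs):
        by, masks = lern_inputs
        phases = [(lab, by[lab].image, masks[lab])
                  for lab in ("60IN", "80IN", "100IN")]
        lern = lern_ventilation(phases, by["0EX"].image, masks["0EX"], FAST_CFG)
        single = bh_ventilation(by["0EX"].image, masks["0EX"],
                                by["100IN"].image, masks["100IN"], FAST_CFG)
        from ctvent.phantom import _grid_point_array

        oop = small_field.oop_membership(_grid_point_array(small_spec))
        oop &= masks["0EX"].data > 0
        diff = lern.values[oop] - single.values[oop]
        assert (diff >= -1e-9).all()          # max property
        assert np.mean(diff > 1e-6) >= 0.5    # strictly larger for most voxels

    def test_lern_requires_two_phases(self, lern_inputs):
        by, masks = lern_inputs
        with pytest.raises(ValueError, match="at least two"):
            lern_ventilation([("100IN", by["100IN"].image, masks["100IN"])],
                             by["0EX"].image, masks["0EX"], FAST_CFG)

    def test_true_expansion_monotone_in_phase_without_oop(
            self, small_spec, breathing):
        # with no out-of-phase region the true map is largest at full
        # inspiration, so LER-N collapses onto the ETV-phase map
        from dataclasses import replace

        from ctvent.phantom import GroundTruthField, _grid_point_array

        br = replace(breathing, out_of_phase_fraction=0.0)
        field = GroundTruthField.build(small_spec, br)
        pts = _grid_point_array(small_spec)
        lung = small_spec.lung_membership(pts)
        dets = [field.jacobian_det(pts[lung], f, 0.0) for f in (0.6, 0.8, 1.0)]
        stacked = np.stack(dets)
        assert np.allclose(stacked.max(axis=0), dets[-1], atol=1e-12)
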