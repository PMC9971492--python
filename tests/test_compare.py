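"""Gamma analysis, rank correlation, Jacobian-ratio CoV and exclusions."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, map_coordinates

from conftest import make_map
from ctvent.compare import (
    GammaConfig,
    ProvenanceError,
    apply_exclusion,
    compare_maps,
    cov_jr,
    gamma_map,
    spearman_voxelwise,
    to_reference_frame,
)
from ctvent.image import ImageVolume
from ctvent.ventilation import VentilationMap


def brute_force_gamma(j1, j2, spacing, cfg, step_vox):
    """Straightforward exhaustive minimiser (independent oracle)."""
    sp = np.asarray(spacing, dtype=float)
    steps = step_vox * sp
    ax = [np.arange(-np.floor(cfg.radius / st), np.floor(cfg.radius / st) + 1) * st
          for st in steps]
    offsets = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    offsets = offsets[np.linalg.norm(offsets, axis=1) <= cfg.radius + 1e-9]
    best = np.full(j1.shape, np.inf)
    idx = np.argwhere(np.ones(j1.shape, bool))
    ref = j1[tuple(idx.T)]
    tol = cfg.ji_percent / 100.0 * ref
    for off in offsets:
        d2 = np.sum((off / cfg.dta_mm) ** 2)
        j2s = map_coordinates(j2, (idx + off / sp).T, order=1, mode="nearest")
        g2 = d2 + ((j2s - ref) / tol) ** 2
        best = np.minimum(best, g2.reshape(j1.shape))
    return 100.0 * np.mean(np.sqrt(best) <= 1.0 + 1e-9)


class TestGamma:
    def test_identical_maps_gamma_zero(self):
        j = 1.0 + 0.3 * np.random.default_rng(0).random((10, 10, 10))
        J = make_map(j)
        grid, rate = gamma_map(J, make_map(j.copy()))
        assert rate == 100.0
        assert np.nanmax(grid.data) == 0.0

    def test_uniform_six_percent_offset_passes_at_boundary(self):
        j1 = np.full((10, 10, 10), 1.3)
        _, rate = gamma_map(make_map(j1), make_map(1.06 * j1))
        assert rate == 100.0

    def test_seven_percent_offset_fails(self):
        j1 = np.full((10, 10, 10), 1.3)
        _, rate = gamma_map(make_map(j1), make_map(1.07 * j1))
        assert rate == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        j1 = 1.0 + 0.3 * gaussian_filter(rng.normal(size=(12, 12, 12)), 1.5)
        j2 = j1 * (1 + rng.normal(0, 0.05, size=j1.shape))
        cfg = GammaConfig(search_step_voxel=0.25)
        _, rate = gamma_map(make_map(j1), make_map(j2), cfg)
        oracle = brute_force_gamma(j1, j2, (3.0, 3.0, 3.0), cfg, 0.25)
        assert abs(rate - oracle) <= 100.0 / 12**3  # one voxel count

    def test_translation_within_dta_passes_on_smooth_maps(self):
        rng = np.random.default_rng(1)
        base = 1.2 + 0.2 * gaussian_filter(rng.normal(size=(14, 14, 14)), 3.0)
        j2 = np.roll(base, 1, axis=0)  # 3 mm shift > DTA 2 mm, but smooth
        # shift below the DTA criterion: half-voxel (1.5 mm) interpolated
        idx = np.stack(np.meshgrid(*[np.arange(14)] * 3, indexing="ij"), 0)
        coords = idx.astype(float)
        coords[0] += 0.5
        j2_half = map_coordinates(base, coords, order=1, mode="nearest")
        _, rate = gamma_map(make_map(base), make_map(j2_half))
        assert rate == 100.0

    def test_tightening_criteria_never_raises_pass_rate(self):
        rng = np.random.default_rng(2)
        j1 = 1.0 + 0.3 * gaussian_filter(rng.normal(size=(12, 12, 12)), 1.5)
        j2 = j1 * (1 + rng.normal(0, 0.08, size=j1.shape))
        rates = []
        for dta, ji in [(3.0, 9.0), (2.0, 6.0), (1.0, 3.0)]:
            _, r = gamma_map(make_map(j1), make_map(j2),
                             GammaConfig(dta_mm=dta, ji_percent=ji))
            rates.append(r)
        assert rates[0] >= rates[1] >= rates[2]

    def test_nonpositive_reference_voxels_excluded(self):
        j1 = np.full((8, 8, 8), 1.2)
        j1[0, 0, 0] = -0.5
        grid, rate = gamma_map(make_map(j1), make_map(np.full_like(j1, 1.2)))
        assert grid.meta["n_excluded"] == 1
        assert np.isnan(grid.data[0, 0, 0])
        assert rate == 100.0


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        j = 1.0 + np.random.default_rng(0).random((8, 8, 8))
        rho, label = spearman_voxelwise(make_map(j), make_map(j**3))
        assert rho == pytest.approx(1.0)
        assert label == "strong"

    def test_antimonotone_gives_minus_one(self):
        j = 1.0 + np.random.default_rng(0).random((8, 8, 8))
        rho, label = spearman_voxelwise(make_map(j), make_map(3.0 - j))
        assert rho == pytest.approx(-1.0)
        assert label == "not strong"

    def test_permutation_null_centres_on_zero(self):
        rng = np.random.default_rng(4)
        j = 1.0 + rng.random((10, 10, 10))
        rhos = []
        for _ in range(40):
            perm = rng.permutation(j.ravel()).reshape(j.shape)
            rhos.append(spearman_voxelwise(make_map(j), make_map(perm))[0])
        assert abs(np.mean(rhos)) < 3.0 / np.sqrt(40 * j.size)

    def test_needs_ten_voxels(self):
        j = np.ones((2, 2, 2))
        with pytest.raises(ValueError, match="10 masked"):
            spearman_voxelwise(make_map(j), make_map(j))


class TestCovJR:
    def test_identical_maps_give_zero(self):
        j = 1.0 + np.random.default_rng(0).random((8, 8, 8))
        mu, sd, cov = cov_jr(make_map(j), make_map(j.copy()))
        assert mu == pytest.approx(1.0)
        assert cov == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        j1 = 1.0 + rng.random((8, 8, 8))
        j2 = j1 * (1 + rng.normal(0, 0.05, j1.shape))
        _, _, cov_a = cov_jr(make_map(j1), make_map(j2))
        _, _, cov_b = cov_jr(make_map(j1), make_map(3.7 * j2))
        assert cov_b == pytest.approx(cov_a, rel=1e-12)

    def test_lognormal_ratio_cov(self):
        # JR ~ lognormal(0, 0.04): CoV = sqrt(exp(s^2) - 1) ~ 0.04
        rng = np.random.default_rng(2)
        n = 40**3
        j1 = np.ones((40, 40, 40))
        jr = rng.lognormal(0.0, 0.04, size=j1.shape)
        _, _, cov = cov_jr(make_map(j1), make_map(jr))
        expected = np.sqrt(np.exp(0.04**2) - 1)
        se = expected / np.sqrt(2 * n)
        assert abs(cov - expected) < 3 * se

    def test_fwhm_estimator_close_to_sample_sd_for_gaussian(self):
        rng = np.random.default_rng(3)
        j1 = np.ones((32, 32, 32))
        jr = 1.0 + rng.normal(0, 0.05, j1.shape)
        _, sd, _ = cov_jr(make_map(j1), make_map(jr))
        _, sd_fwhm, _ = cov_jr(make_map(j1), make_map(jr), sd_from_fwhm=True)
        assert sd_fwhm == pytest.approx(sd, rel=0.15)


class TestToReferenceFrame:
    def test_identical_frames_unchanged(self, small_pair):
        ex, ins = small_pair
        vmap = VentilationMap(ins.true_map, ex.mask, {"mode": "4DCT", "ir": False})
        ref = VentilationMap(ins.true_map.copy(), ex.mask, {"mode": "4DCT", "ir": False})
        out = to_reference_frame(vmap, ex.image, ref, ex.image)
        assert np.array_equal(out.values, vmap.values)

    def test_known_shift_recovered(self, small_pair):
        # inject a one-voxel rigid shift between the exhale frames
        ex, ins = small_pair
        shift_img = ImageVolume(np.roll(ex.image.data, 1, axis=2),
                                ex.image.spacing)
        shift_mask = ImageVolume(np.roll(ex.mask.data, 1, axis=2),
                                 ex.mask.spacing)
        shift_map = ImageVolume(np.roll(ins.true_map.data, 1, axis=2),
                                ins.true_map.spacing)
        red = VentilationMap(shift_map, shift_mask, {"mode": "4DCT"})
        ref = VentilationMap(ins.true_map, ex.mask, {"mode": "4DCT"})
        from ctvent.registration import RegistrationConfig

        cfg = RegistrationConfig(shrink_factors=(2, 1), iterations=(40, 30),
                                 control_spacing=(48.0, 24.0))
        out = to_reference_frame(red, shift_img, ref, ex.image, cfg)
        m = (out.mask.data > 0) & (ref.mask.data > 0)
        err = np.abs(out.values[m] - ref.values[m])
        assert np.median(err) < 0.02  # residual well under the map contrast

    def test_mode_mismatch_refused(self, small_pair):
        ex, ins = small_pair
        a = VentilationMap(ins.true_map, ex.mask, {"mode": "4DCT", "ir": False})
        b = VentilationMap(ins.true_map, ex.mask, {"mode": "BHCT", "ir": False})
        with pytest.raises(ProvenanceError, match="mode"):
            to_reference_frame(a, ex.image, b, ex.image)

    def test_ir_mismatch_refused(self, small_pair):
        ex, ins = small_pair
        a = VentilationMap(ins.true_map, ex.mask, {"mode": "4DCT", "ir": True})
        b = VentilationMap(ins.true_map, ex.mask, {"mode": "4DCT", "ir": False})
        with pytest.raises(ProvenanceError, match="ir"):
            to_reference_frame(a, ex.image, b, ex.image)


class TestExclusionRule:
    def _report(self, tv):
        j = 1.0 + np.random.default_rng(0).random((8, 8, 8))
        return compare_maps(make_map(j), make_map(j * 1.01), tv)

    def test_99cc_retained(self):
        rep = self._report(99.0)
        assert not rep.excluded_from_gamma_cov
        assert rep.gamma_pass_rate is not None

    def test_100cc_retained_strict_inequality(self):
        rep = self._report(100.0)
        assert not rep.excluded_from_gamma_cov

    def test_101cc_excludes_gamma_and_cov_keeps_rho(self):
        rep = self._report(101.0)
        assert rep.excluded_from_gamma_cov
        assert rep.gamma_pass_rate is None
        assert rep.cov_jr is None
        assert np.isfinite(rep.spearman_rho)

    def test_idempotent(self):
        rep = apply_exclusion(self._report(150.0))
        assert rep.gamma_pass_rate is None
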