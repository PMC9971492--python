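"""Synthetic CT inputs: uniformity phantom and a deforming digital lung.

Two generators live here.

* A uniform cylinder ("uniformity phantom") with additive Gaussian HU noise
  whose standard deviation follows the power law ``sigma = A * mAs**(-B)``.
  It drives the noise--mAs calibration.

* A breathing digital subject: a soft-tissue body containing two ellipsoidal
  lungs, deformed through the breathing cycle by a known smooth displacement
  field with a closed-form spatial Jacobian.  HU values co-vary with local
  air content so that per-voxel *tissue* volume is conserved under the
  deformation -- the same physical assumption the SSTVD registration
  similarity makes.  Every phase image therefore comes with its true lung
  mask and true per-voxel expansion (Jacobian determinant) on the end-exhale
  frame, so downstream registration and biomarker code can be validated
  without any external data.

The deformation is a superposition of per-lung inflation lobes
(diaphragm-dominant: the axial gain exceeds the transverse gains) plus an
optional "out-of-phase" sub-region whose expansion peaks at a different
breathing phase than the global lung volume.  Displacement amplitude is
calibrated by root-finding so the mask-derived tidal volume matches the
requested value.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.optimize import brentq

from .image import ImageVolume
from .noisecal import NOISE_MODEL_4DCT, NOISE_MODEL_BHCT, SCANNER_MIN_MAS, NoiseModel

__all__ = [
    "PHASE_LABELS",
    "BH_LABELS",
    "GenerationError",
    "PhantomSpec",
    "BreathingModel",
    "GroundTruthField",
    "AcquisitionSpec",
    "UniformitySpec",
    "SubjectPhase",
    "make_uniformity_phantom",
    "make_subject_images",
    "synthesize_phase",
    "ctdi_for",
]

#: 4DCT breathing phases in acquisition order: inspiratory (IN) limb from
#: full exhale to full inhale, then the expiratory (EX) limb.
PHASE_LABELS = (
    "0EX", "20IN", "40IN", "60IN", "80IN", "100IN",
    "80EX", "60EX", "40EX", "20EX",
)

#: Breath-hold volumes: maximum expiration, 80% inspiration, maximum
#: inspiration (analogous to 0EX, 80IN and 100IN).
BH_LABELS = ("MEBH", "80%Insp", "MIBH")


class GenerationError(RuntimeError):
    """Raised when a synthetic subject cannot meet its requested physiology."""


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and HU constants of the digital subject.

    The body is a capped cylinder of soft tissue along z; two ellipsoidal
    lungs sit inside it.  ``lung_centers`` are mm offsets from the grid
    centre.  Defaults give ~2 L of lung at end exhale, sized so a 1000 cc
    tidal volume produces mean Jacobians in the physiological 1-1.6 range.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    body_radius: float = 135.0        # mm, cylinder radius in the axial plane
    body_half_length: float = 132.0   # mm, half-extent of the body along z
    lung_centers: tuple[tuple[float, float, float], ...] = (
        (-55.0, 0.0, 0.0),
        (55.0, 0.0, 0.0),
    )
    lung_radii: tuple[tuple[float, float, float], ...] = (
        (46.0, 52.0, 100.0),
        (46.0, 52.0, 100.0),
    )
    hu_tissue: float = 50.0
    hu_lung_exhale: float = -750.0
    hu_air: float = -1000.0
    #: parenchymal density texture inside the lungs (vessels, lobular
    #: structure): SD of the air-fraction modulation and its spatial scale.
    #: The texture is a seeded band-limited cosine series, analytic at any
    #: point, so it advects exactly with the ground-truth deformation.
    texture_amp: float = 0.06
    texture_scale_mm: float = 28.0
    texture_modes: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hu_air < self.hu_lung_exhale < self.hu_tissue:
            raise ValueError("require hu_air < hu_lung_exhale < hu_tissue")
        if len(self.lung_centers) != len(self.lung_radii):
            raise ValueError("one radii triple per lung centre")
        half = [(n - 1) / 2.0 * s for n, s in zip(self.grid_shape, self.spacing)]
        if self.body_radius >= min(half[0], half[1]) or self.body_half_length >= half[2]:
            raise ValueError("body must lie strictly inside the grid")
        for c, r in zip(self.lung_centers, self.lung_radii):
            # lungs strictly inside the body cylinder
            if np.hypot(abs(c[0]) + r[0], abs(c[1]) + r[1]) >= self.body_radius:
                raise ValueError("lungs must lie strictly inside the body (axially)")
            if abs(c[2]) + r[2] >= self.body_half_length:
                raise ValueError("lungs must lie strictly inside the body (axially, z)")

    # -- geometry helpers ---------------------------------------------------
    @property
    def grid_center(self) -> np.ndarray:
        return np.array(
            [(n - 1) / 2.0 * s for n, s in zip(self.grid_shape, self.spacing)]
        )

    @property
    def lung_centers_abs(self) -> np.ndarray:
        return self.grid_center[None, :] + np.asarray(self.lung_centers, dtype=float)

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def grid_points(self) -> tuple[np.ndarray, ...]:
        axes = [np.arange(n) * s for n, s in zip(self.grid_shape, self.spacing)]
        return np.meshgrid(*axes, indexing="ij", sparse=True)

    def lung_membership(self, pts: np.ndarray) -> np.ndarray:
        """Boolean: point inside any lung ellipsoid (points shape (..., 3))."""
        inside = np.zeros(pts.shape[:-1], dtype=bool)
        for c, r in zip(self.lung_centers_abs, np.asarray(self.lung_radii)):
            q = (pts - c) / r
            inside |= np.einsum("...d,...d->...", q, q) <= 1.0
        return inside

    def body_membership(self, pts: np.ndarray) -> np.ndarray:
        cc = self.grid_center
        ax = (pts[..., 0] - cc[0]) ** 2 + (pts[..., 1] - cc[1]) ** 2
        return (ax <= self.body_radius**2) & (
            np.abs(pts[..., 2] - cc[2]) <= self.body_half_length
        )

    def _texture_modes(self):
        rng = np.random.default_rng(int(self.seed) + 7919)
        k = self.texture_modes
        dirs = rng.normal(size=(k, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        wavelength = self.texture_scale_mm * rng.uniform(0.7, 1.3, size=k)
        kvec = 2.0 * np.pi * dirs / wavelength[:, None]
        phase = rng.uniform(0, 2 * np.pi, size=k)
        amp = rng.normal(size=k)
        amp *= self.texture_amp / np.sqrt(np.sum(amp**2) / 2.0)
        return kvec, phase, amp

    def texture(self, pts: np.ndarray) -> np.ndarray:
        """Seeded band-limited air-fraction modulation at physical points."""
        if self.texture_amp == 0 or self.texture_modes == 0:
            return np.zeros(np.asarray(pts).shape[:-1])
        kvec, phase, amp = self._texture_modes()
        flat = np.asarray(pts, dtype=float).reshape(-1, 3)
        out = np.zeros(len(flat))
        for i in range(len(amp)):
            out += amp[i] * np.cos(flat @ kvec[i] + phase[i])
        return out.reshape(np.asarray(pts).shape[:-1])

    def exhale_hu(self, pts: np.ndarray) -> np.ndarray:
        """Analytic end-exhale HU at arbitrary physical points."""
        hu = np.full(pts.shape[:-1], self.hu_air, dtype=float)
        body = self.body_membership(pts)
        hu[body] = self.hu_tissue
        lung = self.lung_membership(pts)
        a_lung = self.air_fraction(np.float64(self.hu_lung_exhale))
        a = a_lung + self.texture(pts[lung])
        np.clip(a, 0.05, 0.98, out=a)
        hu[lung] = self.hu_from_air_fraction(a)
        return hu

    def air_fraction(self, hu: np.ndarray) -> np.ndarray:
        """Voxel air fraction a = (HU - hu_tissue) / (hu_air - hu_tissue)."""
        return (hu - self.hu_tissue) / (self.hu_air - self.hu_tissue)

    def hu_from_air_fraction(self, a: np.ndarray) -> np.ndarray:
        return self.hu_tissue + a * (self.hu_air - self.hu_tissue)

    def perturbed(self, seed: int, rel_sd: float = 0.03) -> "PhantomSpec":
        """Anatomy jitter between subjects: lung radii scaled by ~N(1, rel_sd)."""
        rng = np.random.default_rng(seed)
        radii = np.asarray(self.lung_radii, dtype=float)
        radii = radii * np.clip(rng.normal(1.0, rel_sd, size=radii.shape), 0.9, 1.1)
        return replace(self, lung_radii=tuple(tuple(r) for r in radii), seed=seed)


def _grid_point_array(spec: PhantomSpec) -> np.ndarray:
    """Dense (nx, ny, nz, 3) array of physical voxel-centre coordinates."""
    axes = [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing)]
    xs, ys, zs = np.meshgrid(*axes, indexing="ij")
    return np.stack([xs, ys, zs], axis=-1)


def _exhale_image(spec: PhantomSpec) -> ImageVolume:
    pts = _grid_point_array(spec)
    return ImageVolume(spec.exhale_hu(pts), spec.spacing)


# ---------------------------------------------------------------------------
# breathing schedule
# ---------------------------------------------------------------------------

_DEFAULT_PHASE_FRACTION = {
    "0EX": 0.0, "20IN": 0.2, "40IN": 0.4, "60IN": 0.6, "80IN": 0.8,
    "100IN": 1.0, "80EX": 0.8, "60EX": 0.6, "40EX": 0.4, "20EX": 0.2,
}

#: Expansion schedule of the out-of-phase sub-region: peaks at 60IN/60EX
#: rather than at full inspiration.
_DEFAULT_OOP_FRACTION = {
    "0EX": 0.0, "20IN": 0.5, "40IN": 0.85, "60IN": 1.0, "80IN": 0.75,
    "100IN": 0.4, "80EX": 0.75, "60EX": 1.0, "40EX": 0.85, "20EX": 0.5,
}

_BH_FRACTION = {"MEBH": 0.0, "80%Insp": 0.8, "MIBH": 1.0}


@dataclass(frozen=True)
class BreathingModel:
    """Breathing schedule and effort parameters of the mechanical ventilator.

    ``phase_fraction`` maps each phase label to the fraction of full
    inspiration (displacement amplitude scale) in [0, 1].
    ``out_of_phase_fraction`` is the fraction of total lung volume whose
    expansion peaks at a different phase (7.6% on average in mechanically
    ventilated swine).  ``drift_cc_per_scan`` adds a systematic inhale-volume
    drift across repeated breath-hold scans; ``effort_sd_cc`` is the random
    scan-to-scan tidal-volume variability (a few cc under mechanical
    ventilation).
    """

    phase_labels: tuple[str, ...] = PHASE_LABELS
    tidal_volume_full: float = 1000.0          # cc at 100IN
    phase_fraction: dict = dc_field(default_factory=lambda: dict(_DEFAULT_PHASE_FRACTION))
    out_of_phase_fraction: float = 0.076
    oop_phase_fraction: dict = dc_field(default_factory=lambda: dict(_DEFAULT_OOP_FRACTION))
    drift_cc_per_scan: float = 0.0
    effort_sd_cc: float = 4.0

    def __post_init__(self) -> None:
        if tuple(self.phase_labels) != PHASE_LABELS:
            raise ValueError(f"phase labels must be {PHASE_LABELS}")
        if self.phase_fraction["0EX"] != 0.0 or self.phase_fraction["100IN"] != 1.0:
            raise ValueError("phase_fraction must satisfy f(0EX)=0 and f(100IN)=1")
        if not 0.0 <= self.out_of_phase_fraction < 1.0:
            raise ValueError("out_of_phase_fraction must lie in [0, 1)")
        if self.tidal_volume_full <= 0:
            raise ValueError("tidal_volume_full must be positive")

    def fraction(self, label: str) -> float:
        if label in self.phase_fraction:
            return self.phase_fraction[label]
        if label in _BH_FRACTION:
            return _BH_FRACTION[label]
        raise KeyError(f"unknown phase/breath-hold label {label!r}")

    def oop_fraction(self, label: str) -> float:
        if self.out_of_phase_fraction == 0.0:
            return 0.0
        if label in self.oop_phase_fraction:
            return self.oop_phase_fraction[label]
        # breath-holds: the sub-region holds at its 100IN/0EX schedule value
        if label in _BH_FRACTION:
            return {"MEBH": 0.0, "80%Insp": self.oop_phase_fraction["80IN"],
                    "MIBH": self.oop_phase_fraction["100IN"]}[label]
        raise KeyError(f"unknown phase/breath-hold label {label!r}")

    @property
    def inhale_labels(self) -> tuple[str, ...]:
        return tuple(p for p in self.phase_labels if p.endswith("IN"))


# ---------------------------------------------------------------------------
# ground-truth displacement field
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Lobe:
    """One inflation lobe: u_d(x) = gain_d * (x_d - c_d) * w(rho^2).

    ``rho^2 = sum_j ((x_j - c_j)/R_j)^2`` in lung-normalised coordinates.
    Two window shapes, both with closed-form gradients:

    ``flat=False`` (main lungs): Gaussian ``w = exp(-rho^2 / (2 sigma^2))``.
    Expansion fills the lung (``w`` large where rho < 1) and the
    compensating compression is spread gently over the surrounding body,
    which keeps the Jacobian determinant positive with a wide margin and
    produces a physiological centre-to-periphery ventilation gradient.

    ``flat=True`` (out-of-phase sub-region): plateau window
    ``w = (1 - rho^4)^2`` on rho < 1, compactly supported, so the interior
    of the labelled region genuinely peaks at its own phase schedule.
    """

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    gain: tuple[float, float, float]
    sigma: float = 0.95
    flat: bool = False

    def _rho2(self, pts: np.ndarray) -> np.ndarray:
        q = (pts - np.asarray(self.center)) / np.asarray(self.radii)
        return np.einsum("...d,...d->...", q, q)

    def window(self, rho2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Window value and its derivative with respect to rho^2."""
        if self.flat:
            t = 1.0 - rho2**2
            inside = rho2 < 1.0
            w = np.where(inside, t**2, 0.0)
            dw = np.where(inside, -4.0 * rho2 * t, 0.0)
        else:
            w = np.exp(-rho2 / (2.0 * self.sigma**2))
            dw = -w / (2.0 * self.sigma**2)
        return w, dw

    def evaluate(
        self, pts: np.ndarray, need_grad: bool = False
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Displacement and (optionally) its spatial gradient in one pass.

        Returns ``(u, G)`` with ``G[..., d, j] = du_d/dx_j`` or ``G=None``.
        Sharing the radial terms between the two outputs roughly halves the
        cost of a Newton step during inverse mapping.
        """
        c = np.asarray(self.center)
        R = np.asarray(self.radii)
        g = np.asarray(self.gain)
        d = pts - c
        rho2 = self._rho2(pts)
        w, dw = self.window(rho2)
        u = g * d * w[..., None]
        if not need_grad:
            return u, None
        # du_d/dx_j = g_d [delta_dj w + (x_d-c_d) dw * 2 (x_j-c_j)/R_j^2]
        a = (g * d) * dw[..., None]
        b = 2.0 * d / R**2
        grad = a[..., :, None] * b[..., None, :]
        gw = g * w[..., None]
        grad[..., 0, 0] += gw[..., 0]
        grad[..., 1, 1] += gw[..., 1]
        grad[..., 2, 2] += gw[..., 2]
        return u, grad

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        return self.evaluate(pts)[0]

    def gradient(self, pts: np.ndarray) -> np.ndarray:
        """Spatial gradient du_d/dx_j, shape (..., 3, 3)."""
        return self.evaluate(pts, need_grad=True)[1]

    @property
    def support_radii(self) -> np.ndarray | None:
        """Compact support radii, or None for the (global) Gaussian window."""
        return np.asarray(self.radii) if self.flat else None


@dataclass(frozen=True)
class GroundTruthField:
    """Parametric displacement u(x; f) with closed-form spatial Jacobian.

    ``u(x; f, f_oop) = f * amplitude * u_main(x) + f_oop * oop_amplitude *
    u_oop(x)`` where ``u_main`` sums the per-lung inflation lobes and
    ``u_oop`` is the out-of-phase bump (if present).  ``u(x; 0, 0) = 0``.
    """

    main_lobes: tuple[_Lobe, ...]
    amplitude: float
    oop_lobe: _Lobe | None = None
    oop_amplitude: float = 0.2
    #: labelled out-of-phase region: (centre, radii) ellipsoid holding the
    #: requested fraction of lung volume; the driving lobe is broader than
    #: the label so the window stays near 1 across the labelled voxels
    oop_label: tuple[tuple[float, ...], tuple[float, ...]] | None = None

    # -- construction -------------------------------------------------------
    @classmethod
    def build(
        cls,
        spec: PhantomSpec,
        breathing: BreathingModel,
        axial_gain: tuple[float, float, float] = (0.55, 0.55, 1.0),
        sigma: float = 0.95,
        oop_amplitude: float = 0.2,
        amplitude: float | None = None,
    ) -> "GroundTruthField":
        """Build the field for a phantom, calibrating the amplitude so the
        mask-derived tidal volume at full inspiration matches the breathing
        model's ``tidal_volume_full``."""
        lobes = tuple(
            _Lobe(tuple(c), tuple(r), axial_gain, sigma)
            for c, r in zip(spec.lung_centers_abs, spec.lung_radii)
        )
        oop, label = (None, None)
        if breathing.out_of_phase_fraction > 0:
            oop, label = _make_oop_lobe(spec, breathing.out_of_phase_fraction)
        fld = cls(lobes, amplitude=amplitude if amplitude is not None else 0.3,
                  oop_lobe=oop, oop_amplitude=oop_amplitude, oop_label=label)
        if amplitude is None:
            fld = fld.calibrated_for(
                spec, breathing.tidal_volume_full,
                f_oop_at_full=breathing.oop_fraction("100IN"),
            )
        return fld

    def calibrated_for(
        self, spec: PhantomSpec, tv_cc: float, f_oop_at_full: float = 0.0
    ) -> "GroundTruthField":
        """Return a copy whose amplitude yields the requested tidal volume.

        The tidal volume at full inspiration equals the integral of
        ``det - 1`` over the end-exhale lung region; that integral is a
        monotone function of the amplitude, solved here by bracketing.
        """
        pts = _grid_point_array(spec)
        lung = spec.lung_membership(pts)
        lung_pts = pts[lung]
        voxcc = spec.voxel_volume_cc

        def tv_of(amp: float) -> float:
            f = replace(self, amplitude=amp)
            det = f.jacobian_det(lung_pts, 1.0, f_oop_at_full)
            return float(np.sum(det - 1.0)) * voxcc - tv_cc

        hi = 0.6
        while tv_of(hi) < 0:
            hi *= 1.5
            if hi > 4.0:
                raise GenerationError(
                    f"cannot reach a {tv_cc:.0f} cc tidal volume with this anatomy"
                )
        amp = brentq(tv_of, 0.0, hi, xtol=1e-6)
        out = replace(self, amplitude=float(amp))
        det_min = float(np.min(out.jacobian_det(lung_pts, 1.0, f_oop_at_full)))
        if det_min <= 0:
            raise GenerationError(
                f"calibrated field folds (min det {det_min:.3f}); reduce the "
                "tidal volume or enlarge the lungs"
            )
        return out

    # -- evaluation ---------------------------------------------------------
    def evaluate(
        self, pts: np.ndarray, f: float, f_oop: float = 0.0,
        need_grad: bool = False,
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Displacement and optionally its spatial gradient at ``pts``."""
        pts = np.asarray(pts, dtype=float)
        u = np.zeros_like(pts)
        G = np.zeros(pts.shape[:-1] + (3, 3)) if need_grad else None
        weights: list[tuple[float, _Lobe]] = []
        if f != 0.0:
            weights += [(f * self.amplitude, lobe) for lobe in self.main_lobes]
        if self.oop_lobe is not None and f_oop != 0.0:
            weights.append((f_oop * self.oop_amplitude, self.oop_lobe))
        for wgt, lobe in weights:
            ul, Gl = lobe.evaluate(pts, need_grad=need_grad)
            u += wgt * ul
            if need_grad:
                G += wgt * Gl
        return u, G

    def displacement(self, pts: np.ndarray, f: float, f_oop: float = 0.0) -> np.ndarray:
        return self.evaluate(pts, f, f_oop)[0]

    def jacobian_matrix(self, pts: np.ndarray, f: float, f_oop: float = 0.0) -> np.ndarray:
        """d(x+u)/dx = I + grad u, shape (..., 3, 3)."""
        G = self.evaluate(pts, f, f_oop, need_grad=True)[1]
        G[..., 0, 0] += 1.0
        G[..., 1, 1] += 1.0
        G[..., 2, 2] += 1.0
        return G

    def jacobian_det(self, pts: np.ndarray, f: float, f_oop: float = 0.0) -> np.ndarray:
        J = self.jacobian_matrix(pts, f, f_oop)
        return _det3(J)

    def support_bbox(self, spec: PhantomSpec, margin_mm: float = 6.0):
        """Index-space slices covering the region where the field is
        non-negligible; the whole grid when a Gaussian lobe is present."""
        lobes = list(self.main_lobes) + ([self.oop_lobe] if self.oop_lobe else [])
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for lobe in lobes:
            r = lobe.support_radii
            if r is None:  # Gaussian window: global support
                return tuple(slice(0, n) for n in spec.grid_shape)
            c = np.asarray(lobe.center)
            lo = np.minimum(lo, c - r - margin_mm)
            hi = np.maximum(hi, c + r + margin_mm)
        sl = []
        for d in range(3):
            i0 = max(0, int(np.floor(lo[d] / spec.spacing[d])))
            i1 = min(spec.grid_shape[d], int(np.ceil(hi[d] / spec.spacing[d])) + 1)
            sl.append(slice(i0, i1))
        return tuple(sl)

    def oop_membership(self, pts: np.ndarray) -> np.ndarray:
        """Boolean label of the out-of-phase sub-region."""
        if self.oop_label is None:
            return np.zeros(np.asarray(pts).shape[:-1], dtype=bool)
        c, r = self.oop_label
        q = (np.asarray(pts, dtype=float) - np.asarray(c)) / np.asarray(r)
        return np.einsum("...d,...d->...", q, q) <= 1.0

    def inverse_point(
        self, pts: np.ndarray, f: float, f_oop: float = 0.0,
        max_iter: int = 12, tol_mm: float = 0.01,
        u_at_pts: np.ndarray | None = None,
    ) -> np.ndarray:
        """Invert y = x + u(x) by Newton iteration (vectorised).

        Starts from the first-order guess ``x = y - u(y)`` (exact to
        O(|grad u| |u|)), keeps only points whose residual still exceeds
        ``tol_mm``, and polishes those with Newton steps -- the residual's
        Jacobian ``I + grad u`` is available in closed form.  ``u_at_pts``
        may supply a precomputed ``u(y)`` to avoid one field evaluation.
        """
        shape = np.asarray(pts).shape
        y = np.asarray(pts, dtype=float).reshape(-1, 3)
        u0 = (self.displacement(y, f, f_oop) if u_at_pts is None
              else np.asarray(u_at_pts, dtype=float).reshape(-1, 3))
        x = y - u0
        res = x + self.displacement(x, f, f_oop) - y
        active = np.max(np.abs(res), axis=-1) >= tol_mm
        for _ in range(max_iter):
            if not active.any():
                break
            xa, ya = x[active], y[active]
            u, G = self.evaluate(xa, f, f_oop, need_grad=True)
            G[..., 0, 0] += 1.0
            G[..., 1, 1] += 1.0
            G[..., 2, 2] += 1.0
            step = np.linalg.solve(G, (xa + u - ya)[..., None])[..., 0]
            x[active] = xa - step
            conv = np.max(np.abs(step), axis=-1) < tol_mm
            idx = np.flatnonzero(active)
            active[idx[conv]] = False
        return x.reshape(shape)


def _det3(M: np.ndarray) -> np.ndarray:
    a, b, c = M[..., 0, 0], M[..., 0, 1], M[..., 0, 2]
    d, e, f = M[..., 1, 0], M[..., 1, 1], M[..., 1, 2]
    g, h, i = M[..., 2, 0], M[..., 2, 1], M[..., 2, 2]
    return a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)


def _make_oop_lobe(spec: PhantomSpec, volume_fraction: float, spread: float = 1.6):
    """Out-of-phase driver inside the last lung.

    Returns ``(lobe, (label_center, label_radii))``: the label ellipsoid
    holds ``volume_fraction`` of the total lung volume; the Gaussian driving
    lobe is ``spread`` times broader so its window stays near 1 across the
    label and the labelled interior genuinely peaks off-phase.
    """
    radii = np.asarray(spec.lung_radii, dtype=float)
    v_lungs = 4.0 / 3.0 * np.pi * np.prod(radii, axis=1).sum()
    aspect = np.array([1.0, 1.0, 1.3])
    r = (volume_fraction * v_lungs * 3.0 / (4.0 * np.pi * np.prod(aspect))) ** (1.0 / 3.0)
    r_label = aspect * r
    host_c = spec.lung_centers_abs[-1]
    host_r = radii[-1]
    center = host_c + np.array([0.0, 0.0, -(host_r[2] - r_label[2]) * 0.55])
    lobe = _Lobe(tuple(center), tuple(spread * r_label), (1.0, 1.0, 1.0), sigma=0.95)
    return lobe, (tuple(center), tuple(r_label))


# ---------------------------------------------------------------------------
# acquisition and dose
# ---------------------------------------------------------------------------

#: CTDI_vol anchors (mAs, mGy) per acquisition mode for dose scaling.  The
#: 4DCT anchor is the low-dose end of the clinical range; the BHCT anchor is
#: the full-dose (59 mAs) scan.
DEFAULT_CTDI_REF = {"4DCT": (10.0, 6.07), "BHCT": (59.0, 7.9)}


@dataclass(frozen=True)
class AcquisitionSpec:
    """One scan's acquisition parameters.

    ``noise_scale`` multiplies the model noise SD (0 disables noise, useful
    for measuring registration-only error floors); ``ctdi_ref`` is an
    (mAs, CTDI_vol mGy) anchor pair for linear dose scaling.
    """

    mode: str
    mAs: float
    ir_applied: bool = False
    ctdi_ref: tuple[float, float] | None = None
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("4DCT", "BHCT"):
            raise ValueError(f"mode must be '4DCT' or 'BHCT', got {self.mode!r}")
        if self.mAs < SCANNER_MIN_MAS:
            raise ValueError(
                f"mAs = {self.mAs} below the scanner minimum of "
                f"{SCANNER_MIN_MAS:.0f} mAs (0.5 s rotation)"
            )
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")


def ctdi_for(acq: AcquisitionSpec) -> float:
    """CTDI_vol (mGy) for an acquisition, scaled linearly with mAs.

    Dose is proportional to the tube current-time product, so the anchor
    pair fixes the line: CTDI = CTDI_ref * mAs / mAs_ref.
    """
    ref = acq.ctdi_ref if acq.ctdi_ref is not None else DEFAULT_CTDI_REF[acq.mode]
    mas_ref, ctdi_ref = ref
    if mas_ref <= 0:
        raise ValueError("reference mAs must be positive")
    return ctdi_ref * acq.mAs / mas_ref


# ---------------------------------------------------------------------------
# uniformity phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniformitySpec:
    """Uniform cylinder for noise calibration (water-equivalent centre)."""

    grid_shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    radius_mm: float = 90.0
    hu_uniform: float = 0.0
    hu_background: float = -1000.0


def make_uniformity_phantom(
    noise_model: NoiseModel,
    mAs: float,
    ir: bool = False,
    seed: int = 0,
    spec: UniformitySpec | None = None,
    noise_scale: float = 1.0,
) -> ImageVolume:
    """Uniform cylinder plus zero-mean Gaussian HU noise.

    The noise SD is ``noise_model.noise_at(mAs)``, reduced by the model's
    IR factor when ``ir`` is set.  Reproducible under a fixed seed.
    """
    if mAs < SCANNER_MIN_MAS:
        raise ValueError(
            f"mAs = {mAs} below the scanner minimum of {SCANNER_MIN_MAS:.0f} mAs"
        )
    spec = spec or UniformitySpec()
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing
    cx, cy = (nx - 1) / 2.0 * sx, (ny - 1) / 2.0 * sy
    x = (np.arange(nx) * sx - cx)[:, None]
    y = (np.arange(ny) * sy - cy)[None, :]
    disk = (x**2 + y**2 <= spec.radius_mm**2)
    data = np.where(disk, spec.hu_uniform, spec.hu_background)[..., None]
    data = np.broadcast_to(data, (nx, ny, nz)).astype(float).copy()
    sigma = noise_model.noise_at(mAs, ir=ir) * noise_scale
    if sigma > 0:
        rng = np.random.default_rng(seed)
        data += sigma * rng.standard_normal(data.shape)
    return ImageVolume(
        data, spec.spacing,
        meta={"radius_mm": spec.radius_mm, "mAs": float(mAs), "ir": bool(ir),
              "mode": noise_model.mode, "sigma": float(sigma)},
    )


# ---------------------------------------------------------------------------
# breathing subject
# ---------------------------------------------------------------------------

@dataclass
class SubjectPhase:
    """One generated phase/breath-hold volume with its ground truth."""

    label: str
    image: ImageVolume          # HU, with noise applied
    mask: ImageVolume           # true lung mask on this phase's frame (uint8)
    true_map: ImageVolume       # analytic Jacobian det on the exhale frame
    fraction: float
    oop_fraction: float
    lung_volume_cc: float       # mask-derived


def synthesize_phase(
    spec: PhantomSpec,
    field: GroundTruthField,
    f: float,
    f_oop: float = 0.0,
    exhale: ImageVolume | None = None,
) -> tuple[ImageVolume, ImageVolume, ImageVolume]:
    """Noise-free phase image, lung mask and true expansion map.

    The phase image is the exhale phantom pushed forward through
    ``x -> x + u(x; f)``, with HU rescaled so per-voxel tissue volume is
    conserved: where the local Jacobian J > 1 the tissue fraction drops by
    1/J and the voxel becomes more air-like.  Voxel values on the phase grid
    are found through the inverse map (fixed-point iteration).
    """
    exhale = exhale if exhale is not None else _exhale_image(spec)
    hu = exhale.data.astype(float).copy()
    pts = _grid_point_array(spec)

    # true expansion map lives on the exhale frame
    det_full = np.ones(spec.grid_shape)
    bbox = field.support_bbox(spec)
    det_full[bbox] = field.jacobian_det(pts[bbox], f, f_oop)
    true_map = ImageVolume(det_full, spec.spacing,
                           meta={"fraction": f, "oop_fraction": f_oop})

    mask = spec.lung_membership(pts)
    if f != 0.0 or f_oop != 0.0:
        y = pts[bbox]
        # only invert where the forward field actually moves tissue
        u0 = field.displacement(y, f, f_oop)
        active = np.max(np.abs(u0), axis=-1) > 5e-3
        x = y.copy()
        x[active] = field.inverse_point(y[active], f, f_oop, u_at_pts=u0[active])
        J = field.jacobian_det(x[active], f, f_oop)
        t0 = 1.0 - spec.air_fraction(spec.exhale_hu(x[active]))  # tissue fraction
        t = t0 / J
        hu_box = hu[bbox]
        hu_box[active] = spec.hu_from_air_fraction(1.0 - t)
        hu[bbox] = hu_box
        mask[bbox] = spec.lung_membership(x)

    mask_img = ImageVolume(mask.astype(np.uint8), spec.spacing)
    mask_img.meta["lung_volume_cc"] = float(mask.sum()) * spec.voxel_volume_cc
    img = ImageVolume(hu, spec.spacing, meta={"fraction": f})
    return img, mask_img, true_map


def make_subject_images(
    spec: PhantomSpec,
    breathing: BreathingModel,
    field: GroundTruthField,
    acq: AcquisitionSpec,
    phases_or_bh: str | list[str] = "4DCT",
    seed: int = 0,
    noise_model: NoiseModel | None = None,
    scan_index: int = 0,
    tv_tolerance: float = 0.05,
) -> list[SubjectPhase]:
    """Generate one scan: a 4DCT phase series or the three breath-holds.

    ``phases_or_bh`` selects ``"4DCT"`` (all 10 phases), ``"BH"`` (MEBH,
    80%Insp, MIBH) or an explicit label list.  The scan's tidal volume is
    ``tidal_volume_full`` plus random effort jitter plus
    ``scan_index * drift_cc_per_scan`` (breath-hold volume drift); the
    displacement amplitude is recalibrated accordingly.  Noise with
    ``sigma = A * mAs**-B`` (times the IR factor when ``acq.ir_applied``)
    is drawn from ``seed``; calling twice with the same seed but different
    IR flags yields the *same* noise realisation scaled by the IR factor,
    mimicking reconstructing one raw acquisition twice.
    """
    if isinstance(phases_or_bh, str):
        if phases_or_bh == "4DCT":
            labels = list(PHASE_LABELS)
        elif phases_or_bh == "BH":
            labels = list(BH_LABELS)
        else:
            raise ValueError("phases_or_bh must be '4DCT', 'BH' or a label list")
    else:
        labels = list(phases_or_bh)

    noise_model = noise_model or (
        NOISE_MODEL_4DCT if acq.mode == "4DCT" else NOISE_MODEL_BHCT
    )
    rng = np.random.default_rng(seed)
    jitter = float(rng.normal(0.0, breathing.effort_sd_cc))
    tv_target = (
        breathing.tidal_volume_full + jitter
        + scan_index * breathing.drift_cc_per_scan
    )
    if tv_target <= 0:
        raise GenerationError(f"non-positive target tidal volume ({tv_target:.0f} cc)")
    fld = field.calibrated_for(spec, tv_target,
                               f_oop_at_full=breathing.oop_fraction("100IN"))

    exhale = _exhale_image(spec)
    sigma = noise_model.noise_at(acq.mAs, ir=acq.ir_applied) * acq.noise_scale
    exhale_volume = None
    out: list[SubjectPhase] = []
    for label in labels:
        f = breathing.fraction(label)
        f_oop = breathing.oop_fraction(label)
        img, mask_img, true_map = synthesize_phase(spec, fld, f, f_oop, exhale=exhale)
        vol = mask_img.meta["lung_volume_cc"]
        if f == 0.0:
            exhale_volume = vol
        # noise draw happens unconditionally so the same seed yields paired
        # realisations across IR on/off (sigma only scales the field)
        noise = rng.standard_normal(img.data.shape)
        if sigma > 0:
            img.data = img.data + sigma * noise
        img.meta.update({"mAs": acq.mAs, "ir": acq.ir_applied, "mode": acq.mode,
                         "sigma": float(sigma), "label": label,
                         "scan_index": scan_index})
        out.append(SubjectPhase(label, img, mask_img, true_map, f, f_oop, vol))

    # verify the requested tidal volume was realised
    full_labels = {"100IN", "MIBH"}
    for ph in out:
        if ph.label in full_labels:
            if exhale_volume is None:
                ex_pts = _grid_point_array(spec)
                exhale_volume = float(spec.lung_membership(ex_pts).sum()) * spec.voxel_volume_cc
            tv = ph.lung_volume_cc - exhale_volume
            if abs(tv - tv_target) > tv_tolerance * tv_target:
                raise GenerationError(
                    f"mask-derived tidal volume {tv:.0f} cc deviates more than "
                    f"{tv_tolerance:.0%} from the requested {tv_target:.0f} cc"
                )
    return out
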