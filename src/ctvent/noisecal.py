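"""Noise--mAs calibration for CT acquisitions.

CT image noise (the HU standard deviation in a uniform region) falls with
the tube current-time product roughly as ``noise = A * mAs**(-B)`` with
``B`` near 0.5.  Separate constants apply to helical breath-hold scans
(BHCT, pitch ~1, full 360-degree reconstruction) and respiratory-correlated
4DCT (low pitch, limited-angle reconstruction, hence noisier at equal mAs).

This module measures noise on uniformity-phantom images, fits the power
law in log-log space, solves for the noise-equivalent mAs between the two
acquisition modes, and scales dose (CTDI_vol is proportional to mAs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .image import ImageVolume

__all__ = [
    "NoiseModel",
    "NoiseMeasurement",
    "NOISE_MODEL_4DCT",
    "NOISE_MODEL_BHCT",
    "SCANNER_MIN_MAS",
    "measure_noise",
    "fit_power_law",
    "equivalent_mAs",
    "percent_noise_increase",
    "percent_increase",
]

#: Lowest tube current-time product the modelled scanner allows at a 0.5 s
#: rotation time.  Equivalent-mAs solutions are clamped here.
SCANNER_MIN_MAS = 10.0


@dataclass(frozen=True)
class NoiseModel:
    """Power-law noise model ``noise(mAs) = A * mAs**(-B)`` in HU.

    ``A`` has units HU * mAs**B; ``B`` is unitless and expected near 0.5.
    ``ir_factor`` is the multiplicative noise reduction applied when
    iterative reconstruction is switched on (1.0 = no reduction).
    """

    A: float
    B: float
    mode: str = "4DCT"  # "4DCT" or "BHCT"
    r_squared: float = 1.0
    ir_factor: float = 0.6

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError(f"A must be positive, got {self.A}")
        if not 0 < self.B < 1:
            raise ValueError(f"B must lie in (0, 1), got {self.B}")
        if self.mode not in ("4DCT", "BHCT"):
            raise ValueError(f"mode must be '4DCT' or 'BHCT', got {self.mode!r}")
        if not 0 < self.ir_factor <= 1:
            raise ValueError(f"ir_factor must lie in (0, 1], got {self.ir_factor}")

    def noise_at(self, mAs: float, ir: bool = False) -> float:
        """Predicted HU noise at a given mAs (with optional IR reduction)."""
        if mAs <= 0:
            raise ValueError(f"mAs must be positive, got {mAs}")
        sigma = self.A * mAs ** (-self.B)
        return sigma * self.ir_factor if ir else sigma

    def with_ir_factor(self, factor: float) -> "NoiseModel":
        return replace(self, ir_factor=factor)


#: Calibrated models for the modelled scanner (fit constants for the two
#: acquisition modes; the synthetic phantom generator reproduces these).
NOISE_MODEL_4DCT = NoiseModel(A=405.4, B=0.487, mode="4DCT")
NOISE_MODEL_BHCT = NoiseModel(A=325.5, B=0.497, mode="BHCT")


@dataclass(frozen=True)
class NoiseMeasurement:
    """One (mAs, HU-noise) point measured in a uniformity-phantom ROI."""

    mAs: float
    noise: float
    roi_fraction: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("measured noise must be non-negative")
        if self.n_voxels < 100:
            raise ValueError(
                f"ROI too small for a stable SD estimate ({self.n_voxels} voxels; "
                "need >= 100)"
            )


def measure_noise(
    image: ImageVolume,
    roi_fraction: float = 0.4,
    phantom_radius_mm: float | None = None,
    n_slices: int = 5,
    mAs: float = float("nan"),
) -> NoiseMeasurement:
    """HU standard deviation in a centred circular ROI of the uniform region.

    The ROI is a circle of diameter ``roi_fraction`` times the phantom
    diameter, centred on the grid, pooled over the central ``n_slices``
    axial (z) slices.  Sample SD with the n-1 denominator.

    Parameters
    ----------
    phantom_radius_mm:
        Radius of the uniform region.  Taken from ``image.meta['radius_mm']``
        when omitted (the synthetic generator records it).
    """
    if not 0 < roi_fraction < 1:
        raise ValueError(f"roi_fraction must lie in (0, 1), got {roi_fraction}")
    if phantom_radius_mm is None:
        phantom_radius_mm = image.meta.get("radius_mm")
        if phantom_radius_mm is None:
            raise ValueError("phantom radius not given and not present in image.meta")

    nx, ny, nz = image.shape
    sx, sy, sz = image.spacing
    roi_radius = roi_fraction * phantom_radius_mm  # diameter fraction of diameter
    # centred circle in the axial (x, y) plane
    cx = (nx - 1) / 2.0 * sx
    cy = (ny - 1) / 2.0 * sy
    if roi_radius > cx or roi_radius > cy:
        raise ValueError(
            f"ROI radius {roi_radius:.1f} mm exceeds image half-extent "
            f"({cx:.1f} x {cy:.1f} mm)"
        )
    x = (np.arange(nx) * sx - cx)[:, None]
    y = (np.arange(ny) * sy - cy)[None, :]
    in_roi = x**2 + y**2 <= roi_radius**2

    z0 = max(0, nz // 2 - n_slices // 2)
    slices = image.data[:, :, z0 : z0 + n_slices]
    values = slices[in_roi, :].ravel()
    sd = float(np.std(values, ddof=1))
    if "mAs" in image.meta and math.isnan(mAs):
        mAs = float(image.meta["mAs"])
    return NoiseMeasurement(
        mAs=mAs, noise=sd, roi_fraction=roi_fraction, n_voxels=values.size
    )


def fit_power_law(
    measurements: list[NoiseMeasurement], mode: str = "4DCT"
) -> NoiseModel:
    """Fit ``noise = A * mAs**(-B)`` by ordinary least squares in log-log space.

    ``A = exp(intercept)``, ``B = -slope``; ``r_squared`` is reported in log
    space, matching spreadsheet-style power-law trendline fitting.
    """
    mas = np.array([m.mAs for m in measurements], dtype=float)
    noise = np.array([m.noise for m in measurements], dtype=float)
    if np.unique(mas).size < 3:
        raise ValueError(
            f"need >= 3 distinct mAs values to fit a power law, got "
            f"{np.unique(mas).size}"
        )
    if np.any(noise <= 0):
        raise ValueError("all noise measurements must be positive")
    lx, ly = np.log(mas), np.log(noise)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return NoiseModel(A=float(np.exp(intercept)), B=float(-slope), mode=mode,
                      r_squared=r2)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def equivalent_mAs(
    model_bh: NoiseModel,
    model_4d: NoiseModel,
    mAs_4d: float,
    min_mAs: float = SCANNER_MIN_MAS,
    round_to_int: bool = True,
) -> float:
    """BHCT mAs producing the same image noise as a 4DCT at ``mAs_4d``.

    Solves ``A_BH * x**(-B_BH) = A_4D * mAs_4d**(-B_4D)`` for ``x``:

        x = (A_BH / A_4D * mAs_4d**B_4D) ** (1 / B_BH)

    Rounded half-up to an integer mAs (scanner console granularity) and
    clamped at the scanner minimum.
    """
    if mAs_4d <= 0:
        raise ValueError(f"mAs_4d must be positive, got {mAs_4d}")
    if min_mAs <= 0:
        raise ValueError(f"min_mAs must be positive, got {min_mAs}")
    raw = (model_bh.A / model_4d.A * mAs_4d**model_4d.B) ** (1.0 / model_bh.B)
    out = float(_round_half_up(raw)) if round_to_int else raw
    return max(out, float(min_mAs))


def percent_noise_increase(
    model: NoiseModel, mAs_low_dose: float, mAs_high_dose: float
) -> float:
    """Percent noise increase of a low-dose scan over a high-dose scan.

    Computed from unrounded model evaluations, then rounded to the nearest
    percent for reporting.
    """
    if mAs_low_dose <= 0 or mAs_high_dose <= 0:
        raise ValueError("mAs values must be positive")
    if mAs_low_dose > mAs_high_dose:
        raise ValueError("mAs_low_dose must not exceed mAs_high_dose")
    ratio = model.noise_at(mAs_low_dose) / model.noise_at(mAs_high_dose)
    return float(_round_half_up(100.0 * (ratio - 1.0)))


def percent_increase(noise_high: float, noise_low: float) -> float:
    """Percent increase of one measured noise value over another, rounded.

    For quoting increases from measured (printed) noise values rather than
    model evaluations.
    """
    if noise_high <= 0 or noise_low <= 0:
        raise ValueError("noise values must be positive")
    return float(_round_half_up(100.0 * (noise_high / noise_low - 1.0)))
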