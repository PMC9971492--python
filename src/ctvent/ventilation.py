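"""CT-ventilation biomarkers from registered lung volumes.

The biomarker is the Jacobian determinant of the exhale-to-inhale
transform: values above 1 mark local tissue expansion, the surrogate for
ventilation.  Two map types are supported:

* two-image breath-hold maps (inhale registered to the maximum-expiration
  breath-hold), and
* LER-N maps for 4DCT: every inspiratory phase up to the effort-matched
  (ETV) phase is registered to full exhale (0EX) and the per-voxel maximum
  expansion over phases is taken, which captures out-of-phase lung regions.

Effort correction (ETV): when two scans are compared, the inhale phases
with the closest-matching tidal volumes are selected, so volume-dependent
Jacobian values are compared at equivalent effort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .image import ImageVolume
from .registration import RegistrationConfig, RegistrationError, register

__all__ = [
    "VolumeSeries",
    "VentilationMap",
    "segment_lungs",
    "tidal_volumes",
    "select_etv",
    "bh_ventilation",
    "lern_ventilation",
]

#: inhale-side labels eligible for ETV selection (4DCT inspiratory limb
#: plus the two inspiratory breath-holds)
_INHALE_LABELS = ("20IN", "40IN", "60IN", "80IN", "100IN", "80%Insp", "MIBH")
_EXHALE_LABELS = ("0EX", "MEBH")


def segment_lungs(
    image: ImageVolume,
    threshold_hu: float = -400.0,
    min_component_cc: float = 50.0,
    closing_vox: int = 2,
    smooth_vox: float = 0.5,
) -> ImageVolume:
    """Threshold-based lung mask.

    The image is Gaussian-smoothed (``smooth_vox`` voxels) so the threshold
    is stable under HU noise; voxels below ``threshold_hu`` lying inside
    the body contour (the hole-filled above-threshold region) are candidate
    lung; the largest two connected components above ``min_component_cc``
    are kept and closed morphologically.  Returns a uint8 mask with the
    derived lung volume in ``meta['lung_volume_cc']``.
    """
    data = ndimage.gaussian_filter(np.asarray(image.data, dtype=float),
                                   smooth_vox) if smooth_vox else image.data
    body = ndimage.binary_fill_holes(
        ndimage.binary_closing(data > threshold_hu, iterations=1)
    )
    cand = (data < threshold_hu) & body
    labels, n = ndimage.label(cand)
    if n == 0:
        raise ValueError("no lung voxels below threshold inside the body")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    min_vox = min_component_cc / image.voxel_volume_cc
    order = np.argsort(sizes)[::-1]
    keep = [i + 1 for i in order[:2] if sizes[i] >= min_vox]
    if not keep:
        raise ValueError(
            f"no lung component larger than {min_component_cc} cc found"
        )
    mask = np.isin(labels, keep)
    if closing_vox:
        mask = ndimage.binary_closing(mask, iterations=closing_vox)
        mask = ndimage.binary_fill_holes(mask)
    out = ImageVolume(mask.astype(np.uint8), image.spacing, image.origin)
    out.meta["lung_volume_cc"] = float(mask.sum()) * image.voxel_volume_cc
    return out


@dataclass
class VolumeSeries:
    """Per-phase lung volumes (cc) and tidal volumes relative to end exhale."""

    volumes_cc: dict[str, float]
    end_exhale_label: str = ""

    def __post_init__(self) -> None:
        if not self.end_exhale_label:
            for lab in _EXHALE_LABELS:
                if lab in self.volumes_cc:
                    self.end_exhale_label = lab
                    break
            else:
                raise ValueError(
                    f"series must contain an end-exhale phase ({_EXHALE_LABELS})"
                )
        if any(v <= 0 for v in self.volumes_cc.values()):
            raise ValueError("lung volumes must be positive")

    def tidal_volume(self, label: str) -> float:
        return self.volumes_cc[label] - self.volumes_cc[self.end_exhale_label]

    @property
    def tidal_volumes_cc(self) -> dict[str, float]:
        return {lab: self.tidal_volume(lab) for lab in self.volumes_cc}

    @property
    def inhale_labels(self) -> list[str]:
        return [lab for lab in self.volumes_cc if lab in _INHALE_LABELS]


def tidal_volumes(
    masks: dict[str, ImageVolume], end_exhale_label: str = ""
) -> VolumeSeries:
    """Lung and tidal volumes from per-phase masks (volume = voxels x cc)."""
    vols = {
        lab: float(np.count_nonzero(m.data)) * m.voxel_volume_cc
        for lab, m in masks.items()
    }
    return VolumeSeries(vols, end_exhale_label)


def select_etv(
    series_a: VolumeSeries, series_b: VolumeSeries
) -> tuple[str, str, float]:
    """Equivalent-tidal-volume phase pair between two scans.

    Returns the inhale-phase pair ``(phase_a, phase_b)`` minimising the
    absolute tidal-volume difference, with ties broken toward the larger
    tidal volume, plus the residual difference in cc.
    """
    cand_a, cand_b = series_a.inhale_labels, series_b.inhale_labels
    if not cand_a or not cand_b:
        raise ValueError("both series need at least one inhale phase")
    best = None
    for pa in cand_a:
        for pb in cand_b:
            tva, tvb = series_a.tidal_volume(pa), series_b.tidal_volume(pb)
            key = (abs(tva - tvb), -(tva + tvb))
            if best is None or key < best[0]:
                best = (key, pa, pb)
    _, pa, pb = best
    return pa, pb, abs(series_a.tidal_volume(pa) - series_b.tidal_volume(pb))


@dataclass
class VentilationMap:
    """Per-voxel Jacobian ventilation on a reference (end-exhale) frame."""

    jacobian: ImageVolume
    mask: ImageVolume
    provenance: dict = dc_field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.jacobian.data

    def masked_values(self) -> np.ndarray:
        return self.jacobian.data[self.mask.data > 0]

    def save(self, path_prefix: str) -> None:
        """Floating-point NIfTI plus a JSON provenance sidecar."""
        self.jacobian.to_nifti(path_prefix + ".nii.gz", dtype=np.float32)
        self.mask.to_nifti(path_prefix + "_mask.nii.gz", dtype=np.uint8)
        with open(path_prefix + ".json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)


def bh_ventilation(
    exhale: ImageVolume,
    exhale_mask: ImageVolume,
    inhale: ImageVolume,
    inhale_mask: ImageVolume,
    config: RegistrationConfig | None = None,
    provenance: dict | None = None,
) -> VentilationMap:
    """Two-image ventilation: register the (ETV-selected) inhale breath-hold
    to the exhale breath-hold and evaluate the Jacobian on the exhale frame."""
    tf = register(exhale, inhale, exhale_mask, inhale_mask, config)
    det = ImageVolume(tf.jacobian_on(*tf.domain), exhale.spacing, exhale.origin)
    prov = {"method": "BH", **(provenance or {})}
    return VentilationMap(det, exhale_mask, prov)


def lern_ventilation(
    phases: list[tuple[str, ImageVolume, ImageVolume]],
    exhale: ImageVolume,
    exhale_mask: ImageVolume,
    config: RegistrationConfig | None = None,
    provenance: dict | None = None,
) -> VentilationMap:
    """LER-N ventilation from a 4DCT inspiratory series.

    Each phase ``(label, image, mask)`` is registered to the full-exhale
    frame; the output voxel value is the maximum Jacobian determinant over
    phases, capturing regions whose expansion peaks out of phase.
    """
    if len(phases) < 2:
        raise ValueError("LER-N needs at least two non-exhale phases")
    best: np.ndarray | None = None
    used = []
    for label, img, msk in phases:
        try:
            tf = register(exhale, img, exhale_mask, msk, config)
        except RegistrationError as exc:
            raise RegistrationError(
                f"registration of phase {label!r} to exhale failed: {exc}"
            ) from exc
        det = tf.jacobian_on(*tf.domain)
        best = det if best is None else np.maximum(best, det)
        used.append(label)
    out = ImageVolume(best, exhale.spacing, exhale.origin)
    prov = {"method": "LER-N", "phases": used, **(provenance or {})}
    return VentilationMap(out, exhale_mask, prov)
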