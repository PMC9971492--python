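"""Agreement metrics between two ventilation maps.

A reduced-dose (higher-noise) map ``J2`` is compared against the full-dose
reference map ``J1`` after resampling into the reference exhale frame:

* local 3D gamma pass rate (default 2 mm distance-to-agreement, 6% local
  Jacobian-intensity criterion): a voxel passes when

      gamma(x1) = min over x2 of sqrt( (|x2-x1| / C_DTA)^2
                  + ((J2(x2) - J1(x1)) / (C_JI/100 * J1(x1)))^2 )  <= 1

* voxel-wise Spearman rank correlation, labelled "strong" when rho >= 0.8;
* the Jacobian-ratio coefficient of variation CoV_JR = sd(J2/J1)/mean(J2/J1).

Scans whose tidal volumes differ by more than 100 cc are excluded from the
gamma and CoV analyses (these metrics compare values directly and are
confounded by effort differences); the rank-based Spearman is always kept.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import spearmanr

from .image import ImageVolume
from .registration import RegistrationConfig, register, warp
from .ventilation import VentilationMap

__all__ = [
    "GammaConfig",
    "ComparisonReport",
    "ProvenanceError",
    "to_reference_frame",
    "gamma_map",
    "spearman_voxelwise",
    "cov_jr",
    "compare_maps",
    "apply_exclusion",
]

#: tidal-volume difference (cc) beyond which gamma and CoV_JR are excluded
TV_EXCLUSION_CC = 100.0


class ProvenanceError(ValueError):
    """Comparison attempted between maps that must not be compared."""


@dataclass(frozen=True)
class GammaConfig:
    """Local 3D gamma criteria.

    ``dta_mm``: distance-to-agreement; ``ji_percent``: Jacobian-intensity
    criterion as a percentage of the local reference value;
    ``search_radius_mm``: how far candidate points x2 are sought (default
    2 x DTA); ``search_step_voxel``: sub-voxel sampling step of the search.
    """

    dta_mm: float = 2.0
    ji_percent: float = 6.0
    search_radius_mm: float | None = None
    search_step_voxel: float = 0.5
    local: bool = True

    def __post_init__(self) -> None:
        if self.dta_mm <= 0:
            raise ValueError("dta_mm must be positive")
        if not 0 < self.ji_percent <= 100:
            raise ValueError("ji_percent must lie in (0, 100]")

    @property
    def radius(self) -> float:
        return (2.0 * self.dta_mm if self.search_radius_mm is None
                else self.search_radius_mm)


@dataclass
class ComparisonReport:
    """Machine-readable agreement summary for one map pair."""

    gamma_pass_rate: float | None    # percent
    spearman_rho: float
    spearman_label: str              # "strong" iff rho >= 0.8
    jr_mean: float | None
    jr_sd: float | None
    cov_jr: float | None
    tv_difference_cc: float
    excluded_from_gamma_cov: bool
    n_voxels: int
    n_excluded_nonpositive: int = 0
    provenance: dict | None = None

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "gamma_pass_rate", "spearman_rho", "spearman_label", "jr_mean",
            "jr_sd", "cov_jr", "tv_difference_cc", "excluded_from_gamma_cov",
            "n_voxels", "n_excluded_nonpositive")}
        if self.provenance:
            d.update({f"prov_{k}": v for k, v in self.provenance.items()})
        return d


def to_reference_frame(
    reduced: VentilationMap,
    reduced_exhale: ImageVolume,
    reference: VentilationMap,
    reference_exhale: ImageVolume,
    config: RegistrationConfig | None = None,
) -> VentilationMap:
    """Resample a reduced-dose map into the reference (full-dose) frame.

    The two exhale images are registered (reference frame fixed) and the
    reduced map is pulled back through that transform; the comparison mask
    is the intersection of the two lung masks.  Maps from different
    acquisition modes or IR states refuse to compare.
    """
    _check_provenance(reduced, reference)
    if reference.jacobian.same_grid(reduced.jacobian) and np.allclose(
        reference_exhale.data, reduced_exhale.data
    ):
        aligned_j, aligned_m = reduced.jacobian, reduced.mask
    else:
        tf = register(reference_exhale, reduced_exhale,
                      reference.mask, reduced.mask, config)
        aligned_j = warp(reduced.jacobian, tf, "linear", fill=1.0)
        aligned_m = warp(reduced.mask, tf, "nearest", fill=0)
    inter = ImageVolume(
        ((aligned_m.data > 0) & (reference.mask.data > 0)).astype(np.uint8),
        reference.mask.spacing, reference.mask.origin,
    )
    prov = dict(reduced.provenance)
    prov["aligned_to_reference"] = True
    return VentilationMap(aligned_j, inter, prov)


def _check_provenance(reduced: VentilationMap, reference: VentilationMap) -> None:
    for key in ("mode", "ir", "subject", "scan_date"):
        a = reduced.provenance.get(key)
        b = reference.provenance.get(key)
        if a is not None and b is not None and a != b:
            raise ProvenanceError(
                f"maps differ in {key!r} ({a!r} vs {b!r}); comparisons are "
                "restricted to the same acquisition type, IR state, subject "
                "and scan date"
            )


def _search_offsets(spacing, cfg: GammaConfig) -> np.ndarray:
    """Candidate physical offsets within the search radius, ordered by
    increasing distance (so the distance term grows monotonically)."""
    steps = [max(cfg.search_step_voxel * s, 1e-6) for s in spacing]
    ax = [np.arange(-np.floor(cfg.radius / st), np.floor(cfg.radius / st) + 1) * st
          for st in steps]
    off = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    r = np.linalg.norm(off, axis=1)
    off = off[r <= cfg.radius + 1e-9]
    return off[np.argsort(np.linalg.norm(off, axis=1))]


def gamma_map(
    J1: VentilationMap,
    J2: VentilationMap,
    cfg: GammaConfig | None = None,
) -> tuple[ImageVolume, float]:
    """Per-voxel local gamma index and the pass rate (percent).

    ``J1`` is the full-dose reference (it supplies the local normalisation)
    and ``J2`` the reduced-dose map, already on the same grid.  Candidate
    points sample ``J2`` on a half-voxel lattice within the search radius
    with trilinear interpolation; the search exits early once every voxel
    has passed.  Reference voxels with ``J1 <= 0`` are excluded (the local
    criterion is undefined) and counted in ``meta['n_excluded']``.
    """
    cfg = cfg or GammaConfig()
    if not J1.jacobian.same_grid(J2.jacobian):
        raise ValueError("maps must share a grid; use to_reference_frame first")
    spacing = np.asarray(J1.jacobian.spacing)
    mask = (J1.mask.data > 0) & (J2.mask.data > 0)
    valid = mask & (J1.values > 0)
    n_excl = int(mask.sum() - valid.sum())

    idx = np.argwhere(valid)
    x1_val = J1.values[valid]
    tol = cfg.ji_percent / 100.0 * x1_val
    j2 = np.asarray(J2.values, dtype=float)

    offsets = _search_offsets(spacing, cfg)
    best = np.full(len(idx), np.inf)
    for off in offsets:
        dist2 = float(np.sum((off / cfg.dta_mm) ** 2))
        if dist2 >= float(np.max(best)):
            break  # offsets are distance-ordered: nothing can improve
        still = np.flatnonzero(best > dist2)
        coords = (idx[still] + off / spacing).T
        j2_s = map_coordinates(j2, coords, order=1, mode="nearest")
        g2 = dist2 + ((j2_s - x1_val[still]) / tol[still]) ** 2
        better = g2 < best[still]
        best[still[better]] = g2[better]

    gamma = np.sqrt(best)
    grid = np.full(J1.values.shape, np.nan)
    grid[valid] = gamma
    # epsilon keeps the exact boundary case (gamma == 1) a pass
    pass_rate = (100.0 * float(np.mean(gamma <= 1.0 + 1e-9))
                 if len(gamma) else float("nan"))
    out = ImageVolume(grid, J1.jacobian.spacing, J1.jacobian.origin,
                      meta={"n_excluded": n_excl, "dta_mm": cfg.dta_mm,
                            "ji_percent": cfg.ji_percent})
    return out, pass_rate


def spearman_voxelwise(
    J1: VentilationMap, J2: VentilationMap, mask: np.ndarray | None = None
) -> tuple[float, str]:
    """Voxel-level Spearman rank correlation with its strength label."""
    m = _common_mask(J1, J2, mask)
    a, b = J1.values[m], J2.values[m]
    if a.size < 10:
        raise ValueError(f"need at least 10 masked voxels, got {a.size}")
    rho = float(spearmanr(a, b).statistic)
    return rho, ("strong" if rho >= 0.8 else "not strong")


def cov_jr(
    J1: VentilationMap, J2: VentilationMap, mask: np.ndarray | None = None,
    sd_from_fwhm: bool = False,
) -> tuple[float, float, float]:
    """Mean, SD and coefficient of variation of the Jacobian ratio J2/J1.

    ``sd_from_fwhm`` estimates the SD from the full width at half maximum
    of the JR histogram instead of the sample SD (visualisation-style
    estimate); the sample SD is the default.
    """
    m = _common_mask(J1, J2, mask)
    jr = J2.values[m] / J1.values[m]
    mu = float(np.mean(jr))
    if sd_from_fwhm:
        hist, edges = np.histogram(jr, bins=100)
        half = hist.max() / 2.0
        above = np.flatnonzero(hist >= half)
        sd = float((edges[above[-1] + 1] - edges[above[0]]) / 2.3548)
    else:
        sd = float(np.std(jr, ddof=1))
    return mu, sd, sd / mu


def _common_mask(J1, J2, mask):
    m = (J1.mask.data > 0) & (J2.mask.data > 0) if mask is None else mask.copy()
    # voxels with non-positive reference (folding) are excluded everywhere
    return m & (J1.values > 0)


def compare_maps(
    reference: VentilationMap,
    reduced_aligned: VentilationMap,
    tv_difference_cc: float,
    gamma_cfg: GammaConfig | None = None,
    provenance: dict | None = None,
) -> ComparisonReport:
    """Full metric battery for one aligned map pair, with exclusions applied."""
    mask = (reference.mask.data > 0) & (reduced_aligned.mask.data > 0)
    valid = mask & (reference.values > 0)
    _, pass_rate = gamma_map(reference, reduced_aligned, gamma_cfg)
    rho, label = spearman_voxelwise(reference, reduced_aligned)
    mu, sd, cov = cov_jr(reference, reduced_aligned)
    report = ComparisonReport(
        gamma_pass_rate=pass_rate,
        spearman_rho=rho,
        spearman_label=label,
        jr_mean=mu,
        jr_sd=sd,
        cov_jr=cov,
        tv_difference_cc=float(tv_difference_cc),
        excluded_from_gamma_cov=False,
        n_voxels=int(valid.sum()),
        n_excluded_nonpositive=int(mask.sum() - valid.sum()),
        provenance=provenance,
    )
    return apply_exclusion(report)


def apply_exclusion(report: ComparisonReport) -> ComparisonReport:
    """Null gamma and CoV_JR when the tidal-volume difference exceeds
    100 cc (strictly); the Spearman correlation is always retained."""
    if report.tv_difference_cc > TV_EXCLUSION_CC:
        return replace(report, gamma_pass_rate=None, jr_mean=None, jr_sd=None,
                       cov_jr=None, excluded_from_gamma_cov=True)
    return replace(report, excluded_from_gamma_cov=False)
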