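"""B-spline deformable registration with a tissue-volume similarity.

Estimates a smooth free-form transform ``T(x) = x + u(x)`` between an
exhale (fixed) and inhale (moving) CT volume, where ``u`` is a cubic
B-spline field on a regular control grid.  The similarity is the sum of
squared *tissue volume* differences (SSTVD): with air fraction
``a = (HU - hu_tissue) / (hu_air - hu_tissue)`` and tissue fraction
``v = 1 - a`` (clamped to [0, 1]), the cost per fixed-mask voxel is

    [ v_f(x) - J_T(x) * v_m(T(x)) ]^2

so that lung density changes with inflation (air added, tissue conserved)
are modelled rather than penalised.  ``J_T`` is the transform's Jacobian
determinant, computed analytically from the B-spline derivative kernels.
Optimisation is multi-resolution L-BFGS with an analytic gradient,
bending-energy smoothness regularisation on the coefficients, and a
folding penalty that keeps the determinant positive.

Physical (mm) coordinates throughout; voxel index <-> physical conversion
uses spacing and origin only (no direction cosines).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import binary_dilation, map_coordinates
from scipy.optimize import minimize

from .image import ImageVolume

__all__ = [
    "BSplineTransform",
    "RegistrationConfig",
    "RegistrationError",
    "register",
    "jacobian_determinant",
    "warp",
    "tissue_fraction",
]


class RegistrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# cubic B-spline basis
# ---------------------------------------------------------------------------

def _bspline_weights(s: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline weights for local fractions s in [0,1); (4, n)."""
    s2, s3 = s * s, s * s * s
    return np.stack([
        (1 - s) ** 3 / 6.0,
        (3 * s3 - 6 * s2 + 4) / 6.0,
        (-3 * s3 + 3 * s2 + 3 * s + 1) / 6.0,
        s3 / 6.0,
    ])


def _bspline_dweights(s: np.ndarray) -> np.ndarray:
    """Derivatives of the four weights with respect to s; (4, n)."""
    s2 = s * s
    return np.stack([
        -((1 - s) ** 2) / 2.0,
        (3 * s2 - 4 * s) / 2.0,
        (-3 * s2 + 2 * s + 1) / 2.0,
        s2 / 2.0,
    ])


def _basis_matrix(coords: np.ndarray, origin: float, h: float, n_ctrl: int,
                  deriv: bool = False) -> np.ndarray:
    """Dense (len(coords), n_ctrl) cubic B-spline collocation matrix.

    Row i holds the four basis values (or d/dx values) of the control
    points supporting physical coordinate ``coords[i]``.
    """
    t = (np.asarray(coords, dtype=float) - origin) / h
    k0 = np.floor(t).astype(int)
    s = t - k0
    if np.any(k0 - 1 < 0) or np.any(k0 + 2 > n_ctrl - 1):
        raise RegistrationError(
            "point outside the B-spline control grid; the control grid must "
            "cover the image domain with a margin row"
        )
    W = (_bspline_dweights(s) / h) if deriv else _bspline_weights(s)
    B = np.zeros((len(t), n_ctrl))
    rows = np.arange(len(t))
    for j in range(4):
        B[rows, k0 - 1 + j] = W[j]
    return B


def _apply_separable(Bs: list[np.ndarray], coef: np.ndarray) -> np.ndarray:
    """Evaluate a separable tensor-product operator: out[i,j,k,d] =
    sum_abc Bx[i,a] By[j,b] Bz[k,c] coef[a,b,c,d]."""
    t = np.tensordot(Bs[0], coef, axes=(1, 0))      # (Nx, ncy, ncz, d)
    t = np.tensordot(Bs[1], t, axes=(1, 1))         # (Ny, Nx, ncz, d)
    t = np.tensordot(Bs[2], t, axes=(1, 2))         # (Nz, Ny, Nx, d)
    return np.ascontiguousarray(t.transpose(2, 1, 0, 3))


def _scatter_separable(Bs: list[np.ndarray], field: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`_apply_separable` (voxel field -> control grid)."""
    t = np.tensordot(Bs[0].T, field, axes=(1, 0))   # (ncx, Ny, Nz, d)
    t = np.tensordot(Bs[1].T, t, axes=(1, 1))       # (ncy, ncx, Nz, d)
    t = np.tensordot(Bs[2].T, t, axes=(1, 2))       # (ncz, ncy, ncx, d)
    return np.ascontiguousarray(t.transpose(2, 1, 0, 3))


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------

@dataclass
class BSplineTransform:
    """Free-form deformation on a regular cubic B-spline control grid.

    ``coef[a, b, c, :]`` is the mm displacement coefficient of control
    point ``(a, b, c)``; control point positions are
    ``ctrl_origin + index * ctrl_spacing``.  ``domain`` is the reference
    (fixed-image) geometry the transform was estimated on:
    ``(shape, spacing, origin)``.
    """

    ctrl_spacing: tuple[float, float, float]
    ctrl_origin: tuple[float, float, float]
    coef: np.ndarray
    domain: tuple[tuple[int, int, int], tuple[float, float, float], tuple[float, float, float]]

    _basis_cache: dict = dc_field(default_factory=dict, repr=False, compare=False)

    # -- constructors -------------------------------------------------------
    @classmethod
    def identity_for(
        cls,
        shape: tuple[int, int, int],
        spacing: tuple[float, float, float],
        origin: tuple[float, float, float],
        ctrl_spacing_mm: float,
    ) -> "BSplineTransform":
        """Zero-displacement transform whose control grid covers the given
        image geometry with margin rows on every side."""
        h = float(ctrl_spacing_mm)
        n_ctrl, ctrl_origin = [], []
        for d in range(3):
            extent = (shape[d] - 1) * spacing[d]
            n = int(np.ceil(extent / h)) + 5
            n_ctrl.append(n)
            ctrl_origin.append(origin[d] - 2.0 * h)
        coef = np.zeros((*n_ctrl, 3))
        return cls((h, h, h), tuple(ctrl_origin), coef,
                   (tuple(shape), tuple(spacing), tuple(origin)))

    @classmethod
    def fit_field(
        cls,
        field: np.ndarray,
        shape, spacing, origin,
        ctrl_spacing_mm: float,
        ridge: float = 1e-8,
    ) -> "BSplineTransform":
        """Least-squares B-spline approximation of a displacement field
        sampled on a grid (used to carry a coarse-level solution to the
        next pyramid level)."""
        tf = cls.identity_for(shape, spacing, origin, ctrl_spacing_mm)
        Ps = []
        for d in range(3):
            coords = origin[d] + np.arange(shape[d]) * spacing[d]
            B = _basis_matrix(coords, tf.ctrl_origin[d], tf.ctrl_spacing[d],
                              tf.coef.shape[d])
            BtB = B.T @ B
            BtB[np.diag_indices_from(BtB)] += ridge * np.trace(BtB) / len(BtB)
            Ps.append(np.linalg.solve(BtB, B.T))
        tf.coef = _apply_separable(Ps, np.asarray(field, dtype=float))
        return tf

    # -- basis bookkeeping --------------------------------------------------
    def _axes_for(self, shape, spacing, origin):
        return tuple(
            (origin[d], spacing[d], shape[d]) for d in range(3)
        )

    def _bases(self, shape, spacing, origin, deriv_axis: int | None = None):
        key = (self._axes_for(shape, spacing, origin), deriv_axis)
        if key not in self._basis_cache:
            Bs = []
            for d in range(3):
                coords = origin[d] + np.arange(shape[d]) * spacing[d]
                Bs.append(_basis_matrix(
                    coords, self.ctrl_origin[d], self.ctrl_spacing[d],
                    self.coef.shape[d], deriv=(d == deriv_axis),
                ))
            self._basis_cache[key] = Bs
        return self._basis_cache[key]

    # -- evaluation ---------------------------------------------------------
    def displacement_on(self, shape, spacing, origin) -> np.ndarray:
        """Displacement field (mm) sampled on an arbitrary regular grid."""
        return _apply_separable(self._bases(shape, spacing, origin), self.coef)

    def displacement(self) -> np.ndarray:
        return self.displacement_on(*self.domain)

    def gradient_on(self, shape, spacing, origin) -> np.ndarray:
        """Spatial gradient du_d/dx_j on a grid, shape (*grid, 3, 3)."""
        G = np.empty(tuple(shape) + (3, 3))
        for j in range(3):
            G[..., j] = _apply_separable(
                self._bases(shape, spacing, origin, deriv_axis=j), self.coef
            )
        return G

    def jacobian_on(self, shape, spacing, origin) -> np.ndarray:
        """Analytic Jacobian determinant det(I + grad u) on a grid."""
        G = self.gradient_on(shape, spacing, origin)
        G[..., 0, 0] += 1.0
        G[..., 1, 1] += 1.0
        G[..., 2, 2] += 1.0
        return _det3(G)

    def displacement_at_points(self, pts: np.ndarray) -> np.ndarray:
        """Displacement at arbitrary physical points (n, 3)."""
        pts = np.asarray(pts, dtype=float)
        Bs = [
            _basis_matrix(pts[:, d], self.ctrl_origin[d], self.ctrl_spacing[d],
                          self.coef.shape[d])
            for d in range(3)
        ]
        # per-point contraction: u[n,d] = sum_abc Bx[n,a] By[n,b] Bz[n,c] c[abcd]
        t = np.einsum("na,abcd->nbcd", Bs[0], self.coef)
        t = np.einsum("nb,nbcd->ncd", Bs[1], t)
        return np.einsum("nc,ncd->nd", Bs[2], t)

    # -- serialisation ------------------------------------------------------
    def save(self, path_prefix: str) -> None:
        """Write <prefix>.json (geometry) and <prefix>_coef.nii.gz (mm)."""
        import nibabel as nib

        meta = {
            "ctrl_spacing": list(self.ctrl_spacing),
            "ctrl_origin": list(self.ctrl_origin),
            "coef_shape": list(self.coef.shape),
            "domain": {
                "shape": list(self.domain[0]),
                "spacing": list(self.domain[1]),
                "origin": list(self.domain[2]),
            },
        }
        with open(path_prefix + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)
        aff = np.diag(list(self.ctrl_spacing) + [1.0])
        aff[:3, 3] = self.ctrl_origin
        nib.save(nib.Nifti1Image(self.coef.astype(np.float32), aff),
                 path_prefix + "_coef.nii.gz")

    @classmethod
    def load(cls, path_prefix: str) -> "BSplineTransform":
        import nibabel as nib

        with open(path_prefix + ".json") as fh:
            meta = json.load(fh)
        coef = np.asarray(nib.load(path_prefix + "_coef.nii.gz").dataobj, dtype=float)
        dom = meta["domain"]
        return cls(tuple(meta["ctrl_spacing"]), tuple(meta["ctrl_origin"]), coef,
                   (tuple(dom["shape"]), tuple(dom["spacing"]), tuple(dom["origin"])))


def _det3(M: np.ndarray) -> np.ndarray:
    a, b, c = M[..., 0, 0], M[..., 0, 1], M[..., 0, 2]
    d, e, f = M[..., 1, 0], M[..., 1, 1], M[..., 1, 2]
    g, h, i = M[..., 2, 0], M[..., 2, 1], M[..., 2, 2]
    return a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)


def _cofactor3(M: np.ndarray) -> np.ndarray:
    """Cofactor matrix C with C[..., d, j] = d det(M) / d M[..., d, j]."""
    a, b, c = M[..., 0, 0], M[..., 0, 1], M[..., 0, 2]
    d, e, f = M[..., 1, 0], M[..., 1, 1], M[..., 1, 2]
    g, h, i = M[..., 2, 0], M[..., 2, 1], M[..., 2, 2]
    C = np.empty_like(M)
    C[..., 0, 0] = e * i - f * h
    C[..., 0, 1] = f * g - d * i
    C[..., 0, 2] = d * h - e * g
    C[..., 1, 0] = c * h - b * i
    C[..., 1, 1] = a * i - c * g
    C[..., 1, 2] = b * g - a * h
    C[..., 2, 0] = b * f - c * e
    C[..., 2, 1] = c * d - a * f
    C[..., 2, 2] = a * e - b * d
    return C


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistrationConfig:
    """Multi-resolution settings.

    Levels run coarse to fine: image shrink factors, L-BFGS iteration
    budgets and control-point spacings (mm) are per level.  ``bend_weight``
    scales the bending-energy (squared second differences of the
    coefficients) regulariser; ``fold_weight``/``fold_threshold`` penalise
    Jacobian determinants approaching zero.  ``hu_air``/``hu_tissue``
    convert HU to tissue fraction for the SSTVD similarity;
    ``mask_dilation_vox`` grows the fixed lung mask so the cost sees the
    lung boundary.
    """

    shrink_factors: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (150, 100, 50)
    control_spacing: tuple[float, ...] = (48.0, 24.0, 12.0)
    bend_weight: float = 30.0
    fold_weight: float = 10.0
    fold_threshold: float = 0.05
    #: Gaussian smoothing (in level-voxel units) of the tissue-fraction
    #: images at every pyramid level; suppresses voxel noise before the
    #: similarity sees it
    smooth_sigma_vox: float = 1.0
    tol: float = 1e-10
    hu_air: float = -1000.0
    hu_tissue: float = 50.0
    mask_dilation_vox: int = 2
    verbose: bool = False

    def __post_init__(self) -> None:
        n = len(self.shrink_factors)
        if not (len(self.iterations) == len(self.control_spacing) == n):
            raise ValueError("per-level settings must have equal lengths")
        if list(self.shrink_factors) != sorted(self.shrink_factors, reverse=True):
            raise ValueError("levels must be ordered coarse to fine")
        if any(v <= 0 for v in self.shrink_factors + self.iterations
               + self.control_spacing):
            raise ValueError("all per-level settings must be positive")


def tissue_fraction(image: ImageVolume, hu_air: float = -1000.0,
                    hu_tissue: float = 50.0) -> np.ndarray:
    """Tissue fraction 1 - a from HU, clamped to [0, 1]."""
    a = (image.data - hu_tissue) / (hu_air - hu_tissue)
    return np.clip(1.0 - a, 0.0, 1.0)


# ---------------------------------------------------------------------------
# pyramid helpers
# ---------------------------------------------------------------------------

def _downsample(data: np.ndarray, k: int) -> np.ndarray:
    """Local-mean downsampling by integer factor k (edge padded)."""
    if k == 1:
        return np.asarray(data, dtype=float)
    pads = [(0, (-s) % k) for s in data.shape]
    d = np.pad(data, pads, mode="edge").astype(float)
    sh = []
    for s in d.shape:
        sh += [s // k, k]
    return d.reshape(sh).mean(axis=(1, 3, 5))


def _level_geometry(img: ImageVolume, k: int):
    shape = tuple((s + k - 1) // k for s in img.shape)
    spacing = tuple(s * k for s in img.spacing)
    origin = tuple(o + (k - 1) / 2.0 * s for o, s in zip(img.origin, img.spacing))
    return shape, spacing, origin


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def register(
    fixed: ImageVolume,
    moving: ImageVolume,
    fixed_mask: ImageVolume | None = None,
    moving_mask: ImageVolume | None = None,
    config: RegistrationConfig | None = None,
    initial: BSplineTransform | None = None,
) -> BSplineTransform:
    """Estimate the B-spline transform mapping fixed-frame points into the
    moving image, minimising the SSTVD cost over the fixed mask.

    Returns the transform of the finest level; its ``meta`` records the
    per-level cost trace.  Raises :class:`RegistrationError` when the masks
    do not overlap or a level ends with a higher cost than it started.
    """
    config = config or RegistrationConfig()
    if not np.allclose(fixed.spacing, moving.spacing) or fixed.shape != moving.shape:
        # different frames are allowed as long as geometry is physical; we
        # only require identical physical sampling for simplicity
        raise RegistrationError("fixed and moving must share a physical grid")

    vf_full = tissue_fraction(fixed, config.hu_air, config.hu_tissue)
    vm_full = tissue_fraction(moving, config.hu_air, config.hu_tissue)

    if fixed_mask is not None and moving_mask is not None:
        overlap = (fixed_mask.data > 0) & (moving_mask.data > 0)
        if not overlap.any():
            raise RegistrationError("fixed and moving masks do not overlap")
    if fixed_mask is not None:
        fmask_full = binary_dilation(fixed_mask.data > 0,
                                     iterations=config.mask_dilation_vox)
    else:
        fmask_full = np.ones(fixed.shape, dtype=bool)
    if not fmask_full.any():
        raise RegistrationError("empty fixed mask")

    transform: BSplineTransform | None = initial
    trace: list[list[float]] = []
    n_levels = len(config.shrink_factors)
    for lvl in range(n_levels):
        k = config.shrink_factors[lvl]
        shape, spacing, origin = _level_geometry(fixed, k)
        vf = _downsample(vf_full, k)
        vm = _downsample(vm_full, k)
        if config.smooth_sigma_vox > 0:
            from scipy.ndimage import gaussian_filter

            vf = gaussian_filter(vf, config.smooth_sigma_vox)
            vm = gaussian_filter(vm, config.smooth_sigma_vox)
        w = (_downsample(fmask_full.astype(float), k) > 0.25).astype(float)
        if transform is None:
            tf = BSplineTransform.identity_for(shape, spacing, origin,
                                               config.control_spacing[lvl])
        else:
            prev_u = transform.displacement_on(shape, spacing, origin)
            tf = BSplineTransform.fit_field(prev_u, shape, spacing, origin,
                                            config.control_spacing[lvl])
        costs = _optimize_level(tf, vf, vm, w, spacing, origin,
                                moving, config, config.iterations[lvl])
        if costs[-1] > costs[0] + 1e-12:
            raise RegistrationError(
                f"cost increased on level {lvl}: {costs[0]:.6g} -> {costs[-1]:.6g}"
            )
        trace.append(costs)
        transform = tf
        if config.verbose:
            print(f"[register] level {lvl} (shrink {k}): cost "
                  f"{costs[0]:.6g} -> {costs[-1]:.6g} in {len(costs)-1} evals")

    # the transform is evaluable anywhere; report it on the full-resolution
    # fixed geometry regardless of the finest pyramid level used
    transform.domain = (tuple(fixed.shape), tuple(fixed.spacing),
                        tuple(fixed.origin))
    transform.meta = {"cost_trace": trace}  # type: ignore[attr-defined]
    return transform


def _optimize_level(tf, vf, vm, w, spacing, origin, moving, config, maxiter):
    shape = vf.shape
    n_mask = float(w.sum())
    if n_mask == 0:
        raise RegistrationError("fixed mask empty at this pyramid level")
    inv_n = 1.0 / n_mask

    # moving tissue-fraction gradient (for the chain rule), on the level grid
    gm = np.stack(np.gradient(vm, *spacing), axis=-1)

    axes_phys = [origin[d] + np.arange(shape[d]) * spacing[d] for d in range(3)]
    grid_phys = np.stack(np.meshgrid(*axes_phys, indexing="ij"), axis=-1)
    mov_origin = np.asarray(moving.origin)
    # moving image was downsampled on the same physical frame as fixed
    mov_spacing = np.asarray(spacing)
    lvl_origin = np.asarray(origin)

    bend_ops = _bending_stencils(tf)
    coef_shape = tf.coef.shape
    costs: list[float] = []

    def fun(x: np.ndarray):
        tf.coef = x.reshape(coef_shape)
        u = tf.displacement_on(shape, spacing, origin)
        # warped coordinates in (level) voxel units of the moving image
        pos = (grid_phys + u - lvl_origin) / mov_spacing
        coords = [pos[..., d] for d in range(3)]
        vm_w = map_coordinates(vm, coords, order=1, mode="nearest")
        gm_w = np.stack(
            [map_coordinates(gm[..., d], coords, order=1, mode="nearest")
             for d in range(3)], axis=-1)

        G = tf.gradient_on(shape, spacing, origin)
        G[..., 0, 0] += 1.0
        G[..., 1, 1] += 1.0
        G[..., 2, 2] += 1.0
        J = _det3(G)
        C = _cofactor3(G)

        r = w * (vf - J * vm_w)
        data = float(np.sum(r * r)) * inv_n

        # folding penalty over the whole level grid
        deficit = np.maximum(config.fold_threshold - J, 0.0)
        fold = float(np.sum(deficit * deficit)) / J.size

        bend, bend_grad = _bending_energy(tf.coef, bend_ops)
        cost = data + config.fold_weight * fold + config.bend_weight * bend

        # gradient: dJ/dcoef via cofactors (derivative bases), plus the
        # moving-image term via value bases
        dJ_scale = (-2.0 * inv_n) * r * vm_w \
            + config.fold_weight * (-2.0 / J.size) * deficit
        grad = np.zeros(coef_shape)
        for j in range(3):
            S = dJ_scale[..., None] * C[..., :, j]
            grad += _scatter_separable(
                tf._bases(shape, spacing, origin, deriv_axis=j), S)
        S2 = ((-2.0 * inv_n) * r * J)[..., None] * gm_w
        grad += _scatter_separable(tf._bases(shape, spacing, origin), S2)
        grad += config.bend_weight * bend_grad

        costs.append(cost)
        return cost, grad.ravel()

    x0 = tf.coef.ravel().copy()
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": config.tol,
                            "gtol": 1e-12, "maxcor": 8})
    if float(res.fun) <= costs[0]:
        tf.coef = res.x.reshape(coef_shape)
        return [costs[0], float(res.fun)]
    # pathological backtrack: keep the starting point (never worsen)
    tf.coef = x0.reshape(coef_shape)
    return [costs[0], costs[0]]


def _bending_stencils(tf: BSplineTransform):
    """Second-difference operators per axis, scaled to curvature units."""
    return [1.0 / tf.ctrl_spacing[d] ** 2 for d in range(3)]


def _bending_energy(coef: np.ndarray, scales) -> tuple[float, np.ndarray]:
    """Approximate bending energy: mean squared second differences of the
    coefficients along each axis (in 1/mm curvature units), with gradient."""
    energy = 0.0
    grad = np.zeros_like(coef)
    n = coef[..., 0].size
    for ax, sc in enumerate(scales):
        d2 = np.diff(coef, n=2, axis=ax) * sc
        energy += float(np.sum(d2 * d2)) / n
        # adjoint of the second difference
        g = np.zeros_like(coef)
        sl = [slice(None)] * coef.ndim
        core = d2 * (2.0 * sc / n)
        sl[ax] = slice(0, coef.shape[ax] - 2)
        _add_at(g, tuple(sl), core)
        sl[ax] = slice(1, coef.shape[ax] - 1)
        _add_at(g, tuple(sl), -2.0 * core)
        sl[ax] = slice(2, coef.shape[ax])
        _add_at(g, tuple(sl), core)
        grad += g
    return energy, grad


def _add_at(arr, sl, val):
    arr[sl] += val


# ---------------------------------------------------------------------------
# public operations on transforms
# ---------------------------------------------------------------------------

def jacobian_determinant(
    transform: BSplineTransform,
    grid: ImageVolume | None = None,
    mask: ImageVolume | None = None,
) -> ImageVolume:
    """Per-voxel Jacobian determinant of the transform on a reference grid.

    Computed analytically from the B-spline derivative kernels.  Values > 1
    mean local expansion.  A warning is recorded in ``meta`` when
    non-positive determinants occur inside the mask (folding).
    """
    if grid is not None:
        shape, spacing, origin = grid.shape, grid.spacing, grid.origin
    else:
        shape, spacing, origin = transform.domain
    det = transform.jacobian_on(shape, spacing, origin)
    meta: dict = {"kind": "jacobian"}
    if mask is not None:
        folded = int(np.sum((det <= 0) & (mask.data > 0)))
        if folded:
            import warnings

            warnings.warn(f"{folded} folded voxels (det <= 0) inside mask")
        meta["folded_voxels"] = folded
    return ImageVolume(det, spacing, origin, meta=meta)


def warp(
    image: ImageVolume,
    transform: BSplineTransform,
    interpolation: str = "linear",
    fill: float = -1000.0,
) -> ImageVolume:
    """Resample ``image`` at transformed points of the reference grid.

    Output voxel x gets ``image(x + u(x))`` -- i.e. the moving image pulled
    back onto the fixed frame.  Out-of-domain samples get ``fill``.
    """
    shape, spacing, origin = transform.domain
    u = transform.displacement_on(shape, spacing, origin)
    axes_phys = [origin[d] + np.arange(shape[d]) * spacing[d] for d in range(3)]
    grid_phys = np.stack(np.meshgrid(*axes_phys, indexing="ij"), axis=-1)
    pos = (grid_phys + u - np.asarray(image.origin)) / np.asarray(image.spacing)
    order = {"linear": 1, "nearest": 0}[interpolation]
    out = map_coordinates(np.asarray(image.data, dtype=float),
                          [pos[..., d] for d in range(3)],
                          order=order, mode="constant", cval=fill)
    if interpolation == "nearest":
        out = out.astype(image.data.dtype)
    return ImageVolume(out, spacing, origin, meta=dict(image.meta))
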