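"""Rigid and multi-resolution deformable registration with invertible fields.

Conventions
-----------
* :class:`AffineTransform.matrix` maps *moving-space world mm* to
  *fixed-space world mm* (the geometric forward map).  Resampling the moving
  image onto the fixed grid therefore samples the moving image at
  ``M^{-1} x`` for each fixed-voxel world position ``x`` (pull-back).
* :class:`DeformationField` stores per-voxel displacements in world mm on
  the fixed grid.  The total pull-back map warping the moving image into
  fixed space is ``phi(x) = A^{-1}(x + u(x))`` with ``A`` the pre-affine and
  ``u`` the forward displacement.  The inverse displacement satisfies the
  fixed-point relation ``u_inv(x) = -u(x + u_inv(x))``.

The deformable backend is a demons-style scheme (SSD metric, Gaussian fluid
and diffusion smoothing, capped update steps) behind a pluggable contract:
any backend returning a metric-improving, invertible field satisfies it.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize

from .volume import GeometryError, PVEMap, Volume, normalize_pve

INV_TOL_VOXELS = 0.2  # forward-then-inverse residual bound, in voxels


class RegistrationError(RuntimeError):
    """Raised when a registration cannot be computed or does not converge."""


@dataclass
class AffineTransform:
    """4x4 world-mm map, moving space -> fixed space."""

    matrix: np.ndarray
    dof_tag: str = "rigid6"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise GeometryError("transform matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise GeometryError("transform matrix is singular")

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), dof_tag=self.dof_tag)

    @classmethod
    def identity(cls, dof_tag: str = "rigid6") -> "AffineTransform":
        return cls(np.eye(4), dof_tag=dof_tag)


@dataclass
class ResolutionSchedule:
    """Iterations per pyramid level, coarse -> fine (3 levels)."""

    iterations: tuple[int, int, int] = (50, 50, 50)

    def __post_init__(self) -> None:
        it = tuple(int(i) for i in self.iterations)
        if len(it) != 3 or any(i < 0 for i in it):
            raise ValueError("schedule needs 3 non-negative iteration counts")
        self.iterations = it

    @classmethod
    def parse(cls, text: str) -> "ResolutionSchedule":
        return cls(tuple(int(t) for t in text.lower().split("x")))  # type: ignore[arg-type]


#: Pyramid schedules mirroring a coarse / medium / fine plan.
SCHEDULE_COARSE = ResolutionSchedule((50, 0, 0))
SCHEDULE_MEDIUM = ResolutionSchedule((50, 50, 0))
SCHEDULE_FINE = ResolutionSchedule((50, 50, 50))


@dataclass
class DeformationField:
    """Invertible displacement field (mm) on the fixed grid, plus pre-affine."""

    forward: np.ndarray            # (3, *grid_shape) mm
    inverse: np.ndarray            # (3, *grid_shape) mm
    pre_affine: AffineTransform
    grid_affine: np.ndarray        # fixed-grid voxel -> world
    metric_trace: list = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=np.float64)
        self.inverse = np.asarray(self.inverse, dtype=np.float64)
        self.grid_affine = np.asarray(self.grid_affine, dtype=np.float64)
        if self.forward.ndim != 4 or self.forward.shape[0] != 3:
            raise GeometryError("displacement must have shape (3, X, Y, Z)")
        if self.forward.shape != self.inverse.shape:
            raise GeometryError("forward/inverse displacement shapes differ")
        if not (np.all(np.isfinite(self.forward)) and np.all(np.isfinite(self.inverse))):
            raise RegistrationError("displacement field contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.forward.shape[1:]  # type: ignore[return-value]

    @classmethod
    def identity(cls, shape: tuple[int, int, int], affine: np.ndarray) -> "DeformationField":
        zero = np.zeros((3,) + tuple(shape))
        return cls(zero, zero.copy(), AffineTransform.identity(), affine)


# ---------------------------------------------------------------------------
# sampling helpers

def _sample_at_world(volume: Volume, world_pts: np.ndarray, order: int = 1,
                     cval: float = 0.0) -> np.ndarray:
    """Sample a volume at world-mm points (3, ...) via interpolation."""
    shp = world_pts.shape[1:]
    vox = volume.world_to_voxel(world_pts.reshape(3, -1))
    out = ndimage.map_coordinates(volume.data, vox, order=order, mode="constant",
                                  cval=cval, prefilter=order > 1)
    return out.reshape(shp)


def _sample_field_at_world(disp: np.ndarray, grid_affine: np.ndarray,
                           world_pts: np.ndarray) -> np.ndarray:
    """Linearly interpolate a (3, *grid) mm-displacement at world points."""
    inv = np.linalg.inv(grid_affine)
    vox = inv[:3, :3] @ world_pts.reshape(3, -1) + inv[:3, 3:4]
    out = np.stack([
        ndimage.map_coordinates(disp[c], vox, order=1, mode="nearest")
        for c in range(3)
    ])
    return out.reshape(world_pts.shape)


def _target_geometry(target) -> tuple[tuple[int, int, int], np.ndarray]:
    if isinstance(target, Volume):
        return target.shape, target.affine
    shape, affine = target
    return tuple(shape), np.asarray(affine, dtype=np.float64)


_ORDER = {"linear": 1, "nearest": 0}


def apply_transform(image, xf, target_grid=None, interp: str = "linear"):
    """Resample an image (or PVEMap) through a transform onto a target grid.

    ``xf`` may be an :class:`AffineTransform` or a :class:`DeformationField`
    (its forward map).  PVEMap inputs are interpolated per class and
    renormalized to sum to 1 inside the warped mask.
    """
    if interp not in _ORDER:
        raise ValueError(f"unknown interp {interp!r}; use 'linear' or 'nearest'")
    order = _ORDER[interp]

    if isinstance(image, PVEMap):
        warped_maps = {}
        for k, m in image.maps.items():
            v = Volume(m, image.affine)
            warped_maps[k] = apply_transform(v, xf, target_grid, interp).data
        mask_v = Volume(image.mask.astype(np.float64), image.affine)
        warped_mask = apply_transform(mask_v, xf, target_grid, interp).data >= 0.5
        shape, affine = _resolve_target(xf, target_grid)
        from .volume import CLASSES

        stacked = np.stack([warped_maps[k] for k in CLASSES])
        return normalize_pve(stacked, warped_mask, affine)

    shape, affine = _resolve_target(xf, target_grid)
    tgt = Volume(np.zeros(shape), affine)
    world = tgt.world_coordinates()

    if isinstance(xf, AffineTransform):
        pull = np.linalg.inv(xf.matrix)
        pts = pull[:3, :3] @ world.reshape(3, -1) + pull[:3, 3:4]
        data = _sample_at_world(image, pts.reshape(world.shape), order=order)
    elif isinstance(xf, DeformationField):
        disp = _sample_field_at_world(xf.forward, xf.grid_affine, world)
        moved = world + disp
        pull = np.linalg.inv(xf.pre_affine.matrix)
        pts = pull[:3, :3] @ moved.reshape(3, -1) + pull[:3, 3:4]
        data = _sample_at_world(image, pts.reshape(world.shape), order=order)
    else:
        raise TypeError(f"unsupported transform type {type(xf).__name__}")
    return Volume(data, affine)


def _resolve_target(xf, target_grid):
    if target_grid is not None:
        return _target_geometry(target_grid)
    if isinstance(xf, DeformationField):
        return xf.grid_shape, xf.grid_affine
    raise ValueError("target_grid is required for affine transforms")


# ---------------------------------------------------------------------------
# rigid registration

def _rigid_matrix(params: np.ndarray, center: np.ndarray) -> np.ndarray:
    """6 params (tx, ty, tz mm, rx, ry, rz deg) -> 4x4 about ``center``."""
    t = params[:3]
    ang = np.deg2rad(params[3:6])
    cx, sx = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cz, sz = np.cos(ang[2]), np.sin(ang[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    rot = rz @ ry @ rx
    m = np.eye(4)
    m[:3, :3] = rot
    m[:3, 3] = t + center - rot @ center
    return m


def _downsample(data: np.ndarray, affine: np.ndarray, factor: int):
    if factor == 1:
        return data, affine
    sm = ndimage.gaussian_filter(data, sigma=factor / 2.0, mode="nearest")
    sub = sm[::factor, ::factor, ::factor]
    new_aff = affine.copy()
    new_aff[:3, :3] = affine[:3, :3] * factor
    return sub, new_aff


def register_rigid(moving: Volume, fixed: Volume, levels: tuple[int, ...] = (4, 2, 1),
                   ) -> AffineTransform:
    """6-DOF registration minimizing SSD over a resolution pyramid."""
    if np.ptp(moving.data) == 0 or np.ptp(fixed.data) == 0:
        raise RegistrationError("cannot register constant images")

    def com(vol: Volume) -> np.ndarray:
        w = np.clip(vol.data, 0, None)
        tot = w.sum()
        if tot <= 0:
            return np.zeros(3)
        idx = np.array(ndimage.center_of_mass(w))
        return vol.affine[:3, :3] @ idx + vol.affine[:3, 3]

    center = com(fixed)
    params = np.zeros(6)
    params[:3] = com(fixed) - com(moving)

    for li, factor in enumerate(levels):
        f_data, f_aff = _downsample(fixed.data, fixed.affine, factor)
        f_vol = Volume(f_data, f_aff)
        world = f_vol.world_coordinates().reshape(3, -1)
        # restrict the metric to a dilated foreground support: background
        # far from the object carries no signal and dominates the cost
        thresh = 0.02 * float(np.abs(f_data).max())
        support = ndimage.binary_dilation(np.abs(f_data) > thresh, iterations=3)
        if 0 < support.sum() < f_data.size:
            sel = support.ravel()
            world_sel = world[:, sel]
            f_sel = f_data.ravel()[sel]
        else:
            world_sel, f_sel = world, f_data.ravel()

        def cost(p: np.ndarray) -> float:
            m = _rigid_matrix(p, center)
            pull = np.linalg.inv(m)
            pts = pull[:3, :3] @ world_sel + pull[:3, 3:4]
            samp = _sample_at_world(moving, pts, order=1)
            d = samp - f_sel
            c = float(np.mean(d * d))
            if not np.isfinite(c):
                raise RegistrationError("non-finite registration metric")
            return c

        if cost(params) < 1e-12:
            break
        maxiter = 60 if li == 0 else 20  # finer levels start warm
        res = optimize.minimize(
            cost, params, method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": maxiter},
        )
        params = res.x

    return AffineTransform(_rigid_matrix(params, center), dof_tag="rigid6")


# ---------------------------------------------------------------------------
# deformable registration (demons-style backend)

def _ssd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.mean(d * d))


def _warp_level(m0: np.ndarray, u_vox: np.ndarray, base_idx: np.ndarray) -> np.ndarray:
    pts = base_idx + u_vox.reshape(3, -1)
    return ndimage.map_coordinates(m0, pts, order=1, mode="nearest").reshape(m0.shape)


def _demons_level(f: np.ndarray, m0: np.ndarray, u: np.ndarray, spacing: float,
                  iterations: int, fluid_sigma: float = 1.0,
                  diffusion_sigma: float = 1.0, step_cap: float = 0.4,
                  ) -> tuple[np.ndarray, list[float]]:
    """Demons iterations at one pyramid level; ``u`` in mm on the level grid."""
    shape = f.shape
    base_idx = np.indices(shape, dtype=np.float64).reshape(3, -1)
    trace = []
    best_u, best_ssd = u.copy(), _ssd(_warp_level(m0, u / spacing, base_idx), f)
    trace.append(best_ssd)
    cap = step_cap * spacing
    for _ in range(iterations):
        warped = _warp_level(m0, u / spacing, base_idx)
        diff = f - warped
        grad = np.stack(np.gradient(warped, spacing))
        gmag2 = (grad * grad).sum(axis=0)
        denom = gmag2 + (diff * diff) / (spacing * spacing)
        with np.errstate(invalid="ignore", divide="ignore"):
            upd = np.where(denom > 1e-9, diff / denom, 0.0)[None] * grad
        mag = np.sqrt((upd * upd).sum(axis=0))
        scale = np.where(mag > cap, cap / np.maximum(mag, 1e-12), 1.0)
        upd = upd * scale[None]
        upd = np.stack([ndimage.gaussian_filter(upd[c], fluid_sigma, mode="nearest")
                        for c in range(3)])
        u = u + upd
        u = np.stack([ndimage.gaussian_filter(u[c], diffusion_sigma, mode="nearest")
                      for c in range(3)])
        cur = _ssd(_warp_level(m0, u / spacing, base_idx), f)
        if not np.isfinite(cur):
            raise RegistrationError("deformable metric became non-finite")
        trace.append(cur)
        if cur < best_ssd:
            best_ssd, best_u = cur, u.copy()
    return best_u, trace


def _invert_displacement(u: np.ndarray, grid_affine: np.ndarray, world: np.ndarray,
                         max_iter: int = 20, tol_mm: float | None = None,
                         ) -> np.ndarray:
    """Fixed-point inverse: ``u_inv(x) = -u(x + u_inv(x))``."""
    u_inv = -u.copy()
    for _ in range(max_iter):
        u_inv_new = -_sample_field_at_world(u, grid_affine, world + u_inv)
        delta = np.abs(u_inv_new - u_inv).max()
        u_inv = u_inv_new
        if delta < 1e-4:
            break
    return u_inv


def composition_residual(field: DeformationField) -> float:
    """Max |forward-then-inverse| residual in mm over the grid."""
    world = Volume(np.zeros(field.grid_shape), field.grid_affine).world_coordinates()
    moved = world + field.forward
    back = _sample_field_at_world(field.inverse, field.grid_affine, moved)
    resid = field.forward + back
    return float(np.sqrt((resid * resid).sum(axis=0)).max())


def invert_deformation(field: DeformationField, max_iter: int = 20,
                       inv_tol_voxels: float = INV_TOL_VOXELS) -> DeformationField:
    """Swap forward/inverse (and invert the pre-affine), validating the residual.

    The returned field maps fixed-space images back onto the moving grid:
    its application form is ``A'^{-1}(y + u'(y))`` with ``A' = A^{-1}``.
    """
    world = Volume(np.zeros(field.grid_shape), field.grid_affine).world_coordinates()
    voxel = float(np.linalg.norm(field.grid_affine[:3, :3], axis=0).min())
    # recompute inverse to guarantee the fixed-point contract, then check it
    u_inv = _invert_displacement(field.forward, field.grid_affine, world, max_iter)
    cand = DeformationField(field.forward, u_inv, field.pre_affine, field.grid_affine)
    resid = composition_residual(cand)
    if resid > inv_tol_voxels * voxel:
        raise RegistrationError(
            f"deformation inverse did not converge: worst residual {resid:.3f} mm "
            f"exceeds {inv_tol_voxels} voxel ({inv_tol_voxels * voxel:.3f} mm)"
        )
    A = field.pre_affine
    R = A.matrix[:3, :3]
    Rinv = np.linalg.inv(R)
    # forward map of the inverted object: psi(y) = A y + u_inv(A y); in the
    # canonical form A'^{-1}(y + u'(y)) with A' = A^{-1} this requires
    # u'(y) = R^{-1} u_inv(A y).
    pts = A.matrix[:3, :3] @ world.reshape(3, -1) + A.matrix[:3, 3:4]
    u_at = _sample_field_at_world(u_inv, field.grid_affine, pts.reshape(world.shape))
    u_prime = np.einsum("ij,j...->i...", Rinv, u_at)
    u_prime_inv = np.einsum("ij,j...->i...", Rinv,
                            _sample_field_at_world(field.forward, field.grid_affine,
                                                   pts.reshape(world.shape)))
    return DeformationField(u_prime, u_prime_inv, A.inverse(), field.grid_affine)


def register_deformable(moving: Volume, fixed: Volume,
                        schedule: ResolutionSchedule = SCHEDULE_FINE,
                        pre_affine: AffineTransform | None = None,
                        ) -> DeformationField:
    """Rigid pre-alignment then multi-resolution demons refinement.

    The returned field warps ``moving`` into the fixed grid via
    :func:`apply_transform`; its SSD metric does not exceed the affine-only
    SSD, and the inverse displacement satisfies the composition tolerance.
    """
    if pre_affine is None:
        pre_affine = register_rigid(moving, fixed)
    m0 = apply_transform(moving, pre_affine, target_grid=fixed)

    factors = (4, 2, 1)
    voxel = float(fixed.voxel_sizes.min())
    u = None
    metric_trace: list[float] = []
    for factor, iters in zip(factors, schedule.iterations):
        f_data, f_aff = _downsample(fixed.data, fixed.affine, factor)
        m_data, _ = _downsample(m0.data, m0.affine, factor)
        spacing = voxel * factor
        if u is None:
            u = np.zeros((3,) + f_data.shape)
        elif u.shape[1:] != f_data.shape:
            zoom = np.array(f_data.shape) / np.array(u.shape[1:])
            u = np.stack([ndimage.zoom(u[c], zoom, order=1, mode="nearest")
                          for c in range(3)])
        if iters > 0:
            u, trace = _demons_level(f_data, m_data, u, spacing, iters)
            metric_trace.append(trace)
        else:
            metric_trace.append([])
    if u.shape[1:] != fixed.shape:
        zoom = np.array(fixed.shape) / np.array(u.shape[1:])
        u = np.stack([ndimage.zoom(u[c], zoom, order=1, mode="nearest")
                      for c in range(3)])

    world = fixed.world_coordinates()
    u_inv = _invert_displacement(u, fixed.affine, world)
    out = DeformationField(u, u_inv, pre_affine, fixed.affine,
                           metric_trace=metric_trace)
    return out


def registration_metric(moving: Volume, fixed: Volume, xf) -> float:
    """SSD of the warped moving image against the fixed image."""
    warped = apply_transform(moving, xf, target_grid=fixed)
    return _ssd(warped.data, fixed.data)
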