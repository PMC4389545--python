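"""File-preparation chain: brain extraction, bias correction, GM-peak norming.

The bias estimator is a simplified N4-style scheme: the multiplicative field
is modelled as ``exp(P)`` with ``P`` a low-order 3D polynomial, and ``P`` is
recovered by iteratively-reweighted least squares on the *gradient* of the
log image (piecewise-constant anatomy contributes zero gradient away from
edges, so edge voxels are down-weighted/excluded and the smooth residual is
attributed to the field).  The fitted field is gauged to unit geometric mean
inside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .register import AffineTransform, apply_transform, register_rigid
from .segment import SegConfig, segment_em
from .volume import GeometryError, PVEMap, Volume

PURE_GM_THRESHOLD = 0.999  # "PVE of 1.0" with float tolerance
GM_TARGET = 100.0


class PreprocessError(RuntimeError):
    pass


@dataclass
class BiasField:
    """Strictly positive multiplicative field on the same grid as its volume."""

    field: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=np.float64)
        if np.any(self.field <= 0):
            raise ValueError("bias field must be strictly positive")


def _poly_basis_and_grads(coords: np.ndarray, order: int):
    """Monomial basis (constant excluded) and analytic gradients.

    ``coords`` is (3, N) in normalized units; returns (basis (N, B),
    grads (3, N, B)).
    """
    x, y, z = coords
    exps = [
        (a, b, c)
        for a in range(order + 1)
        for b in range(order + 1)
        for c in range(order + 1)
        if 0 < a + b + c <= order
    ]
    n = x.size
    basis = np.empty((n, len(exps)))
    grads = np.zeros((3, n, len(exps)))
    for j, (a, b, c) in enumerate(exps):
        xa, yb, zc = x**a, y**b, z**c
        basis[:, j] = xa * yb * zc
        if a > 0:
            grads[0, :, j] = a * x ** (a - 1) * yb * zc
        if b > 0:
            grads[1, :, j] = b * xa * y ** (b - 1) * zc
        if c > 0:
            grads[2, :, j] = c * xa * yb * z ** (c - 1)
    return basis, grads


def estimate_bias_field(
    volume: Volume,
    mask: np.ndarray,
    control_spacing: float = 32.0,
    order: int = 2,
    n_iter: int = 3,
) -> BiasField:
    """Estimate a smooth multiplicative bias field inside ``mask``.

    ``control_spacing`` (mm) sets the coordinate normalization of the
    polynomial basis (larger spacing -> smoother fit for a given order).
    The output field has unit geometric mean inside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise PreprocessError("mask is empty")
    data = volume.data
    if np.all(data[mask] <= 0):
        raise PreprocessError("volume is all-zero inside the mask")

    eps = 1e-6 * max(float(data[mask].max()), 1.0)
    logv = np.log(np.clip(data, eps, None))

    # interior mask: stay clear of the mask boundary so finite differences
    # never straddle it
    interior = ndimage.binary_erosion(mask, structure=ball(1), iterations=2)
    if not interior.any():
        interior = mask

    spacing = volume.voxel_sizes
    grad = np.stack(np.gradient(logv, *spacing))  # d(log I)/d(mm)

    world = volume.world_coordinates()
    scale = max(float(control_spacing), 1e-6)
    coords_n = world / scale  # normalized coordinates

    gmag = np.sqrt((grad * grad).sum(axis=0))
    sel = interior.copy()
    coeffs = None
    basis_cache = None
    for _ in range(max(n_iter, 1)):
        vals = gmag[sel]
        if vals.size < 32:
            break
        # exclude anatomy edges: robust threshold on gradient magnitude,
        # dilated by one voxel so central differences near edges drop out too
        med = np.median(vals)
        mad = np.median(np.abs(vals - med)) + 1e-12
        thresh = med + 4.0 * 1.4826 * mad
        edge = (gmag > thresh) & interior
        edge = ndimage.binary_dilation(edge, structure=ball(1))
        fit_mask = interior & ~edge
        if fit_mask.sum() < 32:
            fit_mask = interior
        pts = coords_n[:, fit_mask]
        _, grads = _poly_basis_and_grads(pts, order)
        # gradient of P w.r.t. mm = grad w.r.t. normalized coord / scale
        design = np.concatenate([grads[c] for c in range(3)], axis=0) / scale
        target = np.concatenate([grad[c][fit_mask] for c in range(3)])
        coeffs, *_ = np.linalg.lstsq(design, target, rcond=None)
        sel = fit_mask

    if coeffs is None:
        logb = np.zeros_like(data)
    else:
        basis_full, _ = _poly_basis_and_grads(coords_n.reshape(3, -1), order)
        logb = (basis_full @ coeffs).reshape(data.shape)
    logb -= logb[mask].mean()  # unit geometric mean gauge
    return BiasField(np.exp(logb), volume.affine)


def correct_bias(volume: Volume, field: BiasField) -> Volume:
    """Divide out a multiplicative field, voxel-wise."""
    if volume.shape != field.field.shape:
        raise GeometryError("bias field grid does not match volume grid")
    return Volume(volume.data / field.field, volume.affine)


def normalize_gm_peak(
    volume: Volume, pve: PVEMap, threshold: float = PURE_GM_THRESHOLD
) -> tuple[Volume, float]:
    """Rescale intensities so the pure-GM peak intensity equals 100.

    The central pure-GM intensity is taken as the median over voxels with
    GM PVE above ``threshold``: the pure plateau dominates that set, so the
    median coincides with the histogram peak, whereas the mean is dragged by
    the asymmetric partial-volume band and would land the peak off 100.
    """
    pure = pve.maps["gm"] >= threshold
    if not pure.any():
        raise PreprocessError(
            f"no pure GM voxels (GM PVE >= {threshold}); segmentation unusable"
        )
    center = float(np.median(volume.data[pure]))
    if center <= 0:
        raise PreprocessError("non-positive central pure-GM intensity")
    scale = GM_TARGET / center
    return Volume(volume.data * scale, volume.affine), scale


def extract_brain(
    head: Volume,
    atlas_head: Volume,
    atlas_brain_mask: np.ndarray,
    closing_radius: int = 1,
) -> tuple[Volume, np.ndarray]:
    """Brain extraction by atlas-mask propagation.

    Registers the head to the atlas head (rigid), pulls the atlas brain mask
    back into subject space through the inverse transform, and closes it
    morphologically (ball radius 1 voxel).
    """
    atlas_brain_mask = np.asarray(atlas_brain_mask, dtype=bool)
    if not atlas_brain_mask.any():
        raise PreprocessError("atlas brain mask is empty")
    xf = register_rigid(head, atlas_head)  # head (moving) -> atlas (fixed)
    # subject voxel world y sits at atlas-world M y; sample the mask there
    mask_vol = Volume(atlas_brain_mask.astype(np.float64), atlas_head.affine)
    propagated = apply_transform(
        mask_vol, AffineTransform(np.linalg.inv(xf.matrix), dof_tag=xf.dof_tag),
        target_grid=head, interp="linear",
    )
    mask = propagated.data >= 0.5
    mask = ndimage.binary_closing(mask, structure=ball(max(closing_radius, 1)))
    brain = Volume(np.where(mask, head.data, 0.0), head.affine)
    return brain, mask


def prepare_brain(
    brain: Volume,
    mask: np.ndarray,
    correct_bias_field: bool = True,
    control_spacing: float = 32.0,
) -> tuple[Volume, PVEMap, dict]:
    """Bias-correct, provisionally segment (no priors), and GM-peak norm.

    Returns the normalized brain, the provisional prior-free PVE map, and a
    log dict with the scale factor.
    """
    log: dict = {}
    vol = brain
    if correct_bias_field:
        field = estimate_bias_field(vol, mask, control_spacing=control_spacing)
        vol = correct_bias(vol, field)
        log["bias_field_range"] = [float(field.field.min()), float(field.field.max())]
    seg = segment_em(vol, mask, priors=None, config=SegConfig())
    # under heavy noise posterior PVEs may never reach the pure threshold;
    # fall back to the most-confident GM voxels
    gm_max = float(seg.pve.maps["gm"].max())
    threshold = PURE_GM_THRESHOLD if gm_max >= PURE_GM_THRESHOLD else 0.95 * gm_max
    vol, scale = normalize_gm_peak(vol, seg.pve, threshold=threshold)
    log["gm_scale"] = scale
    log["gm_pure_threshold"] = threshold
    # rescale class means to the normalized intensity frame
    seg.class_means = {k: v * scale for k, v in seg.class_means.items()}
    return vol, seg.pve, log
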