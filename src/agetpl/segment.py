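"""Prior-guided Gaussian-mixture EM tissue classification (OM/GM/WM PVEs).

The partial volume estimate is the EM posterior probability (soft
assignment).  Spatial priors can be used in two modes:

* ``a_priori`` — priors seed the initial posteriors only; the per-voxel
  mixing weights are flat afterwards (global weights re-estimated).
* ``a_posteriori`` — the prior map enters every E-step as the per-voxel
  mixing weight pi_k(v).

With ``mrf_beta = 0`` (the default, no spatial regularization) the
log-likelihood trace is non-decreasing, which every test asserts.

By default a single pooled variance is shared across the classes
(``shared_variance=True``): intensity noise does not depend on tissue
class, and free per-class variances let one class inflate its sigma to
absorb partial-volume mixture voxels, which badly biases class volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import CLASSES, LABELS, PVEMap, Volume

PRIOR_USAGES = ("a_priori", "a_posteriori")


class SegmentationError(RuntimeError):
    pass


@dataclass
class SegConfig:
    prior_usage: str = "a_posteriori"
    mrf_beta: float = 0.0
    max_iter: int = 200
    tol: float = 1e-6           # relative log-likelihood change
    var_floor_rel: float = 1e-4  # sigma floor relative to intensity range
    shared_variance: bool = True  # one sigma for all classes (see module docs)

    def __post_init__(self) -> None:
        if self.prior_usage not in PRIOR_USAGES:
            raise ValueError(f"prior_usage must be one of {PRIOR_USAGES}")
        if self.mrf_beta < 0:
            raise ValueError("mrf_beta must be >= 0")


@dataclass
class SegResult:
    pve: PVEMap
    class_means: dict[str, float]
    class_sds: dict[str, float]
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _log_gauss(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi * sd * sd) - 0.5 * ((x - mu) / sd) ** 2


def segment_em(
    volume: Volume,
    mask: np.ndarray,
    priors=None,
    config: SegConfig | None = None,
) -> SegResult:
    """3-class Gaussian-mixture EM; PVE = final posterior probabilities.

    ``priors`` may be ``None``, a :class:`~agetpl.volume.PVEMap`, or a
    ``dict`` of per-class probability arrays already on the subject grid
    (use :func:`agetpl.register.apply_transform` to resample template-space
    priors first).  In-mask voxels where the prior sums to zero fall back to
    flat priors.
    """
    config = config or SegConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("mask is empty")
    x = volume.data[mask]
    if np.unique(x).size < len(CLASSES):
        raise SegmentationError(
            f"need at least {len(CLASSES)} distinct intensities, "
            f"got {np.unique(x).size}"
        )
    rng_span = float(np.ptp(x))
    sd_floor = max(config.var_floor_rel * rng_span, 1e-12)
    n = x.size
    K = len(CLASSES)

    prior_arr = None
    if priors is not None:
        if isinstance(priors, PVEMap):
            maps = priors.maps
        elif hasattr(priors, "maps"):
            maps = priors.maps  # TissuePriors duck-typing
        else:
            maps = priors
        prior_arr = np.stack([np.asarray(maps[k], dtype=np.float64)[mask]
                              for k in CLASSES])
        prior_arr = np.clip(prior_arr, 0.0, None)
        tot = prior_arr.sum(axis=0)
        dead = tot <= 1e-12
        if dead.any():
            prior_arr[:, dead] = 1.0 / K
            tot = prior_arr.sum(axis=0)
        prior_arr = prior_arr / tot

    # --- initialization ------------------------------------------------
    if prior_arr is not None:
        resp = prior_arr.copy()
        # guard against degenerate all-zero responsibilities for a class
        if np.any(resp.sum(axis=1) <= 1e-9):
            resp = 0.99 * resp + 0.01 / K
    else:
        # deterministic T1-ordered init; outer percentiles sit inside the
        # extreme-class intensity modes rather than in partial-volume bands
        mus = np.percentile(x, [10, 50, 90])
        sd0 = max(rng_span / 8.0, sd_floor)
        logp = np.stack([_log_gauss(x, mu, sd0) for mu in mus])
        logp -= logp.max(axis=0, keepdims=True)
        resp = np.exp(logp)
        resp /= resp.sum(axis=0)

    use_spatial_prior = prior_arr is not None and config.prior_usage == "a_posteriori"

    loglik_trace: list[float] = []
    mus = np.zeros(K)
    sds = np.ones(K)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        # M-step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        mus = (resp * x).sum(axis=1) / nk
        var = (resp * (x - mus[:, None]) ** 2).sum(axis=1) / nk
        if config.shared_variance:
            # pooled variance: intensity noise is class-independent, and a
            # free per-class sigma lets one class absorb partial-volume
            # mixtures, badly biasing class volumes
            var = np.full_like(var, float((var * nk).sum() / nk.sum()))
        sds = np.maximum(np.sqrt(var), sd_floor)
        weights = nk / n

        # E-step
        logp = np.stack([_log_gauss(x, mus[k], sds[k]) for k in range(K)])
        if use_spatial_prior:
            with np.errstate(divide="ignore"):
                logpi = np.log(prior_arr)
        else:
            with np.errstate(divide="ignore"):
                logpi = np.log(weights)[:, None] * np.ones((K, n))
        joint = logp + logpi
        jmax = joint.max(axis=0, keepdims=True)
        stable = joint - jmax
        denom = np.exp(stable).sum(axis=0)
        ll = float((jmax.ravel() + np.log(denom)).sum())
        resp = np.exp(stable) / denom

        loglik_trace.append(ll)
        if len(loglik_trace) > 1:
            prev = loglik_trace[-2]
            if abs(ll - prev) <= config.tol * abs(prev):
                converged = True
                break

    if not use_spatial_prior:
        # class identity is only weakly pinned without per-voxel priors;
        # enforce the T1 intensity ordering OM < GM < WM
        order = np.argsort(mus)
        mus, sds, resp = mus[order], sds[order], resp[order]

    pve_full = np.zeros((K,) + volume.shape)
    for k in range(K):
        pve_full[k][mask] = resp[k]
    pve = PVEMap({c: pve_full[i] for i, c in enumerate(CLASSES)}, mask, volume.affine)

    if config.mrf_beta > 0:
        pve = _mrf_icm(volume, pve, mus, sds, prior_arr if use_spatial_prior else None,
                       config)

    return SegResult(
        pve=pve,
        class_means={c: float(mus[i]) for i, c in enumerate(CLASSES)},
        class_sds={c: float(sds[i]) for i, c in enumerate(CLASSES)},
        loglik_trace=loglik_trace,
        n_iter=it,
        converged=converged,
    )


def _mrf_icm(volume, pve, mus, sds, prior_arr, config, n_passes: int = 3):
    """Potts smoothing of posteriors via iterated conditional modes."""
    mask = pve.mask
    K = len(CLASSES)
    post = pve.stacked()
    kernel = np.zeros((3, 3, 3))
    kernel[1, 1, 0] = kernel[1, 1, 2] = 1
    kernel[1, 0, 1] = kernel[1, 2, 1] = 1
    kernel[0, 1, 1] = kernel[2, 1, 1] = 1
    for _ in range(n_passes):
        labels = np.argmax(post, axis=0)
        logp = np.stack([
            np.where(mask, _log_gauss(volume.data, mus[k], sds[k]), 0.0)
            for k in range(K)
        ])
        for k in range(K):
            nbr = ndimage.convolve((labels == k).astype(np.float64), kernel,
                                   mode="constant")
            logp[k] += config.mrf_beta * nbr
        logp -= logp.max(axis=0, keepdims=True)
        post = np.exp(logp)
        post /= post.sum(axis=0)
        post[:, ~mask] = 0.0
    return PVEMap({c: post[i] for i, c in enumerate(CLASSES)}, mask, pve.affine)


def classify_hard(pve: PVEMap) -> np.ndarray:
    """Per-voxel argmax label; ties go to the lowest class (OM < GM < WM).

    Returns uint8 labels: 0 background, 1 OM, 2 GM, 3 WM.
    """
    stacked = pve.stacked()
    labels = np.argmax(stacked, axis=0).astype(np.uint8) + 1
    labels[~pve.mask] = 0
    return labels


def label_mask(labels: np.ndarray, tissue: str) -> np.ndarray:
    """Binary mask of one tissue class from a hard label volume."""
    return labels == LABELS[tissue]
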