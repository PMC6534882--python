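"""Affine registration of atlas slices to a target slice under NCC.

The transform is a 2-D similarity ``p' = K·R(theta)·(p - c) + c + t`` about
the image center ``c`` with isotropic scale ``K``, rotation ``theta`` and
translation ``t = (dy, dx)`` in pixels.  Similarity between target and
warped atlas is the normalized correlation coefficient (NCC), evaluated over
the target ROI box so background pixels do not dominate.

The optimizer is a 3-level Gaussian pyramid with phase-correlation
translation initialization and derivative-free (Nelder–Mead) refinement,
multi-started over rotation at the coarsest level.  It is fully
deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from skimage.registration import phase_cross_correlation
from skimage.transform import pyramid_reduce

from .imageio import Atlas, RoiBox


@dataclass(frozen=True)
class AffineParams:
    """Similarity-transform parameters: scale K, rotation theta (rad),
    translation (dx, dy) in (column, row) pixels."""

    K: float = 1.0
    theta: float = 0.0
    dx: float = 0.0
    dy: float = 0.0

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"scale K must be positive, got {self.K}")

    @property
    def is_identity(self) -> bool:
        return self.K == 1.0 and self.theta == 0.0 and self.dx == 0.0 and self.dy == 0.0

    def inverse(self) -> "AffineParams":
        """Parameters of the inverse transform about the same center."""
        c, s = np.cos(-self.theta), np.sin(-self.theta)
        # t' = -(1/K)·R(-theta)·t, with t = (dy, dx) in (row, col) order
        tr = -(c * self.dy - s * self.dx) / self.K
        tc = -(s * self.dy + c * self.dx) / self.K
        return AffineParams(K=1.0 / self.K, theta=-self.theta, dx=tc, dy=tr)

    def to_json(self) -> str:
        return json.dumps(
            {"K": self.K, "theta_rad": self.theta, "dx": self.dx, "dy": self.dy}
        )


@dataclass
class RegistrationResult:
    params: AffineParams
    ncc: float
    warped_intensity: np.ndarray
    warped_label: np.ndarray | None = None
    atlas_id: str = ""
    converged: bool = True
    selected_by_fallback: bool = False


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def apply_affine(
    img: np.ndarray, params: AffineParams, interpolation: str = "bilinear"
) -> np.ndarray:
    """Warp an image by the similarity transform (inverse-mapped sampling).

    Out-of-bounds samples are 0 (background).  Label images (integer dtype)
    must use nearest-neighbor interpolation.
    """
    arr = np.asarray(img)
    is_label = np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool
    if interpolation == "bilinear":
        if is_label:
            raise ValueError("bilinear interpolation is invalid for label images")
        order = 1
    elif interpolation == "nearest":
        order = 0
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if params.is_identity and order == 0:
        return arr.copy()
    center = (np.array(arr.shape, dtype=float) - 1.0) / 2.0
    t = np.array([params.dy, params.dx])
    rows, cols = np.indices(arr.shape)
    out = np.stack([rows.ravel(), cols.ravel()]).astype(float)
    # inverse map: p = R(-theta)/K · (p' - c - t) + c
    src = (_rot(-params.theta) / params.K) @ (out - (center + t)[:, None]) + center[:, None]
    warped = ndimage.map_coordinates(
        arr.astype(float), src, order=order, mode="constant", cval=0.0
    )
    warped = warped.reshape(arr.shape)
    if is_label:
        return warped.astype(arr.dtype)
    return warped


def ncc(target: np.ndarray, warped: np.ndarray, roi: RoiBox | None = None) -> float:
    """Normalized correlation coefficient between two equal-shape images.

    Evaluated over the ROI box when given.  Zero variance in either image is
    defined as NCC 0 (no evidence of similarity) so blank slices do not abort
    multi-atlas runs.
    """
    a = np.asarray(target, dtype=np.float64)
    b = np.asarray(warped, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if roi is not None:
        a, b = a[roi.slices], b[roi.slices]
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        return 0.0
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


@dataclass(frozen=True)
class SearchConfig:
    """Registration optimizer settings."""

    n_levels: int = 3
    theta_starts: tuple[float, ...] = (-0.30, -0.15, 0.0, 0.15, 0.30)
    k_bounds: tuple[float, float] = (0.5, 2.0)
    maxiter_coarse: int = 120
    maxiter_fine: int = 80
    xatol: float = 1e-3
    fatol: float = 1e-6


def _pyramid(img: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Fine-to-coarse Gaussian pyramid (factor 2 per level)."""
    levels = [np.asarray(img, dtype=np.float64)]
    for _ in range(n_levels - 1):
        if min(levels[-1].shape) < 16:
            break
        levels.append(pyramid_reduce(levels[-1], downscale=2, channel_axis=None))
    return levels


def _scale_roi(roi: RoiBox | None, factor: float, shape: tuple[int, int]) -> RoiBox | None:
    if roi is None:
        return None
    r0 = int(np.floor(roi.row_min * factor))
    r1 = min(shape[0], max(r0 + 1, int(np.ceil(roi.row_max * factor))))
    c0 = int(np.floor(roi.col_min * factor))
    c1 = min(shape[1], max(c0 + 1, int(np.ceil(roi.col_max * factor))))
    return RoiBox(r0, r1, c0, c1)


def register(
    target: np.ndarray,
    atlas: Atlas,
    config: SearchConfig | None = None,
    roi: RoiBox | None = None,
) -> RegistrationResult:
    """Estimate the similarity transform aligning an atlas to the target.

    Returns the best parameters found by the pyramid search together with
    the warped intensity and (nearest-neighbor) warped label.  If no
    candidate improves on the identity transform, the identity result is
    returned with ``converged=False``.
    """
    cfg = config or SearchConfig()
    tgt = np.asarray(target, dtype=np.float64)
    if tgt.shape != atlas.intensity.shape:
        raise ValueError("target and atlas must share a common grid")

    tgt_pyr = _pyramid(tgt, cfg.n_levels)
    atl_pyr = _pyramid(atlas.intensity, cfg.n_levels)
    n_levels = len(tgt_pyr)

    def objective(x: np.ndarray, level: int, roi_l: RoiBox | None) -> float:
        k, th, dx, dy = x
        lo, hi = cfg.k_bounds
        if not (lo <= k <= hi) or abs(th) > np.pi:
            return 1.0
        p = AffineParams(K=float(k), theta=float(th), dx=float(dx), dy=float(dy))
        w = apply_affine(atl_pyr[level], p, "bilinear")
        return -ncc(tgt_pyr[level], w, roi_l)

    # --- coarsest level: translation init + theta multi-start
    level = n_levels - 1
    factor = 2.0 ** (-level)
    roi_l = _scale_roi(roi, factor, tgt_pyr[level].shape)
    shift, _, _ = phase_cross_correlation(
        tgt_pyr[level], atl_pyr[level], upsample_factor=4, normalization=None
    )
    dy0, dx0 = float(shift[0]), float(shift[1])

    best_x, best_f = None, np.inf
    for th0 in cfg.theta_starts:
        x0 = np.array([1.0, th0, dx0, dy0])
        res = minimize(
            objective,
            x0,
            args=(level, roi_l),
            method="Nelder-Mead",
            options={
                "maxiter": cfg.maxiter_coarse,
                "xatol": cfg.xatol,
                "fatol": cfg.fatol,
                "initial_simplex": _simplex(x0, (0.05, 0.1, 2.0, 2.0)),
            },
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun

    # --- refine through finer levels
    for level in range(n_levels - 2, -1, -1):
        factor = 2.0 ** (-level)
        roi_l = _scale_roi(roi, factor, tgt_pyr[level].shape)
        x0 = best_x.copy()
        x0[2:] *= 2.0  # translations double at each finer level
        res = minimize(
            objective,
            x0,
            args=(level, roi_l),
            method="Nelder-Mead",
            options={
                "maxiter": cfg.maxiter_fine,
                "xatol": cfg.xatol,
                "fatol": cfg.fatol,
                "initial_simplex": _simplex(x0, (0.02, 0.03, 1.0, 1.0)),
            },
        )
        best_x, best_f = res.x, res.fun

    params = AffineParams(
        K=float(best_x[0]), theta=float(best_x[1]), dx=float(best_x[2]), dy=float(best_x[3])
    )
    warped = apply_affine(atlas.intensity, params, "bilinear")
    score = ncc(tgt, warped, roi)
    identity_score = ncc(tgt, atlas.intensity, roi)
    converged = True
    if score < identity_score:
        warnings.warn(
            f"registration of atlas {atlas.id!r} failed to improve on identity",
            stacklevel=2,
        )
        params, score, converged = AffineParams(), identity_score, False
        warped = atlas.intensity.copy()
    warped_label = apply_affine(atlas.label, params, "nearest")
    return RegistrationResult(
        params=params,
        ncc=score,
        warped_intensity=warped,
        warped_label=warped_label,
        atlas_id=atlas.id,
        converged=converged,
    )


def _simplex(x0: np.ndarray, steps: Sequence[float]) -> np.ndarray:
    simplex = np.tile(x0, (len(x0) + 1, 1))
    for i, s in enumerate(steps):
        simplex[i + 1, i] += s
    return simplex


def register_all(
    target: np.ndarray,
    atlases: Sequence[Atlas],
    ncc_threshold: float = 0.87,
    fallback_k: int = 3,
    config: SearchConfig | None = None,
    roi: RoiBox | None = None,
) -> list[RegistrationResult]:
    """Register every atlas and keep those with NCC above the threshold.

    If no atlas passes, the top ``fallback_k`` by NCC are returned with
    ``selected_by_fallback=True`` so downstream fusion still has votes.
    """
    if len(atlases) == 0:
        raise ValueError("register_all requires at least one atlas")
    results = [register(target, a, config=config, roi=roi) for a in atlases]
    selected = [r for r in results if r.ncc > ncc_threshold]
    if not selected:
        ranked = sorted(results, key=lambda r: r.ncc, reverse=True)
        selected = ranked[: max(1, fallback_k)]
        for r in selected:
            r.selected_by_fallback = True
    return selected
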