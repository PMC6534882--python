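"""Parametric active contour (snake) evolution.

The snake minimizes the classic closed-curve energy

    E = ∮ ( α/2 |v'(s)|² + β/2 |v''(s)|² − γ E_img(v(s)) ) ds

with α the elasticity weight, β the bending weight and γ the weight of the
external (image) term.  The hybrid potential combines squared gradient
magnitude and a per-pixel intensity-prior weight,

    E_img(x) = | |∇(G_σ * I)(x)|² + P(x) |,

and is large at edges and at modal-intensity pixels, so the *attraction*
force is +γ·∇E_img and the external energy contribution is −γ·E_img (the
curve is pulled toward high E_img).

Time stepping is the standard semi-implicit scheme: the internal terms are
solved implicitly through a cyclic pentadiagonal system, the external force
is applied explicitly with bilinear sampling, and the step size is halved
whenever a step would increase the total discrete energy, making the energy
non-increasing between resampling events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.linalg import lu_factor, lu_solve

from .template import IntensityPrior, InitialActiveContour, resample_closed


@dataclass(frozen=True)
class SnakeParams:
    """Evolution parameters.

    alpha, beta, gamma follow the energy above (constants per run); the
    defaults are the white-matter profile.  ``tol`` is the mean point
    displacement (pixels) below which, sustained for ``tol_iters``
    consecutive iterations, the evolution is declared converged.
    """

    alpha: float = 30.0
    beta: float = 70.0
    gamma: float = 70.0
    step_size: float = 0.01
    max_iters: int = 500
    tol: float = 0.05
    tol_iters: int = 10
    resample_every: int = 25
    min_evolve_area: float = 20.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("alpha, beta, gamma must be nonnegative")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")


@dataclass
class PotentialField:
    """External potential E_img and its spatial gradient (force field)."""

    energy: np.ndarray
    force_r: np.ndarray
    force_c: np.ndarray

    def sample_energy(self, points: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            self.energy, points.T, order=1, mode="nearest"
        )

    def sample_force(self, points: np.ndarray) -> np.ndarray:
        fr = ndimage.map_coordinates(self.force_r, points.T, order=1, mode="nearest")
        fc = ndimage.map_coordinates(self.force_c, points.T, order=1, mode="nearest")
        return np.stack([fr, fc], axis=1)


@dataclass
class SnakeState:
    """Final contour loops with iteration/energy bookkeeping."""

    loops: list[np.ndarray]
    iterations: int
    energy: float
    converged: bool
    clamped: bool = False
    #: per loop, a list of energy segments; a new segment starts after each
    #: arc-length resampling (energy is non-increasing within a segment)
    energy_trace: list[list[list[float]]] = field(default_factory=list)


def build_potential(
    target: np.ndarray, prior: IntensityPrior | None = None, sigma: float = 0.5
) -> PotentialField:
    """Hybrid grayscale+gradient external potential.

    The target is smoothed with a Gaussian of the given sigma; the squared
    gradient magnitude of the smoothed image is added to the per-pixel
    intensity-prior weight P(x) (omitted when no prior is given); the
    absolute value is the potential and its spatial gradient the attraction
    force.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = np.asarray(target, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(img, sigma=sigma)
    gr, gc = np.gradient(smoothed)
    e_img = gr * gr + gc * gc
    if prior is not None:
        e_img = e_img + prior.weight_of(np.clip(smoothed, 0.0, 1.0), smooth=True)
    e_img = np.abs(e_img)
    force_r, force_c = np.gradient(e_img)
    return PotentialField(energy=e_img, force_r=force_r, force_c=force_c)


def internal_energy(points: np.ndarray, alpha: float, beta: float) -> float:
    """Discrete internal energy of a closed polygon.

    Cyclic finite differences with unit parameter spacing:
    ``0.5 * sum(alpha |v_{i+1}-v_i|^2 + beta |v_{i+1}-2v_i+v_{i-1}|^2)``.
    """
    v = np.asarray(points, dtype=np.float64)
    if v.ndim != 2 or len(v) < 4:
        raise ValueError("need a closed loop of at least 4 points")
    d1 = np.roll(v, -1, axis=0) - v
    d2 = np.roll(v, -1, axis=0) - 2 * v + np.roll(v, 1, axis=0)
    return float(0.5 * (alpha * (d1 * d1).sum() + beta * (d2 * d2).sum()))


def total_energy(points: np.ndarray, field_: PotentialField, params: SnakeParams) -> float:
    """Internal energy minus the gamma-weighted sampled potential."""
    ext = -params.gamma * float(field_.sample_energy(points).sum())
    return internal_energy(points, params.alpha, params.beta) + ext


def _internal_matrix(n: int, alpha: float, beta: float) -> np.ndarray:
    """Cyclic pentadiagonal stiffness matrix of the internal energy."""
    a, b = alpha, beta
    m = np.zeros((n, n))
    idx = np.arange(n)
    m[idx, idx] = 2 * a + 6 * b
    m[idx, (idx + 1) % n] = -a - 4 * b
    m[idx, (idx - 1) % n] = -a - 4 * b
    m[idx, (idx + 2) % n] = b
    m[idx, (idx - 2) % n] = b
    return m


def evolve(
    iac: InitialActiveContour,
    field_: PotentialField,
    params: SnakeParams | None = None,
) -> SnakeState:
    """Evolve every loop of the initial active contour to convergence.

    Semi-implicit Euler: ``(I + τ·M) v_new = v_old + τ·γ·F(v_old)`` with M
    the internal stiffness matrix and F the bilinearly sampled attraction
    force.  Steps that would raise the total discrete energy trigger step
    halving (retried up to 30 times), so the energy is non-increasing
    between arc-length resampling events (every ``resample_every``
    iterations).  Points leaving the image are clamped to the frame and
    flagged.  Deterministic.
    """
    p = params or SnakeParams()
    shape = field_.energy.shape
    out_loops: list[np.ndarray] = []
    traces: list[list[float]] = []
    clamped_any = False
    total_iters = 0
    converged_all = True
    for loop in iac.loops:
        v = np.asarray(loop, dtype=np.float64).copy()
        n = len(v)
        if _shoelace_area(v) < p.min_evolve_area:
            # sub-resolution loop: below the snake's spatial discretization
            # scale the elastic term would simply collapse it; pass through
            out_loops.append(v)
            traces.append([[]])
            continue
        tau = p.step_size
        lu = _factor(n, tau, p)
        energy = total_energy(v, field_, p)
        segments = [[energy]]
        calm = 0
        it = 0
        converged = False
        while it < p.max_iters:
            it += 1
            accepted = False
            for _ in range(30):
                rhs = v + tau * p.gamma * field_.sample_force(v)
                v_new = np.column_stack(
                    [lu_solve(lu, rhs[:, 0]), lu_solve(lu, rhs[:, 1])]
                )
                lo = np.zeros(2)
                hi = np.array(shape, dtype=float) - 1.0
                clipped = np.clip(v_new, lo, hi)
                if not np.array_equal(clipped, v_new):
                    clamped_any = True
                    v_new = clipped
                e_new = total_energy(v_new, field_, p)
                if e_new <= energy + 1e-9:
                    accepted = True
                    break
                tau /= 2.0
                lu = _factor(n, tau, p)
            if not accepted:
                converged = True  # cannot descend further at any step size
                break
            disp = float(np.linalg.norm(v_new - v, axis=1).mean())
            v, energy = v_new, e_new
            segments[-1].append(energy)
            calm = calm + 1 if disp < p.tol else 0
            if calm >= p.tol_iters:
                converged = True
                break
            if p.resample_every and it % p.resample_every == 0:
                v = resample_closed(v, n)
                energy = total_energy(v, field_, p)
                segments.append([energy])
        if not converged:
            converged_all = False
        total_iters = max(total_iters, it)
        out_loops.append(v)
        traces.append(segments)
    final_energy = sum(total_energy(v, field_, p) for v in out_loops)
    return SnakeState(
        loops=out_loops,
        iterations=total_iters,
        energy=final_energy,
        converged=converged_all,
        clamped=clamped_any,
        energy_trace=traces,
    )


def _factor(n: int, tau: float, p: SnakeParams):
    m = np.eye(n) + tau * _internal_matrix(n, p.alpha, p.beta)
    try:
        return lu_factor(m)
    except Exception as exc:  # pragma: no cover - degenerate parameters
        raise ValueError(f"singular snake system (n={n}, tau={tau})") from exc


def contour_to_mask(
    state: SnakeState | InitialActiveContour | list, shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize closed loops into a binary mask (union of even–odd fills).

    A pixel is foreground when its center lies strictly inside a loop by
    the even–odd (ray crossing) rule, or exactly on a loop edge (inclusive
    boundary rule).  Degenerate loops of sub-pixel area contribute nothing.
    """
    if isinstance(state, (SnakeState, InitialActiveContour)):
        loops = state.loops
    else:
        loops = [np.asarray(l, dtype=np.float64) for l in state]
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    px = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    for loop in loops:
        v = np.asarray(loop, dtype=np.float64)
        if len(v) < 3 or _shoelace_area(v) < 1.0:
            warnings.warn("degenerate loop (< 1 px area) contributes no pixels",
                          stacklevel=2)
            continue
        mask |= _even_odd_fill(v, px).reshape(shape)
        mask |= _on_edge(v, shape)
    return mask


def _shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return float(
        0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    )


def _even_odd_fill(poly: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Vectorized even–odd (crossing-number) point-in-polygon test."""
    inside = np.zeros(len(points), dtype=bool)
    x, y = points[:, 0], points[:, 1]
    n = len(poly)
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        if y0 == y1:
            continue
        crosses = ((y0 > y) != (y1 > y)) & (
            x < (x1 - x0) * (y - y0) / (y1 - y0) + x0
        )
        inside ^= crosses
    return inside


def _on_edge(poly: np.ndarray, shape: tuple[int, int], eps: float = 1e-9) -> np.ndarray:
    """Pixels whose center lies exactly (within eps) on a polygon edge."""
    out = np.zeros(shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        p0, p1 = poly[i], poly[(i + 1) % n]
        lo = np.floor(np.minimum(p0, p1)).astype(int)
        hi = np.ceil(np.maximum(p0, p1)).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.array(shape) - 1)
        if np.any(hi < lo):
            continue
        rr, cc = np.mgrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1]
        pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        d = p1 - p0
        seg_len2 = float(d @ d)
        if seg_len2 == 0:
            dist = np.linalg.norm(pts - p0, axis=1)
        else:
            t = np.clip((pts - p0) @ d / seg_len2, 0.0, 1.0)
            dist = np.linalg.norm(pts - (p0 + t[:, None] * d), axis=1)
        hit = pts[dist <= eps].astype(int)
        out[hit[:, 0], hit[:, 1]] = True
    return out
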