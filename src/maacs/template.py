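"""Template optimization: correct registration errors in the fused template.

Three steps re-select the tissue contour from image evidence:

1. *Search-area setting* — around every pixel of the template contour a
   square search window is opened; when another, non-adjacent contour line
   crosses the window along a coordinate axis, the window is clipped back to
   the midpoint between the two contour lines so neighboring windows do not
   claim each other's boundary.
2. *Contour-point determination* — every pixel inside the actual search
   areas is scored by ``Y = w_p * P(x) + w_g * grad_norm(x)``, where ``P`` is
   an intensity prior (a 20-bin histogram of intensities on the structure
   contour in the atlas set, min–max rescaled) and ``grad_norm`` is the
   Roberts gradient magnitude min–max normalized over the search-area
   support.  Pixels with Y at or above a threshold are accepted.
3. *Initial-active-contour acquisition* — the accepted points are rastered,
   1-px gaps are closed, each connected component is traced with
   Moore-neighbor boundary following, and the ordered loops are resampled to
   uniform arc-length spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import roberts

from .fusion import InitialTemplate
from .imageio import Atlas

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class IntensityPrior:
    """Histogram prior over contour-pixel intensities on [0, 1].

    ``pr`` are the per-bin relative frequencies (summing to 1) and
    ``weights`` their min–max rescaling: the modal bin gets weight 1, the
    emptiest bin weight 0.  When every bin is equally full the prior is
    uninformative and all weights are 1.
    """

    counts: np.ndarray
    bin_edges: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 1 or self.counts.size < 2:
            raise ValueError("counts must be a 1-D array of >= 2 bins")
        if self.counts.min() < 0:
            raise ValueError("negative bin count")
        if self.counts.sum() == 0:
            raise ValueError("empty histogram")
        if self.bin_edges is None:
            self.bin_edges = np.linspace(0.0, 1.0, self.counts.size + 1)
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.pr = self.counts / self.counts.sum()
        lo, hi = self.pr.min(), self.pr.max()
        if hi > lo:
            self.weights = (self.pr - lo) / (hi - lo)
        else:  # uninformative prior: defer entirely to the gradient term
            self.weights = np.ones_like(self.pr)

    @property
    def n_bins(self) -> int:
        return self.counts.size

    def bin_of(self, values: np.ndarray) -> np.ndarray:
        """Bin index of each intensity (right edge inclusive in last bin)."""
        idx = np.digitize(np.asarray(values), self.bin_edges[1:-1], right=False)
        return np.clip(idx, 0, self.n_bins - 1)

    def weight_of(self, values: np.ndarray, smooth: bool = False) -> np.ndarray:
        """Prior weight P(x) for each intensity value.

        ``smooth=True`` interpolates linearly between bin centers instead of
        the piecewise-constant bin lookup — used where a spatially
        differentiable P is needed (the snake's external force), since the
        binned P has zero gradient almost everywhere.
        """
        vals = np.asarray(values)
        if not smooth:
            return self.weights[self.bin_of(vals)]
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return np.interp(vals, centers, self.weights)

    def to_json(self) -> str:
        return json.dumps(
            {
                "bin_edges": self.bin_edges.tolist(),
                "counts": self.counts.tolist(),
                "pr": self.pr.tolist(),
                "weights": self.weights.tolist(),
            }
        )


@dataclass(frozen=True)
class SearchArea:
    """Axis-aligned search window around a contour pixel.

    Extents are per-direction distances from the center (all >= 0); the
    window is ``[row-up, row+down] x [col-left, col+right]`` clipped to the
    image frame when rasterized.
    """

    row: int
    col: int
    left: int
    right: int
    up: int
    down: int

    def __post_init__(self) -> None:
        if min(self.left, self.right, self.up, self.down) < 0:
            raise ValueError("search-area extents must be nonnegative")


@dataclass
class ContourPointSet:
    """Accepted contour points and their decision scores."""

    points: np.ndarray  # (n, 2) integer (row, col)
    scores: np.ndarray  # (n,)
    threshold: float
    score_image: np.ndarray | None = None


@dataclass
class InitialActiveContour:
    """One or more ordered closed loops of (row, col) points."""

    loops: list[np.ndarray]

    def __post_init__(self) -> None:
        self.loops = [np.asarray(l, dtype=np.float64) for l in self.loops]
        for l in self.loops:
            if l.ndim != 2 or l.shape[1] != 2 or len(l) < 4:
                raise ValueError("each loop must be an (n>=4, 2) point array")

    def to_json(self) -> str:
        return json.dumps([l.tolist() for l in self.loops])


# ---------------------------------------------------------------------------
# intensity prior


def boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels 8-adjacent to background (1-px boundary)."""
    fg = np.asarray(mask).astype(bool)
    return fg & ~ndimage.binary_erosion(fg, structure=_EIGHT, border_value=0)


def contour_ring(mask: np.ndarray) -> np.ndarray:
    """Two-sided boundary ring: pixels whose 3x3 neighborhood spans the
    fore/background transition (morphological gradient).

    Intensities *on the contour* straddle the edge, so sampling both sides
    centers the intensity histogram on the edge mid-intensity rather than
    on the structure interior.
    """
    fg = np.asarray(mask).astype(bool)
    dil = ndimage.binary_dilation(fg, structure=_EIGHT, border_value=0)
    ero = ndimage.binary_erosion(fg, structure=_EIGHT, border_value=0)
    return dil & ~ero


def build_intensity_prior(
    atlases: Sequence[Atlas],
    target_class: int,
    n_bins: int = 20,
    sigma: float = 0.5,
    smooth_bins: bool = True,
) -> IntensityPrior:
    """Histogram the (smoothed) intensities on the structure contour of each
    atlas's own label image into ``n_bins`` uniform bins on [0, 1].

    Atlas intensities must already be normalized to [0, 1]; each is smoothed
    with a Gaussian of the given sigma before sampling, matching the
    preprocessing applied to the target when scoring candidates.  Intensities
    are sampled (bilinearly) at subpixel positions on the 0.5 iso-contour of
    the class mask — the intensity *on* the contour — which centers the
    histogram mode at the edge mid-intensity regardless of how the label
    rasterization rounds boundary pixels.
    """
    from skimage.measure import find_contours

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.float64)
    found = False
    for atlas in atlases:
        mask = (atlas.label == target_class).astype(float)
        contours = find_contours(mask, 0.5)
        if not contours:
            continue
        found = True
        smoothed = ndimage.gaussian_filter(atlas.intensity, sigma=sigma)
        for contour in contours:
            vals = np.clip(
                ndimage.map_coordinates(smoothed, contour.T, order=1), 0.0, 1.0
            )
            hist, _ = np.histogram(vals, bins=edges)
            counts += hist
    if not found:
        raise ValueError(f"no contour pixels for class {target_class} in any atlas")
    if smooth_bins:
        # light kernel smoothing of the sampled histogram: a density-estimate
        # of the contour-intensity distribution rather than the raw counts,
        # so a one-bin gap in the samples does not zero out the weight there
        kernel = np.array([1.0, 2.0, 1.0]) / 4.0
        counts = np.convolve(counts, kernel, mode="same")
    return IntensityPrior(counts=counts, bin_edges=edges)


# ---------------------------------------------------------------------------
# search areas


def extract_template_contour(template: InitialTemplate | np.ndarray) -> np.ndarray:
    """(n, 2) array of template contour pixels (row, col)."""
    binary = template.binary if isinstance(template, InitialTemplate) else template
    if not np.any(binary):
        raise ValueError("cannot extract the contour of an empty template")
    return np.argwhere(boundary_mask(binary))


def set_search_areas(
    contour: np.ndarray, initial_half_width: int = 8, shape: tuple[int, int] | None = None
) -> list[SearchArea]:
    """Open a square search window per contour pixel, clipped at other
    contour lines.

    Scanning outward from the center along +-x and +-y: the first contour
    pixel met that is *not* 8-adjacent to the center (distance d >= 2) clips
    that direction's extent to floor(d / 2) — the midpoint between the two
    contour lines.  Extents are also clipped at the image frame when
    ``shape`` is given.
    """
    if initial_half_width < 1:
        raise ValueError("initial_half_width must be >= 1")
    pts = np.asarray(contour)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour must be an (n, 2) coordinate array")
    h = initial_half_width
    if shape is None:
        shape = (int(pts[:, 0].max()) + h + 1, int(pts[:, 1].max()) + h + 1)
    on_contour = np.zeros(shape, dtype=bool)
    on_contour[pts[:, 0], pts[:, 1]] = True

    def scan(r: int, c: int, dr: int, dc: int) -> int:
        for d in range(2, h + 1):
            rr, cc = r + dr * d, c + dc * d
            if not (0 <= rr < shape[0] and 0 <= cc < shape[1]):
                break
            if on_contour[rr, cc]:
                return d // 2
        return h

    areas = []
    for r, c in pts:
        r, c = int(r), int(c)
        areas.append(
            SearchArea(
                row=r,
                col=c,
                left=min(scan(r, c, 0, -1), c),
                right=min(scan(r, c, 0, 1), shape[1] - 1 - c),
                up=min(scan(r, c, -1, 0), r),
                down=min(scan(r, c, 1, 0), shape[0] - 1 - r),
            )
        )
    return areas


def search_area_mask(areas: Sequence[SearchArea], shape: tuple[int, int]) -> np.ndarray:
    """Union of the actual search areas as a boolean image."""
    mask = np.zeros(shape, dtype=bool)
    for a in areas:
        mask[a.row - a.up : a.row + a.down + 1, a.col - a.left : a.col + a.right + 1] = True
    return mask


# ---------------------------------------------------------------------------
# contour point scoring


def roberts_gradient(img: np.ndarray) -> np.ndarray:
    """Roberts-cross gradient magnitude sqrt(Gx^2 + Gy^2)."""
    return roberts(np.asarray(img, dtype=np.float64))


def score_candidates(
    target: np.ndarray,
    areas: Sequence[SearchArea],
    prior: IntensityPrior,
    w_p: float = 0.7,
    w_g: float = 0.3,
    threshold: float = 0.6,
    sigma: float = 0.5,
) -> ContourPointSet:
    """Score every search-area pixel by intensity prior + Roberts gradient.

    The target is Gaussian-smoothed (sigma, default 0.5) first.  The
    gradient is min–max normalized *per actual search area* — each window is
    scaled by its own gradient range, so a weak edge of a small structure is
    scored against its local contrast rather than against the strongest
    edge in the slice; where windows overlap, a pixel keeps its largest
    normalized value.  ``Y = w_p * P + w_g * grad_norm``; pixels with
    ``Y >= threshold`` are accepted.
    """
    if not np.isclose(w_p + w_g, 1.0):
        raise ValueError(f"w_p + w_g must equal 1, got {w_p + w_g}")
    img = np.asarray(target, dtype=np.float64)
    support = search_area_mask(areas, img.shape)
    if not support.any():
        raise ValueError("empty union of search areas")
    smoothed = ndimage.gaussian_filter(img, sigma=sigma)
    p_img = prior.weight_of(np.clip(smoothed, 0.0, 1.0))
    grad = roberts_gradient(smoothed)
    grad_norm = np.zeros_like(grad)
    for a in areas:
        sl = (
            slice(a.row - a.up, a.row + a.down + 1),
            slice(a.col - a.left, a.col + a.right + 1),
        )
        window = grad[sl]
        lo, hi = window.min(), window.max()
        if hi > lo:
            local = (window - lo) / (hi - lo)
        else:
            local = np.zeros_like(window)
        np.maximum(grad_norm[sl], local, out=grad_norm[sl])
    y_img = w_p * p_img + w_g * grad_norm
    accepted = support & (y_img >= threshold)
    points = np.argwhere(accepted)
    return ContourPointSet(
        points=points,
        scores=y_img[accepted],
        threshold=threshold,
        score_image=np.where(support, y_img, np.nan),
    )


# ---------------------------------------------------------------------------
# IAC acquisition


_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def moore_trace(component: np.ndarray) -> np.ndarray:
    """Ordered outer-boundary pixels of a connected component.

    Moore-neighbor tracing starting from the top-most left-most foreground
    pixel, scanning clockwise from the backtrack pixel.  Termination is by
    state recurrence — the walk stops when the (pixel, backtrack) pair
    repeats — which is equivalent to Jacob's stopping criterion and robust
    on 1-px spurs.
    """
    fg = np.asarray(component).astype(bool)
    coords = np.argwhere(fg)
    if coords.size == 0:
        raise ValueError("empty component")
    start = tuple(int(v) for v in coords[np.lexsort((coords[:, 1], coords[:, 0]))[0]])
    if len(coords) == 1:
        return np.array([start])

    def is_fg(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < fg.shape[0] and 0 <= p[1] < fg.shape[1] and fg[p]

    def step(cur: tuple[int, int], back: tuple[int, int]):
        """Next boundary pixel clockwise from the backtrack, and the
        background pixel scanned immediately before it (new backtrack)."""
        k0 = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        prev = back
        for i in range(1, 9):
            d = _MOORE[(k0 + i) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if is_fg(cand):
                return cand, prev
            prev = cand
        return None, None  # isolated pixel

    state = (start, (start[0], start[1] - 1))  # left of start is background
    seen: dict = {}
    boundary: list[tuple[int, int]] = []
    while state not in seen:
        seen[state] = len(boundary)
        boundary.append(state[0])
        nxt, back = step(*state)
        if nxt is None:
            break
        state = (nxt, back)
    cut = seen.get(state, 0)
    return np.array(boundary[cut:] if cut else boundary)


def _polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as an ordered vertex list."""
    x, y = np.asarray(poly, float).T
    return float(0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def smooth_closed(points: np.ndarray, window: int = 3) -> np.ndarray:
    """Circular moving-average smoothing of a closed polyline.

    Averages out the +-0.5 px quantization of integer boundary walks; the
    window is small relative to any resolvable boundary feature.
    """
    pts = np.asarray(points, dtype=np.float64)
    if window <= 1 or len(pts) <= window:
        return pts
    kernel = np.ones(window) / window
    out = np.empty_like(pts)
    for k in (0, 1):
        padded = np.concatenate([pts[-(window // 2):, k], pts[:, k], pts[: window // 2, k]])
        out[:, k] = np.convolve(padded, kernel, mode="valid")
    return out


def resample_closed(points: np.ndarray, n_out: int) -> np.ndarray:
    """Resample an ordered closed polyline to uniform arc-length spacing."""
    pts = np.asarray(points, dtype=np.float64)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return np.tile(pts[:1], (n_out, 1))
    targets = np.linspace(0.0, total, n_out, endpoint=False)
    out = np.empty((n_out, 2))
    out[:, 0] = np.interp(targets, s, closed[:, 0])
    out[:, 1] = np.interp(targets, s, closed[:, 1])
    return out


def chain_contour(
    points: ContourPointSet | np.ndarray,
    shape: tuple[int, int],
    min_loop_points: int = 4,
    spacing: float = 1.5,
    min_resample: int = 16,
    min_loop_area: float = 6.0,
) -> InitialActiveContour:
    """Chain accepted contour points into ordered closed loops.

    The points are rastered into a contour image; one pass of 3x3
    morphological closing bridges 1-px gaps; holes are filled so each
    component has a well-defined outer boundary; every component is traced
    with Moore-neighbor following; loops shorter than ``min_loop_points``
    are dropped; surviving loops are resampled to uniform arc length with
    ``max(min_resample, round(perimeter / spacing))`` points.
    """
    pts = points.points if isinstance(points, ContourPointSet) else np.asarray(points)
    if len(pts) < 4:
        raise ValueError(
            "need at least 4 accepted contour points; consider relaxing the Y threshold"
        )
    img = np.zeros(shape, dtype=bool)
    img[pts[:, 0], pts[:, 1]] = True
    closed = ndimage.binary_closing(img, structure=_EIGHT, border_value=0)
    filled = ndimage.binary_fill_holes(closed)
    labeled, n = ndimage.label(filled, structure=_EIGHT)

    def trace_solid(region: np.ndarray) -> np.ndarray:
        """Outline of a solid (satellite-scale) blob."""
        if region.sum() < 60:
            # accepted points often cover only an arc of a small structure's
            # rim; the convex hull is the right completion at a scale where
            # concavities are not resolvable anyway
            from skimage.morphology import convex_hull_image

            region = convex_hull_image(region)
        eroded = ndimage.binary_erosion(region, structure=_EIGHT, border_value=0)
        if eroded.sum() >= min_loop_points:
            trace = moore_trace(eroded)
            if _polygon_area(trace) >= min_loop_area:
                return trace
        # erosion collapsed the blob: keep the uneroded outline rather than
        # losing the structure
        return moore_trace(region)

    traces: list[np.ndarray] = []
    for k in range(1, n + 1):
        region = labeled == k
        band = closed & region
        interior = region & ~band
        # the accepted band straddles the true edge, so tracing the filled
        # region follows its outer margin (~1 px outside).  For an annular
        # band the unbiased contour is its centerline: trace the filled
        # skeleton.  Solid blobs are handled by trace_solid.
        if interior.sum() > band.sum():
            from skimage.measure import find_contours
            from skimage.morphology import skeletonize

            # subpixel medial line of the annular band: the zero level of
            # (distance from background) - (distance from the enclosed
            # interior) runs equidistant between the band's two margins
            d_out = ndimage.distance_transform_edt(region)
            d_in = ndimage.distance_transform_edt(~interior)
            phi = np.where(region, d_out - d_in, -band.shape[0] * 1.0)
            medials = [c for c in find_contours(phi, 0.0) if len(c) >= min_loop_points]
            if medials:
                traces.append(max(medials, key=len))
            # a small structure merged onto the band sticks out as a spur
            # that the medial centerline amputates; recover such residual
            # chunks as solid blobs of their own
            core = ndimage.binary_fill_holes(skeletonize(band))
            residual = region & ~ndimage.binary_dilation(
                core, structure=_EIGHT, border_value=0
            )
            res_lab, n_res = ndimage.label(residual, structure=_EIGHT)
            for j in range(1, n_res + 1):
                chunk = res_lab == j
                if chunk.sum() >= 2 * min_loop_points:
                    traces.append(trace_solid(chunk))
        else:
            traces.append(trace_solid(region))

    # leftover pass: accepted points not claimed by any traced outline are
    # clustered at a slightly coarser scale — a small structure whose rim was
    # only sparsely accepted still yields a blob worth keeping
    claimed = np.zeros(shape, dtype=bool)
    for trace in traces:
        tr = np.clip(np.round(trace).astype(int), 0, np.array(shape) - 1)
        claimed[tr[:, 0], tr[:, 1]] = True
    claimed = ndimage.binary_dilation(claimed, iterations=2, structure=_EIGHT)
    leftover = img & ~claimed & ~filled
    if leftover.any():
        r2 = np.array([[0, 1, 1, 1, 0], [1, 1, 1, 1, 1], [1, 1, 1, 1, 1],
                       [1, 1, 1, 1, 1], [0, 1, 1, 1, 0]], dtype=bool)
        clustered = ndimage.binary_fill_holes(
            ndimage.binary_closing(leftover, structure=r2, border_value=0)
        )
        left_lab, n_left = ndimage.label(clustered, structure=_EIGHT)
        for j in range(1, n_left + 1):
            chunk = left_lab == j
            if chunk.sum() >= 2 * min_loop_points:
                traces.append(trace_solid(chunk))

    loops: list[np.ndarray] = []
    for trace in traces:
        if len(trace) < min_loop_points or _polygon_area(trace) < min_loop_area:
            continue
        closed_trace = np.vstack([trace, trace[:1]])
        perimeter = float(np.linalg.norm(np.diff(closed_trace, axis=0), axis=1).sum())
        n_out = max(min_resample, int(round(perimeter / spacing)))
        loops.append(smooth_closed(resample_closed(trace, n_out)))
    if not loops:
        raise ValueError(
            "no chained loop has enough points; consider relaxing the Y threshold"
        )
    return InitialActiveContour(loops=loops)
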