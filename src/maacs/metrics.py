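"""Segmentation evaluation: Dice, Recall, Precision and Hausdorff distance.

Overlap metrics are set-volume ratios between the reference (T) and
segmented (F) pixel sets of the target class:

    Dice = 2|T∩F| / (|T|+|F|),  Recall = |T∩F|/|T|,  Precision = |T∩F|/|F|.

The Hausdorff distance is the max of the two directed farthest-nearest
Euclidean distances.  By default it is computed between *boundary* pixel
sets (the standard surface-distance reading); the full-pixel-set variant is
available behind a flag.  Distances are in pixel units unless a physical
spacing is given.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial import cKDTree

from .template import boundary_mask


@dataclass(frozen=True)
class MetricsReport:
    dice: float
    recall: float
    precision: float
    hausdorff: float

    def to_dict(self) -> dict:
        return asdict(self)


def overlap_metrics(
    reference: np.ndarray, segmented: np.ndarray, target_class: int = 1
) -> tuple[float, float, float]:
    """(dice, recall, precision) for one class.

    An empty segmentation has precision (and hence dice) 0; an empty
    reference is an error — the class must exist to be evaluated.
    """
    ref = np.asarray(reference)
    seg = np.asarray(segmented)
    if ref.shape != seg.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {seg.shape}")
    t = ref == target_class
    f = seg == target_class
    vt, vf = int(t.sum()), int(f.sum())
    if vt == 0:
        raise ValueError(f"reference contains no pixels of class {target_class}")
    inter = int((t & f).sum())
    recall = inter / vt
    precision = inter / vf if vf else 0.0
    dice = 2 * inter / (vt + vf)
    return dice, recall, precision


def hausdorff(
    reference: np.ndarray,
    segmented: np.ndarray,
    target_class: int = 1,
    boundary: bool = True,
    spacing: float = 1.0,
) -> float:
    """Symmetric Hausdorff distance between the two class masks.

    With ``boundary=True`` (default) the distance is between boundary pixel
    sets; otherwise between the full pixel sets.
    """
    ref = np.asarray(reference) == target_class
    seg = np.asarray(segmented) == target_class
    if not ref.any() or not seg.any():
        raise ValueError("both masks must be nonempty for the Hausdorff distance")
    if boundary:
        ref, seg = boundary_mask(ref), boundary_mask(seg)
    a = np.argwhere(ref).astype(float)
    b = np.argwhere(seg).astype(float)
    d_ab = cKDTree(b).query(a)[0].max()
    d_ba = cKDTree(a).query(b)[0].max()
    return float(max(d_ab, d_ba)) * float(spacing)


def metrics_report(
    reference: np.ndarray,
    segmented: np.ndarray,
    target_class: int = 1,
    spacing: float = 1.0,
) -> MetricsReport:
    dice, recall, precision = overlap_metrics(reference, segmented, target_class)
    if (np.asarray(segmented) == target_class).any():
        hd = hausdorff(reference, segmented, target_class, spacing=spacing)
    else:
        hd = float("inf")
    return MetricsReport(dice=dice, recall=recall, precision=precision, hausdorff=hd)


def evaluate_volume(
    reference: list[np.ndarray] | np.ndarray,
    segmented: list[np.ndarray] | np.ndarray,
    target_class: int = 1,
    spacing: float = 1.0,
) -> dict:
    """Slice-wise volume evaluation.

    Overlap metrics are pooled over all slices; the Hausdorff distance is
    computed per slice (where both masks are nonempty) and reported as the
    max over slices together with the per-slice table.
    """
    refs = [np.asarray(s) for s in reference]
    segs = [np.asarray(s) for s in segmented]
    if len(refs) != len(segs):
        raise ValueError("slice count mismatch")
    t = np.concatenate([(r == target_class).ravel() for r in refs])
    f = np.concatenate([(s == target_class).ravel() for s in segs])
    vt, vf, inter = int(t.sum()), int(f.sum()), int((t & f).sum())
    if vt == 0:
        raise ValueError(f"reference contains no pixels of class {target_class}")
    per_slice = []
    for k, (r, s) in enumerate(zip(refs, segs)):
        if (r == target_class).any() and (s == target_class).any():
            per_slice.append((k, hausdorff(r, s, target_class, spacing=spacing)))
    return {
        "dice": 2 * inter / (vt + vf),
        "recall": inter / vt,
        "precision": inter / vf if vf else 0.0,
        "hausdorff_max": max((h for _, h in per_slice), default=float("nan")),
        "hausdorff_per_slice": per_slice,
    }
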