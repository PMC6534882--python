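"""Label fusion by local weighted voting.

Each warped atlas votes for its label at every pixel with a weight equal to
the NCC between the 3x3 (configurable) patches of the target and the warped
atlas intensity centered at that pixel.  Negative patch NCCs are clamped to
zero (a negative correlation is no evidence for the vote), weights are
normalized across atlases to sum to one, and the fused foreground
probability is thresholded at 0.5 to produce the initial template.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class FusionWeights:
    """Per-atlas, per-pixel normalized voting weights (shape L x H x W)."""

    weights: np.ndarray
    patch_size: int = 3

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 3:
            raise ValueError("weights must have shape (n_atlases, H, W)")
        if self.weights.min() < 0:
            raise ValueError("fusion weights must be nonnegative")


@dataclass
class InitialTemplate:
    """Fused foreground probability and its binarized template."""

    prob: np.ndarray
    binary: np.ndarray
    target_class: int
    label_map: np.ndarray | None = None
    threshold: float = 0.5


def _box_sums(a: np.ndarray, radius: int) -> np.ndarray:
    """Sums over the (2r+1)^2 window clipped at the image border."""
    h, w = a.shape
    ii = np.zeros((h + 1, w + 1), dtype=np.float64)
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=ii[1:, 1:])
    r = np.arange(h)
    c = np.arange(w)
    r0 = np.clip(r - radius, 0, h)
    r1 = np.clip(r + radius + 1, 0, h)
    c0 = np.clip(c - radius, 0, w)
    c1 = np.clip(c + radius + 1, 0, w)
    return (
        ii[np.ix_(r1, c1)] - ii[np.ix_(r0, c1)] - ii[np.ix_(r1, c0)] + ii[np.ix_(r0, c0)]
    )


def patch_ncc(target: np.ndarray, other: np.ndarray, patch_size: int = 3) -> np.ndarray:
    """Per-pixel NCC of local patches (clipped at borders).

    Zero-variance patches in either image give NCC 0 at that pixel.
    """
    if patch_size < 3 or patch_size % 2 == 0:
        raise ValueError("patch_size must be an odd integer >= 3")
    t = np.asarray(target, dtype=np.float64)
    f = np.asarray(other, dtype=np.float64)
    if t.shape != f.shape:
        raise ValueError(f"shape mismatch {t.shape} vs {f.shape}")
    r = patch_size // 2
    ones = np.ones_like(t)
    n = _box_sums(ones, r)
    st, sf = _box_sums(t, r), _box_sums(f, r)
    stt, sff = _box_sums(t * t, r), _box_sums(f * f, r)
    stf = _box_sums(t * f, r)
    cov = stf - st * sf / n
    var_t = stt - st * st / n
    var_f = sff - sf * sf / n
    var_t = np.clip(var_t, 0.0, None)
    var_f = np.clip(var_f, 0.0, None)
    denom = np.sqrt(var_t * var_f)
    out = np.zeros_like(t)
    # a patch whose variance is at cancellation-noise level is constant
    good = (var_t > 1e-10) & (var_f > 1e-10)
    out[good] = cov[good] / denom[good]
    return np.clip(out, -1.0, 1.0)


def local_weights(
    target: np.ndarray,
    warped_intensities: Sequence[np.ndarray],
    patch_size: int = 3,
) -> FusionWeights:
    """Local-patch-NCC voting weights, clamped at 0 and normalized.

    At pixels where every raw weight is zero the vote falls back to uniform
    weights (the pixel must still be labeled).
    """
    if len(warped_intensities) == 0:
        raise ValueError("need at least one warped atlas intensity")
    raw = np.stack(
        [
            np.clip(patch_ncc(target, w, patch_size), 0.0, None)
            for w in warped_intensities
        ]
    )
    total = raw.sum(axis=0)
    dead = total <= 0.0
    raw[:, dead] = 1.0
    total = raw.sum(axis=0)
    return FusionWeights(weights=raw / total, patch_size=patch_size)


def fuse(
    warped_labels: Sequence[np.ndarray],
    weights: FusionWeights,
    target_class: int = 1,
    classes: Sequence[int] | None = None,
    threshold: float = 0.5,
) -> InitialTemplate:
    """Weighted-vote label fusion with argmax labeling and binarization.

    The fused foreground probability for ``target_class`` is the normalized
    weight mass of atlases voting for that class; pixels with probability
    >= ``threshold`` (ties included — the foreground-biased rule) form the
    binary initial template.  ``label_map`` is the per-pixel argmax class
    over ``classes`` (defaults to every label observed).
    """
    if len(warped_labels) == 0:
        raise ValueError("need at least one warped label image")
    labels = np.stack([np.asarray(l) for l in warped_labels])
    if labels.shape != weights.weights.shape:
        raise ValueError(
            f"labels shape {labels.shape} incompatible with weights "
            f"{weights.weights.shape}"
        )
    if classes is None:
        classes = np.unique(labels)
    classes = np.asarray(classes)
    if classes.size == 0:
        raise ValueError("empty class set")
    # accumulate sequentially over atlases (index order) so the result is
    # bit-identical to a naive per-pixel loop
    scores = np.zeros((classes.size,) + labels.shape[1:], dtype=np.float64)
    for j, c in enumerate(classes):
        for i in range(labels.shape[0]):
            scores[j] += np.where(labels[i] == c, weights.weights[i], 0.0)
    label_map = classes[np.argmax(scores, axis=0)].astype(np.int32)
    if target_class in classes:
        prob = scores[int(np.flatnonzero(classes == target_class)[0])]
    else:
        prob = np.zeros(labels.shape[1:], dtype=np.float64)
    binary = (prob >= threshold).astype(np.int32)
    return InitialTemplate(
        prob=prob,
        binary=binary,
        target_class=int(target_class),
        label_map=label_map,
        threshold=threshold,
    )
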