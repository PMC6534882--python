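"""End-to-end segmentation pipeline as a scikit-learn style estimator.

``MultiAtlasSegmenter`` treats the atlas set as training data (``fit``
stores the atlases and builds the contour-intensity prior) and labels new
target slices in ``predict``: registration → local weighted-voting fusion →
template optimization → snake evolution.  Two named parameter profiles
bundle the published settings for T1 white-matter (``ibsr``) and thalamus
(``mrbrains``) segmentation.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import imageio
from .fusion import InitialTemplate, fuse, local_weights
from .imageio import Atlas, RoiBox, compute_roi, normalize_intensity
from .metrics import MetricsReport, metrics_report
from .registration import RegistrationResult, SearchConfig, register_all
from .snake import SnakeParams, SnakeState, build_potential, contour_to_mask, evolve
from .template import (
    ContourPointSet,
    InitialActiveContour,
    IntensityPrior,
    build_intensity_prior,
    chain_contour,
    extract_template_contour,
    score_candidates,
    set_search_areas,
)

#: Published parameter profiles: template-optimization (search half-width,
#: score weights w_p/w_g, acceptance threshold Y) and snake weights.
PROFILES: dict[str, dict[str, float]] = {
    "ibsr": dict(half_width=8, w_p=0.7, w_g=0.3, y_threshold=0.6,
                 alpha=30.0, beta=70.0, gamma=70.0),
    "mrbrains": dict(half_width=8, w_p=0.6, w_g=0.4, y_threshold=0.6,
                     alpha=60.0, beta=100.0, gamma=100.0),
}


@dataclass
class SegmentationResult:
    """Final mask plus every intermediate stage artifact."""

    mask: np.ndarray
    registrations: list[RegistrationResult]
    template: InitialTemplate
    contour_points: ContourPointSet | None
    iac: InitialActiveContour | None
    snake_state: SnakeState | None
    prior: IntensityPrior
    roi: RoiBox
    metrics: MetricsReport | None = None
    timings: dict[str, float] = field(default_factory=dict)
    fallbacks: list[str] = field(default_factory=list)


class MultiAtlasSegmenter(BaseEstimator):
    """Multi-atlas active-contour segmentation of 2-D gray slices.

    Parameters
    ----------
    profile : {"ibsr", "mrbrains"}
        Named defaults for the template-optimization and snake parameters;
        any explicit keyword overrides its profile value.
    target_class : int
        Label of the structure to segment.
    ncc_threshold : float
        Atlas selection cut on post-registration NCC (default 0.87); when no
        atlas passes, the best ``fallback_k`` are used instead.
    patch_size : int
        Side of the local square patch for voting weights (default 3).
    sigma : float
        Gaussian smoothing used for scoring and the snake potential.

    Attributes
    ----------
    atlases_ : list of Atlas (normalized intensities)
    prior_ : IntensityPrior built from the atlas contour intensities
    params_ : dict of resolved stage parameters
    """

    def __init__(
        self,
        profile: str = "ibsr",
        target_class: int = 1,
        ncc_threshold: float = 0.87,
        fallback_k: int = 3,
        patch_size: int = 3,
        half_width: int | None = None,
        w_p: float | None = None,
        w_g: float | None = None,
        y_threshold: float | None = None,
        alpha: float | None = None,
        beta: float | None = None,
        gamma: float | None = None,
        sigma: float = 0.5,
        n_bins: int = 20,
        binarization_threshold: float = 0.5,
        step_size: float = 0.01,
        max_iters: int = 500,
        tol: float = 0.05,
        search_config: SearchConfig | None = None,
    ) -> None:
        self.profile = profile
        self.target_class = target_class
        self.ncc_threshold = ncc_threshold
        self.fallback_k = fallback_k
        self.patch_size = patch_size
        self.half_width = half_width
        self.w_p = w_p
        self.w_g = w_g
        self.y_threshold = y_threshold
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.sigma = sigma
        self.n_bins = n_bins
        self.binarization_threshold = binarization_threshold
        self.step_size = step_size
        self.max_iters = max_iters
        self.tol = tol
        self.search_config = search_config

    # -- fitting ------------------------------------------------------------

    def fit(self, X: Sequence[np.ndarray], y: Sequence[np.ndarray]):
        """Store the atlas set and build the contour-intensity prior.

        ``X`` are atlas intensity slices, ``y`` the matching label slices.
        Intensities are min-max normalized over their tissue ROI.
        """
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; choose from {list(PROFILES)}")
        if len(X) == 0 or len(X) != len(y):
            raise ValueError("need equally many atlas intensities and labels")
        prof = PROFILES[self.profile]
        self.params_ = {
            k: (getattr(self, k) if getattr(self, k) is not None else prof[k])
            for k in prof
        }
        self.atlases_ = []
        for i, (img, lbl) in enumerate(zip(X, y)):
            lbl = imageio.as_label(lbl)
            roi = compute_roi(lbl > 0) if (lbl > 0).any() else None
            norm = normalize_intensity(np.asarray(img, dtype=float), roi)
            self.atlases_.append(Atlas(intensity=norm, label=lbl, id=f"atlas_{i:02d}"))
        self.prior_ = build_intensity_prior(
            self.atlases_, self.target_class, n_bins=self.n_bins, sigma=self.sigma
        )
        self.classes_ = np.unique(np.concatenate([a.label.ravel() for a in self.atlases_]))
        return self

    def fit_from_atlases(self, atlases: Sequence[Atlas]):
        """Convenience: fit from already-paired Atlas objects."""
        return self.fit([a.intensity for a in atlases], [a.label for a in atlases])

    # -- prediction ---------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Segment a target slice (2-D array) or list of slices.

        Returns a label image with ``target_class`` on the segmented
        structure and 0 elsewhere (a list of them for list input).
        """
        self._check_fitted()
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return self.segment(X).mask * self.target_class
        return [self.segment(np.asarray(x)).mask * self.target_class for x in X]

    def segment(
        self, target: np.ndarray, reference: np.ndarray | None = None
    ) -> SegmentationResult:
        """Run the full pipeline on one slice, keeping stage artifacts."""
        self._check_fitted()
        p = self.params_
        timings: dict[str, float] = {}
        fallbacks: list[str] = []

        target = np.asarray(target, dtype=np.float64)
        roi = _tissue_roi(target)
        target_n = normalize_intensity(target, roi)

        t0 = time.perf_counter()
        regs = register_all(
            target_n,
            self.atlases_,
            ncc_threshold=self.ncc_threshold,
            fallback_k=self.fallback_k,
            config=self.search_config,
            roi=roi,
        )
        timings["registration"] = time.perf_counter() - t0
        if any(r.selected_by_fallback for r in regs):
            fallbacks.append("atlas_selection_fallback")

        t0 = time.perf_counter()
        weights = local_weights(
            target_n, [r.warped_intensity for r in regs], self.patch_size
        )
        template = fuse(
            [r.warped_label for r in regs],
            weights,
            target_class=self.target_class,
            threshold=self.binarization_threshold,
        )
        timings["fusion"] = time.perf_counter() - t0

        contour_points: ContourPointSet | None = None
        iac: InitialActiveContour | None = None
        state: SnakeState | None = None
        mask = template.binary.astype(bool)
        t0 = time.perf_counter()
        try:
            contour = extract_template_contour(template)
            areas = set_search_areas(
                contour, int(p["half_width"]), shape=target_n.shape
            )
            contour_points = score_candidates(
                target_n,
                areas,
                self.prior_,
                w_p=p["w_p"],
                w_g=p["w_g"],
                threshold=p["y_threshold"],
                sigma=self.sigma,
            )
            iac = chain_contour(contour_points, target_n.shape)
        except ValueError as exc:
            warnings.warn(f"template optimization fell back to the fused template: {exc}")
            fallbacks.append("template_optimization_fallback")
        timings["template_optimization"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        if iac is not None:
            field_ = build_potential(target_n, self.prior_, sigma=self.sigma)
            state = evolve(
                iac,
                field_,
                SnakeParams(
                    alpha=p["alpha"],
                    beta=p["beta"],
                    gamma=p["gamma"],
                    step_size=self.step_size,
                    max_iters=self.max_iters,
                    tol=self.tol,
                ),
            )
            mask = contour_to_mask(state, target_n.shape)
        timings["snake"] = time.perf_counter() - t0

        report = None
        if reference is not None:
            report = metrics_report(
                imageio.as_label(reference),
                mask.astype(np.int32) * self.target_class,
                self.target_class,
            )
        return SegmentationResult(
            mask=mask.astype(np.int32),
            registrations=regs,
            template=template,
            contour_points=contour_points,
            iac=iac,
            snake_state=state,
            prior=self.prior_,
            roi=roi,
            metrics=report,
            timings=timings,
            fallbacks=fallbacks,
        )

    def score(self, X, y) -> float:
        """Mean Dice over (target, reference) slices."""
        self._check_fitted()
        dices = []
        for img, ref in zip([X] if isinstance(X, np.ndarray) and X.ndim == 2 else X,
                            [y] if isinstance(y, np.ndarray) and y.ndim == 2 else y):
            res = self.segment(np.asarray(img), reference=ref)
            dices.append(res.metrics.dice)
        return float(np.mean(dices))

    def _check_fitted(self) -> None:
        if not hasattr(self, "atlases_"):
            raise RuntimeError("this MultiAtlasSegmenter instance is not fitted yet")


def _tissue_roi(target: np.ndarray) -> RoiBox:
    """Bounding box of tissue (above-background) pixels of the target."""
    from skimage.filters import threshold_otsu

    arr = np.asarray(target, dtype=float)
    try:
        mask = arr > threshold_otsu(arr)
    except ValueError:
        mask = arr > arr.mean()
    if not mask.any():
        return RoiBox(0, arr.shape[0], 0, arr.shape[1])
    return compute_roi(mask)


def segment(
    target: np.ndarray,
    atlases: Sequence[Atlas],
    profile: str = "ibsr",
    target_class: int = 1,
    reference: np.ndarray | None = None,
    **params,
) -> SegmentationResult:
    """Functional one-shot interface over :class:`MultiAtlasSegmenter`."""
    est = MultiAtlasSegmenter(profile=profile, target_class=target_class, **params)
    est.fit_from_atlases(list(atlases))
    return est.segment(target, reference=reference)


def leave_one_out(
    atlases: Sequence[Atlas],
    profile: str = "ibsr",
    target_class: int = 1,
    **params,
) -> list[dict]:
    """Leave-one-out cross-validation over an atlas set.

    Each atlas in turn serves as the target (its label as the reference)
    while the remaining atlases form the training set; returns one metrics
    row per held-out subject.
    """
    if len(atlases) < 2:
        raise ValueError("leave-one-out needs at least two atlases")
    rows = []
    for i, held in enumerate(atlases):
        rest = list(atlases[:i]) + list(atlases[i + 1 :])
        res = segment(held.intensity, rest, profile=profile,
                      target_class=target_class, reference=held.label, **params)
        rows.append({"target_id": held.id, **res.metrics.to_dict()})
    return rows


def save_artifacts(result: SegmentationResult, out_dir: str | Path) -> None:
    """Persist every stage artifact plus a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    imageio.save_volume(out / "final_mask.txt", [result.mask], label=True)
    imageio.save_volume(out / "initial_template.txt", [result.template.binary], label=True)
    imageio.save_volume(out / "fused_prob.txt", [result.template.prob])
    for r in result.registrations:
        imageio.save_volume(out / f"warped_label_{r.atlas_id}.txt", [r.warped_label],
                            label=True)
    if result.iac is not None:
        (out / "iac.json").write_text(result.iac.to_json())
    if result.snake_state is not None:
        (out / "final_contour.json").write_text(
            json.dumps([l.tolist() for l in result.snake_state.loops])
        )
    if result.contour_points is not None:
        pts_img = np.zeros_like(result.mask)
        pts_img[result.contour_points.points[:, 0], result.contour_points.points[:, 1]] = 1
        imageio.save_volume(out / "template_contour_points.txt", [pts_img], label=True)
    (out / "prior.json").write_text(result.prior.to_json())
    manifest = {
        "roi": json.loads(result.roi.to_json()),
        "registrations": [
            {"atlas_id": r.atlas_id, "ncc": r.ncc, "converged": r.converged,
             "fallback": r.selected_by_fallback,
             "params": json.loads(r.params.to_json())}
            for r in result.registrations
        ],
        "timings": result.timings,
        "fallbacks": result.fallbacks,
        "metrics": dataclasses.asdict(result.metrics) if result.metrics else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
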