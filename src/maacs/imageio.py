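"""Image and label I/O, ROI cropping and intensity normalization.

Working representations are plain numpy arrays: a gray image is a 2-D float
array with values in [0, 1] after :func:`normalize_intensity`; a label image
is a 2-D integer array of the same shape (0 = background).  Volumes are
handled slice-wise along the last (axial) axis.

Two on-disk formats are supported: NIfTI-1 (``.nii`` / ``.nii.gz``, via
nibabel) for real data, and a plain-text raster (``.txt``) for small test
fixtures.  The text format stores floats at full precision so write→read
round trips are bit-exact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

_TEXT_SUFFIX = ".txt"
_NIFTI_SUFFIXES = (".nii", ".nii.gz")


@dataclass(frozen=True)
class RoiBox:
    """Half-open bounding box ``[row_min, row_max) x [col_min, col_max)``.

    Coordinates are 0-based with the origin at the top-left pixel.
    """

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_min < self.row_max and 0 <= self.col_min < self.col_max):
            raise ValueError(f"degenerate ROI box {self}")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_min, self.row_max), slice(self.col_min, self.col_max)

    @property
    def shape(self) -> tuple[int, int]:
        return self.row_max - self.row_min, self.col_max - self.col_min

    def to_json(self) -> str:
        return json.dumps(
            {
                "row_min": self.row_min,
                "row_max": self.row_max,
                "col_min": self.col_min,
                "col_max": self.col_max,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RoiBox":
        return cls(**json.loads(text))


@dataclass
class Atlas:
    """An intensity image paired with its expert label image."""

    intensity: np.ndarray
    label: np.ndarray
    id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = as_gray(self.intensity, normalized=False)
        self.label = as_label(self.label)
        if self.intensity.shape != self.label.shape:
            raise ValueError(
                f"atlas {self.id!r}: intensity shape {self.intensity.shape} "
                f"!= label shape {self.label.shape}"
            )


def as_gray(img: np.ndarray, *, normalized: bool = True) -> np.ndarray:
    """Validate and return a 2-D float64 gray image."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or arr.size < 4:
        raise ValueError(f"expected a 2-D image with >= 4 pixels, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if normalized and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError("image values outside [0, 1]; call normalize_intensity first")
    return arr


def as_label(lbl: np.ndarray) -> np.ndarray:
    """Validate and return a 2-D non-negative integer label image."""
    arr = np.asarray(lbl)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D label image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("label image has non-integer values")
        arr = np.round(arr).astype(np.int32)
    if arr.min() < 0:
        raise ValueError("label image has negative values")
    return arr.astype(np.int32, copy=False)


# ---------------------------------------------------------------------------
# fixture text format


def write_gray_text(path: str | Path, img: np.ndarray) -> None:
    """Write a gray image as a plain-text raster (bit-exact round trip)."""
    arr = np.atleast_2d(np.asarray(img, dtype=np.float64))
    np.savetxt(path, arr, fmt="%.17g", header="maacs gray raster")


def read_gray_text(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, ndmin=2, dtype=np.float64)


def write_label_text(path: str | Path, lbl: np.ndarray) -> None:
    np.savetxt(path, as_label(lbl), fmt="%d", header="maacs label raster")


def read_label_text(path: str | Path) -> np.ndarray:
    return as_label(np.loadtxt(path, ndmin=2, dtype=np.int64))


# ---------------------------------------------------------------------------
# volumes


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def load_volume(
    path: str | Path, slice_index: int | str = "all", *, label: bool = False
) -> list[np.ndarray]:
    """Load a volume (or single-slice fixture) as a list of 2-D slices.

    NIfTI volumes are split along the last axis in axial order.  Intensities
    are returned as stored — *not* yet normalized.  With ``label=True`` the
    data are validated and cast as integer labels.

    Parameters
    ----------
    slice_index
        ``"all"`` (default) returns every slice; an integer returns a
        single-element list with that slice.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    if _is_nifti(path):
        import nibabel as nib

        try:
            data = np.asanyarray(nib.load(str(path)).dataobj)
        except Exception as exc:  # pragma: no cover - nibabel error surface
            raise ValueError(f"unreadable NIfTI file {path}: {exc}") from exc
        if data.ndim == 2:
            data = data[..., None]
        if data.ndim != 3:
            raise ValueError(f"expected a 2-D/3-D volume in {path}, got ndim={data.ndim}")
        slices = [np.asarray(data[..., k]) for k in range(data.shape[-1])]
    elif path.suffix == _TEXT_SUFFIX:
        slices = [read_label_text(path) if label else read_gray_text(path)]
    else:
        raise ValueError(f"unsupported image format: {path}")
    if label:
        slices = [as_label(s) for s in slices]
    else:
        slices = [np.asarray(s, dtype=np.float64) for s in slices]
    if slice_index == "all":
        return slices
    idx = int(slice_index)
    if not 0 <= idx < len(slices):
        raise IndexError(f"slice_index {idx} out of range for {len(slices)}-slice volume")
    return [slices[idx]]


def save_volume(path: str | Path, slices: Sequence[np.ndarray], *, label: bool = False) -> None:
    """Write slices as a NIfTI volume or (single slice) text fixture."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        import nibabel as nib

        vol = np.stack([np.asarray(s) for s in slices], axis=-1)
        if label:
            vol = vol.astype(np.int16)
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
    elif path.suffix == _TEXT_SUFFIX:
        if len(slices) != 1:
            raise ValueError("text fixture format stores exactly one slice per file")
        (write_label_text if label else write_gray_text)(path, slices[0])
    else:
        raise ValueError(f"unsupported image format: {path}")


# ---------------------------------------------------------------------------
# normalization and ROI


def normalize_intensity(img: np.ndarray, roi: RoiBox | None = None) -> np.ndarray:
    """Min–max rescale intensities to [0, 1].

    The scaling support is the ROI box when given (so background pixels do
    not dominate the range), but the whole image is rescaled with that
    mapping and clipped to [0, 1].  A constant image maps to all zeros with
    a warning.  Idempotent: normalizing twice equals normalizing once.
    """
    arr = as_gray(img, normalized=False)
    support = arr[roi.slices] if roi is not None else arr
    lo, hi = float(support.min()), float(support.max())
    if hi <= lo:
        warnings.warn("constant image: normalized to all zeros", stacklevel=2)
        return np.zeros_like(arr)
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


def compute_roi(mask: np.ndarray) -> RoiBox:
    """Tight half-open bounding box of the nonzero pixels of a mask."""
    arr = np.asarray(mask)
    rows = np.flatnonzero(arr.any(axis=1))
    cols = np.flatnonzero(arr.any(axis=0))
    if rows.size == 0:
        raise ValueError("cannot compute ROI of an empty mask")
    return RoiBox(int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)


def crop(img: np.ndarray, roi: RoiBox) -> np.ndarray:
    return np.asarray(img)[roi.slices]
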