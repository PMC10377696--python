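"""Morphological tumor segmentation and TP/FP/FN validation statistics.

Back-projection images are binarized (fixed fraction of the maximum, or
Otsu), cleaned with cycles of erosion/dilation, and compared against the
geometric source truth mask. Scores follow the pixel-count definitions

    accuracy    = 100 * TP / (TP + FP)
    sensitivity = 100 * TP / (TP + FN)

so accuracy measures the precision of the segmented region and sensitivity
the fraction of true source pixels recovered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, erosion

from .errors import DegenerateImageError, GeometryError, UndefinedScoreError
from .geometry import SourceModel
from .grid import Image3D, VoxelGrid

# overlay category codes
BACKGROUND, TP, FP, FN = 0, 1, 2, 3


@dataclass(frozen=True)
class MorphParams:
    """Binarization threshold plus the erosion/dilation schedule.

    ``binarize_threshold`` is a fraction of the image maximum in (0, 1), or
    the string ``"otsu"``. ``operation_order`` is applied in sequence,
    ``n_cycles`` times, with the chosen structuring element.
    """

    n_cycles: int = 2
    operation_order: Sequence[str] = ("erode", "dilate")
    structuring_element: str = "square"
    selem_radius: int = 1
    binarize_threshold: Union[float, str] = 0.5

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.selem_radius < 1:
            raise ValueError("structuring element radius must be >= 1")
        if self.structuring_element not in ("cross", "square", "disk"):
            raise ValueError(f"unknown structuring element {self.structuring_element!r}")
        for op in self.operation_order:
            if op not in ("erode", "dilate"):
                raise ValueError(f"unknown operation {op!r}")
        if not isinstance(self.binarize_threshold, str):
            if not 0.0 < self.binarize_threshold < 1.0:
                raise ValueError("threshold fraction must be in (0, 1)")
        elif self.binarize_threshold != "otsu":
            raise ValueError("string threshold must be 'otsu'")

    def footprint(self) -> np.ndarray:
        r = self.selem_radius
        if self.structuring_element == "square":
            return np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
        if self.structuring_element == "disk":
            return disk(r).astype(bool)
        # cross: plus-shaped connectivity-1 element
        fp = np.zeros((2 * r + 1, 2 * r + 1), dtype=bool)
        fp[r, :] = True
        fp[:, r] = True
        return fp


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class SegmentationScore:
    """Accuracy and sensitivity in percent."""

    accuracy: float
    sensitivity: float


def binarize(image: Union[Image3D, np.ndarray],
             params: Optional[MorphParams] = None) -> np.ndarray:
    """Binary mask of pixels at or above the threshold.

    Fraction thresholds are relative to the image maximum; ``"otsu"`` uses
    Otsu's inter-class-variance criterion. All-zero input is degenerate.
    """
    params = params or MorphParams()
    arr = image.intensity if isinstance(image, Image3D) else np.asarray(image, float)
    mx = arr.max()
    if mx <= 0:
        raise DegenerateImageError("cannot binarize an all-zero image")
    if params.binarize_threshold == "otsu":
        thr = threshold_otsu(arr)
    else:
        thr = params.binarize_threshold * mx
    return arr >= thr


def morph_filter(mask: np.ndarray, params: Optional[MorphParams] = None) -> np.ndarray:
    """Apply the configured erode/dilate sequence ``n_cycles`` times."""
    params = params or MorphParams()
    mask = np.asarray(mask).astype(bool)
    fp = params.footprint()
    if mask.ndim == 3:
        r = params.selem_radius
        fp3 = np.zeros((2 * r + 1,) * 3, dtype=bool)
        fp3[r] = fp  # prism footprint for the 3-D mode
        fp3[:, r, r] = True
        fp = fp3
    if any(f > s for f, s in zip(fp.shape, mask.shape)):
        raise GeometryError("structuring element larger than the image")
    out = mask
    for _ in range(params.n_cycles):
        for op in params.operation_order:
            if op == "erode":
                out = erosion(out, fp)
            else:
                out = dilation(out, fp)
    return out.astype(bool)


def confusion_counts(predicted: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel counts: tp = |pred & truth|, fp = |pred & ~truth|,
    fn = |~pred & truth|."""
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch {predicted.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int(np.sum(predicted & truth)),
        fp=int(np.sum(predicted & ~truth)),
        fn=int(np.sum(~predicted & truth)),
    )


def score(counts: ConfusionCounts) -> SegmentationScore:
    """Accuracy/sensitivity percentages; undefined for an empty prediction
    or an empty truth."""
    if counts.tp + counts.fp == 0:
        raise UndefinedScoreError("empty prediction: accuracy undefined")
    if counts.tp + counts.fn == 0:
        raise UndefinedScoreError("empty truth: sensitivity undefined")
    return SegmentationScore(
        accuracy=100.0 * counts.tp / (counts.tp + counts.fp),
        sensitivity=100.0 * counts.tp / (counts.tp + counts.fn),
    )


def overlay_categories(predicted: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-pixel categorical overlay: 1 = TP, 2 = FP, 3 = FN, 0 = background.

    Category pixel counts equal :func:`confusion_counts`.
    """
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ValueError("shape mismatch")
    out = np.full(predicted.shape, BACKGROUND, dtype=np.uint8)
    out[predicted & truth] = TP
    out[predicted & ~truth] = FP
    out[~predicted & truth] = FN
    return out


# ---------------------------------------------------------------------------
# Geometric truth masks
# ---------------------------------------------------------------------------

def truth_mask_3d(grid: VoxelGrid, source: SourceModel) -> np.ndarray:
    """Binary source field on the grid: voxels whose center lies inside the
    sphere, or the single voxels containing each point emitter."""
    if source.shape == "sphere":
        return source.contains(grid.flat_centers()).reshape(grid.shape)
    mask = np.zeros(grid.shape, dtype=bool)
    for p in source.points:
        ijk = tuple(grid.index_of(float(c)) for c in p)
        mask[ijk] = True
    return mask


def truth_mask_slice(grid: VoxelGrid, source: SourceModel) -> np.ndarray:
    """Central XY slice of the 3-D truth mask."""
    return truth_mask_3d(grid, source)[:, :, grid.origin_index]


def segment_slice(image: Image3D, params: Optional[MorphParams] = None,
                  coord: float = 0.0) -> np.ndarray:
    """Binarize + morphologically filter the XY slice at z = ``coord``."""
    from .profiles import extract_slice

    sl = extract_slice(image, "XY", coord)
    return morph_filter(binarize(sl, params), params)
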