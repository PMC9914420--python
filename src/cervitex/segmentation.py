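"""Morphological lesion segmentation.

Images the classifier calls abnormal are binarized (Otsu by default), cleaned
by morphological closing (dilation then erosion: fills small holes and gaps)
followed by opening (erosion then dilation: removes specks and sharp peaks),
and reduced to regions of interest by connected-component labeling with a
minimum area.  Erosion uses the fit-inside convention with outside-image
pixels counting as background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk

__all__ = [
    "StructuringElement",
    "SegmentationResult",
    "binarize",
    "dilate",
    "erode",
    "open_close",
    "extract_roi",
    "dice",
    "segment",
]


@dataclass(frozen=True)
class StructuringElement:
    """Binary probe set for morphology: a disk or square, origin at center."""

    shape: str = "disk"
    size: int = 3  # disk radius or square side

    def footprint(self) -> np.ndarray:
        if self.shape == "disk":
            fp = disk(self.size)
        elif self.shape == "square":
            fp = np.ones((self.size, self.size))
        else:
            raise ValueError(f"unknown structuring element shape {self.shape!r}")
        if fp.sum() == 0:
            raise ValueError("empty structuring element")
        return fp.astype(bool)

    @classmethod
    def parse(cls, text: str) -> "StructuringElement":
        """Parse 'disk:3' / 'square:5' CLI syntax."""
        shape, _, size = text.partition(":")
        return cls(shape, int(size or 3))


@dataclass
class SegmentationResult:
    """Final lesion mask plus a per-region property table."""

    mask: np.ndarray
    regions: list[dict] = field(default_factory=list)
    dice_vs_truth: float | None = None


def _as_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, [0, 1]).all():
        raise ValueError("mask values must be strictly binary")
    return mask.astype(bool)


def binarize(image: np.ndarray, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Threshold a grayscale image to a binary foreground mask.

    ``otsu`` (default) maximizes inter-class variance; ``fixed`` uses the
    given threshold.  A constant image yields an all-background mask with a
    warning.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed binarization needs a threshold")
        return (image > threshold).astype(np.uint8)
    if method != "otsu":
        raise ValueError(f"unknown binarization method {method!r}")
    if image.min() == image.max():
        warnings.warn("constant image: returning empty mask", stacklevel=2)
        return np.zeros(image.shape, dtype=np.uint8)
    return (image > threshold_otsu(image)).astype(np.uint8)


def dilate(mask: np.ndarray, se: StructuringElement = StructuringElement()) -> np.ndarray:
    """Set dilation: union of structuring-element translates over foreground."""
    return ndimage.binary_dilation(_as_mask(mask), structure=se.footprint()).astype(np.uint8)


def erode(mask: np.ndarray, se: StructuringElement = StructuringElement()) -> np.ndarray:
    """Set erosion: keep pixels where the element fits inside foreground."""
    return ndimage.binary_erosion(
        _as_mask(mask), structure=se.footprint(), border_value=0
    ).astype(np.uint8)


def open_close(
    mask: np.ndarray,
    se: StructuringElement = StructuringElement(),
    operation: str = "close_open",
) -> np.ndarray:
    """Morphological cleanup.

    ``open`` (erosion then dilation) removes components smaller than the
    element; ``close`` (dilation then erosion) fills holes and gaps smaller
    than the element; ``open_close`` and ``close_open`` chain the two.  The
    pipeline default is ``close_open``: a thresholded lesion is typically
    riddled with sub-element gaps from its own texture, and opening first
    would erase it outright, so the mask is solidified by closing before
    opening sweeps away background specks.
    """
    mask = _as_mask(mask).astype(np.uint8)
    if operation not in ("open", "close", "open_close", "close_open"):
        raise ValueError(f"unknown operation {operation!r}")
    steps = {"open": "o", "close": "c", "open_close": "oc", "close_open": "co"}[operation]
    for step in steps:
        if step == "o":
            mask = dilate(erode(mask, se), se)
        else:
            mask = erode(dilate(mask, se), se)
    return mask


def extract_roi(mask: np.ndarray, min_area: int = 25) -> SegmentationResult:
    """8-connected components of the mask, discarding regions below min_area."""
    mask = _as_mask(mask)
    labeled = cc_label(mask, connectivity=2)
    keep = np.zeros(mask.shape, dtype=np.uint8)
    regions = []
    for prop in regionprops(labeled):
        if prop.area < min_area:
            continue
        keep[labeled == prop.label] = 1
        regions.append(
            {
                "label": int(prop.label),
                "area": int(prop.area),
                "bbox": tuple(int(v) for v in prop.bbox),
                "centroid": tuple(float(v) for v in prop.centroid),
            }
        )
    return SegmentationResult(keep, regions)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|A^B| / (|A|+|B|); two empty masks score 1.0."""
    pred = _as_mask(pred)
    truth = _as_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, truth).sum() / denom)


def segment(
    image: np.ndarray,
    se: StructuringElement = StructuringElement("disk", 3),
    min_area: int = 25,
    method: str = "otsu",
    threshold: float | None = None,
    truth: np.ndarray | None = None,
    operation: str = "close_open",
) -> SegmentationResult:
    """Full lesion segmentation of a grayscale image.

    Binarize, clean up morphologically (closing then opening by default),
    extract regions of at least ``min_area`` pixels; optionally score the
    mask against a ground truth with the Dice coefficient.
    """
    mask = binarize(image, method, threshold)
    mask = open_close(mask, se, operation)
    result = extract_roi(mask, min_area)
    if truth is not None:
        result.dice_vs_truth = dice(result.mask, truth)
    return result
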