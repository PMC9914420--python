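"""Directional associated histogram equalization (AHE).

Contrast enhancement for cervigram pre-processing.  Each pixel is re-valued
by windowed histogram equalization evaluated with the pixel sitting at each
of eight directional *anchor* positions of the sliding window (the window's
corners and edge midpoints), giving eight directionally enhanced images that
are fused into a single output.  Unlike a plain local histogram equalization
the operator therefore responds to edge orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ANCHOR_NAMES",
    "DirectionalStack",
    "anchor_offset",
    "to_grayscale",
    "ahe_pixel",
    "directional_enhance",
    "fuse_stack",
    "enhance_image",
]

#: The eight anchor names, in the fixed order used throughout the package.
#: (unit_dy, unit_dx) are scaled by the window half-size r = (n-1)/2.
ANCHOR_NAMES: dict[str, tuple[int, int]] = {
    "TL": (-1, -1),
    "TC": (-1, 0),
    "TR": (-1, 1),
    "CL": (0, -1),
    "CR": (0, 1),
    "LL": (1, -1),
    "LC": (1, 0),
    "LR": (1, 1),
}


def anchor_offset(name: str, window_size: int) -> tuple[int, int]:
    """Return the (dy, dx) anchor position relative to the window center.

    For an odd window of size ``n`` the offsets are the corners and edge
    midpoints at distance ``(n-1)/2``.
    """
    if window_size % 2 == 0 or window_size < 3:
        raise ValueError(f"window size must be odd and >= 3, got {window_size}")
    if name not in ANCHOR_NAMES:
        raise ValueError(f"unknown anchor {name!r}; expected one of {list(ANCHOR_NAMES)}")
    r = (window_size - 1) // 2
    uy, ux = ANCHOR_NAMES[name]
    return (uy * r, ux * r)


@dataclass
class DirectionalStack:
    """Eight directionally enhanced images, keyed by anchor name."""

    images: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images.values()}
        if len(shapes) > 1:
            raise ValueError(f"stack images disagree in shape: {shapes}")

    def as_array(self) -> np.ndarray:
        """Stack as an (8, H, W) array in fixed anchor order."""
        return np.stack([self.images[k] for k in ANCHOR_NAMES])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to grayscale by luminance weighting.

    Uses the Rec.601 luma weights 0.299 R + 0.587 G + 0.114 B rounded to the
    nearest integer.  A 2-D (already gray) image passes through unchanged.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.uint8, copy=False)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(
            f"expected a 2-D gray or (H, W, 3) RGB image, got shape {image.shape}"
        )
    lum = (
        0.299 * image[..., 0].astype(np.float64)
        + 0.587 * image[..., 1]
        + 0.114 * image[..., 2]
    )
    return np.floor(lum + 0.5).astype(np.uint8)


def ahe_pixel(window: np.ndarray, anchor: str | tuple[int, int], levels: int = 256) -> int:
    """Windowed histogram equalization of the pixel at ``anchor``.

    The output intensity is ``round((cdf(a) - cdf_min) / (n*n - cdf_min) * (L-1))``
    where ``a`` is the intensity at the anchor position, ``cdf`` the cumulative
    histogram count over the window and ``cdf_min`` its smallest nonzero value.
    A constant window (0/0) passes the anchor value through unchanged.
    """
    window = np.asarray(window)
    n = window.shape[0]
    if window.shape != (n, n) or n % 2 == 0:
        raise ValueError(f"window must be odd and square, got shape {window.shape}")
    if isinstance(anchor, str):
        dy, dx = anchor_offset(anchor, n)
    else:
        dy, dx = anchor
    r = (n - 1) // 2
    if abs(dy) > r or abs(dx) > r:
        raise ValueError(f"anchor offset ({dy}, {dx}) outside a {n}x{n} window")
    a = int(window[r + dy, r + dx])
    cdf_a = int(np.count_nonzero(window <= a))
    cdf_min = int(np.count_nonzero(window == window.min()))
    area = n * n
    if cdf_min == area:  # constant window: formula degenerates to 0/0
        return a
    out = np.floor((cdf_a - cdf_min) / (area - cdf_min) * (levels - 1) + 0.5)
    return int(np.clip(out, 0, levels - 1))


def _ahe_all_pixels(windows: np.ndarray, anchors: np.ndarray, levels: int) -> np.ndarray:
    """Vectorized ahe_pixel over an (H, W, n, n) window view.

    ``anchors`` holds the intensity at the anchor position of each window,
    which by construction is the original pixel value.
    """
    n2 = windows.shape[-1] * windows.shape[-2]
    cdf_a = np.count_nonzero(windows <= anchors[..., None, None], axis=(-2, -1))
    wmin = windows.min(axis=(-2, -1))
    cdf_min = np.count_nonzero(windows == wmin[..., None, None], axis=(-2, -1))
    constant = cdf_min == n2
    denom = np.where(constant, 1, n2 - cdf_min)
    out = np.floor((cdf_a - cdf_min) / denom * (levels - 1) + 0.5)
    out = np.clip(out, 0, levels - 1)
    return np.where(constant, anchors, out).astype(windows.dtype)


def directional_enhance(
    image: np.ndarray, window_size: int = 3, levels: int = 256
) -> DirectionalStack:
    """Apply AHE with the processed pixel at each of the 8 anchor positions.

    Border windows use edge-replication padding.  Returns one enhanced image
    per anchor, each the same shape as the input.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if window_size % 2 == 0 or window_size < 3:
        raise ValueError(f"window size must be odd and >= 3, got {window_size}")
    if min(image.shape) < 3:
        raise ValueError("image must be at least 3x3 for windowed enhancement")
    n = window_size
    r = (n - 1) // 2
    h, w = image.shape
    # Pad by 2r: the window center sits up to r pixels away from the processed
    # pixel (anchor at a corner), and the window extends r beyond its center.
    padded = np.pad(image, 2 * r, mode="edge")
    view = sliding_window_view(padded, (n, n))  # center c at view[c + r]
    images: dict[str, np.ndarray] = {}
    for name in ANCHOR_NAMES:
        dy, dx = anchor_offset(name, n)
        # pixel p sits at anchor (dy, dx) => window center at p - (dy, dx)
        oy, ox = r - dy, r - dx
        windows = view[oy : oy + h, ox : ox + w]
        images[name] = _ahe_all_pixels(windows, image, levels)
    return DirectionalStack(images)


def fuse_stack(stack: DirectionalStack, rule: str = "max") -> np.ndarray:
    """Fuse the 8 directional images into one enhanced image.

    ``max`` (default) keeps the highest intensity per pixel; ``mean`` averages
    and rounds.
    """
    if set(stack.images) != set(ANCHOR_NAMES):
        missing = set(ANCHOR_NAMES) - set(stack.images)
        raise ValueError(f"incomplete directional stack, missing anchors {sorted(missing)}")
    arr = stack.as_array()
    if rule == "max":
        return arr.max(axis=0)
    if rule == "mean":
        return np.floor(arr.mean(axis=0) + 0.5).astype(arr.dtype)
    raise ValueError(f"unknown fusion rule {rule!r}; expected 'max' or 'mean'")


def enhance_image(
    image: np.ndarray,
    window_size: int = 3,
    fusion: str = "max",
    levels: int = 256,
) -> np.ndarray:
    """Full enhancement: grayscale conversion, directional AHE, fusion."""
    gray = to_grayscale(image)
    return fuse_stack(directional_enhance(gray, window_size, levels), fusion)
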