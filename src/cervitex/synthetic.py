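"""Synthetic cervigram generator.

Stands in for a clinical image bank so the whole pipeline is testable without
external data.  Images are RGB with the dominant red cast of colposcopy
photographs, a smooth illumination gradient and Gaussian sensor noise.
Abnormal images carry an elliptical lesion whose texture differs from the
background in the properties the feature extractors measure: a brightness
offset (thresholdable), high-frequency speckle (raises the local mean
absolute deviation the ternary coding thresholds against, emulating the
punctation/mosaic texture of acetowhite lesions) and horizontal striping
(anisotropic run-length structure).  The background is smooth at pixel scale
(the default noise sd is 0): normal epithelium in a blurred photograph is
locally flat, which is what gives it its long gray-level runs and all-zero
ternary codes.  The ground-truth mask delimits the ellipse exactly, so
lesion texture is defined in feature-space terms rather than visual realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SyntheticSpec", "generate_dataset", "worked_fixtures"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; the defaults define the package's test regime.

    Intensities are 8-bit counts.  ``background`` is (base intensity,
    illumination-gradient amplitude, noise sd); ``lesion`` is (intensity
    offset, speckle sd, stripe amplitude, stripe period in pixels);
    ``semi_axes`` bounds the ellipse half-axes in pixels.
    """

    image_size: tuple[int, int] = (64, 64)
    lesion_probability: float = 0.5
    background: tuple[float, float, float] = (120.0, 25.0, 0.0)
    lesion: tuple[float, float, float, float] = (60.0, 18.0, 25.0, 4.0)
    semi_axes: tuple[tuple[float, float], tuple[float, float]] = ((8.0, 14.0), (6.0, 12.0))
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        max_axis = max(self.semi_axes[0][1], self.semi_axes[1][1])
        if 2 * max_axis >= min(h, w):
            raise ValueError(
                f"infeasible geometry: lesion axis {max_axis} cannot fit a {h}x{w} image"
            )


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    return ((u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0).astype(np.uint8)


def _to_rgb(gray_field: np.ndarray) -> np.ndarray:
    """Map a luminance field to a red-dominant cervigram-like RGB image."""
    r = np.clip(gray_field + 35.0, 0, 255)
    g = np.clip(0.62 * gray_field, 0, 255)
    b = np.clip(0.55 * gray_field, 0, 255)
    return np.stack([r, g, b], axis=-1).astype(np.uint8)


def generate_dataset(
    spec: SyntheticSpec, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate ``n`` labeled images with ground-truth masks.

    Returns (images (n,H,W,3) uint8, masks (n,H,W) uint8, labels (n,) int)
    with label 1 (abnormal) iff the mask is nonempty.  Bit-identical for a
    fixed spec (the seed is part of the spec).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    base, grad_amp, noise_sd = spec.background
    offset, speckle_sd, stripe_amp, stripe_period = spec.lesion
    yy, xx = np.mgrid[0:h, 0:w]
    images = np.empty((n, h, w, 3), dtype=np.uint8)
    masks = np.zeros((n, h, w), dtype=np.uint8)
    labels = np.zeros(n, dtype=int)
    for i in range(n):
        theta = rng.uniform(0, 2 * np.pi)
        gradient = (
            (xx - w / 2) * np.cos(theta) + (yy - h / 2) * np.sin(theta)
        ) / max(h, w)
        field = base + grad_amp * gradient + rng.normal(0, noise_sd, (h, w))
        abnormal = rng.uniform() < spec.lesion_probability
        if abnormal:
            a = rng.uniform(*spec.semi_axes[0])
            b = rng.uniform(*spec.semi_axes[1])
            margin = max(a, b) + 2
            center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            angle = rng.uniform(0, np.pi)
            mask = _ellipse_mask((h, w), center, (a, b), angle)
            stripes = stripe_amp * np.sin(2 * np.pi * yy / stripe_period)
            speckle = rng.normal(0, speckle_sd, (h, w))
            field = field + mask * (offset + stripes + speckle)
            masks[i] = mask
            labels[i] = 1
        images[i] = _to_rgb(np.clip(field, 0, 255))
    return images, masks, labels


def worked_fixtures() -> dict:
    """Small deterministic fixtures with hand-computed expected outputs.

    Shared by the unit tests of several modules: a 4x4 run-length example, a
    3x3 impulse for the finite Radon transform, a ternary-pattern neighbor
    ring, a hand-workable equalization window, and morphology block masks.
    """
    glrlm_image = np.array(
        [
            [0, 0, 1, 1],
            [0, 0, 1, 1],
            [2, 2, 2, 2],
            [3, 3, 3, 3],
        ]
    )
    impulse = np.zeros((3, 3), dtype=float)
    impulse[0, 0] = 1.0
    ahe_window = np.array([[1, 2, 2], [3, 3, 3], [4, 4, 5]])
    speck_and_block = np.zeros((16, 16), dtype=np.uint8)
    speck_and_block[2, 2] = 1  # 1-pixel speck: removed by opening
    speck_and_block[5:15, 5:15] = 1  # 10x10 block: survives
    holed_block = np.ones((8, 8), dtype=np.uint8)
    holed_block[4, 4] = 0  # interior hole: filled by closing
    return {
        "glrlm_4x4": {
            "image": glrlm_image,
            "gray_bins": 4,
            "levels": 4,
            "expected_runs_0deg": {(0, 2): 2, (1, 2): 2, (2, 4): 1, (3, 4): 1},
            "num_runs_0deg": 6,
            "SHE_0deg": 0.1875,
            "GLNU_0deg": 10.0 / 6.0,
        },
        "impulse_3x3": {
            "image": impulse,
            "p": 3,
            "hits_per_direction": 1,  # one offset of value 1 per direction
        },
        "eltp_patch": {
            "neighbors": np.array([10, 2, 6, 6, 6, 6, 6, 6]),
            "ace": 6.0,
            "we": 1.0,
            "expected_codes": np.array([1, -1, 0, 0, 0, 0, 0, 0], dtype=np.int8),
        },
        "ahe_window": {
            "window": ahe_window,
            "anchor": (0, 0),  # window center, value 3
            "levels": 8,
            "expected": 4,  # round((6-1)/(9-1)*7)
        },
        "morphology": {
            "speck_and_block": speck_and_block,
            "holed_block": holed_block,
        },
    }
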