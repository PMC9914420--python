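"""Finite ridgelet transform.

The finite Radon transform (FRAT) over the prime grid Z_p x Z_p sums pixels
along the p+1 pencils of finite-geometry lines; unlike interpolated
discretizations of the continuous Radon transform it is non-redundant and
exactly invertible.  A 1-D discrete wavelet transform applied independently
to each projection yields the finite ridgelet transform (FRT), which
represents line singularities sparsely — the projection aligned with a bright
line concentrates its energy in few coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _dwt

__all__ = [
    "RadonDomain",
    "RidgeletCoefficients",
    "is_prime",
    "largest_prime_leq",
    "prime_crop",
    "frat",
    "frat_inverse",
    "frt",
    "frt_inverse",
    "ridgelet_stats",
    "ridgelet_stat_names",
]


def is_prime(n: int) -> bool:
    if n < 2:
        return False
    if n < 4:
        return True
    if n % 2 == 0:
        return False
    d = 3
    while d * d <= n:
        if n % d == 0:
            return False
        d += 2
    return True


def largest_prime_leq(n: int) -> int:
    """Largest prime <= n (n >= 2)."""
    if n < 2:
        raise ValueError(f"no prime <= {n}")
    while not is_prime(n):
        n -= 1
    return n


def prime_crop(image: np.ndarray, p: int | None = None) -> tuple[np.ndarray, int]:
    """Center-crop an image to the largest admissible prime-sized square.

    If ``p`` is given it must be prime and fit inside the image.  Returns the
    cropped p x p image and p.
    """
    image = np.asarray(image)
    h, w = image.shape
    if p is None:
        p = largest_prime_leq(min(h, w))
    elif not is_prime(p) or p > min(h, w):
        raise ValueError(f"p={p} must be prime and <= min(h, w)={min(h, w)}")
    top = (h - p) // 2
    left = (w - p) // 2
    return image[top : top + p, left : left + p], p


@dataclass
class RadonDomain:
    """Finite Radon projections: (p+1) directions x p offsets.

    Rows 0..p-1 are the "slope k" directions (line set {(i, (k*i + t) mod p)}),
    row p collects the horizontal lines (constant row).  Every row sums to the
    total image mass because each direction partitions the pixels into lines.
    """

    projections: np.ndarray
    p: int

    @property
    def total_mass(self) -> float:
        return float(self.projections[0].sum())

    def validate(self) -> None:
        sums = self.projections.sum(axis=1)
        if not np.allclose(sums, sums[0], rtol=0, atol=1e-6 * max(1.0, abs(sums[0]))):
            raise ValueError("inconsistent Radon domain: projection sums differ")


@dataclass
class RidgeletCoefficients:
    """Wavelet sub-bands of each finite-Radon projection.

    ``coeffs[d]`` is the coarse-to-fine sub-band list ``[cA_L, cD_L, .., cD_1]``
    of direction ``d``; ``pads`` carries the odd-length pad flags needed for
    exact inversion.
    """

    coeffs: list[list[np.ndarray]]
    wavelet: str
    levels: int
    p: int
    pads: list[bool]


def frat(image: np.ndarray, p: int | None = None) -> RadonDomain:
    """Finite Radon transform of a p x p image (p prime)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"expected a square image, got shape {image.shape}")
    side = image.shape[0]
    if p is None:
        p = side
    if side != p or not is_prime(p):
        raise ValueError(f"image side {side} must equal a prime p (got p={p})")
    proj = np.empty((p + 1, p))
    rows = np.arange(p)
    offsets = np.arange(p)
    for k in range(p):
        cols = (k * rows[:, None] + offsets[None, :]) % p  # (i, t) -> column
        proj[k] = image[rows[:, None], cols].sum(axis=0)
    proj[p] = image.sum(axis=1)  # horizontal lines: row i is one line
    return RadonDomain(proj, p)


def frat_inverse(radon: RadonDomain) -> np.ndarray:
    """Exact inverse FRAT by back-projection.

    Summing, over all p+1 lines through a pixel, the line integrals counts the
    pixel p+1 times and every other pixel exactly once (two distinct points of
    the finite plane share one line), so
    ``x = (backprojection - total_mass) / p``.
    """
    radon.validate()
    p = radon.p
    proj = np.asarray(radon.projections, dtype=np.float64)
    if proj.shape != (p + 1, p):
        raise ValueError(f"expected ({p + 1}, {p}) projections, got {proj.shape}")
    rows = np.arange(p)
    cols = np.arange(p)
    back = np.zeros((p, p))
    for k in range(p):
        # pixel (i, j) lies on line t = (j - k*i) mod p of direction k
        t = (cols[None, :] - k * rows[:, None]) % p
        back += proj[k][t]
    back += proj[p][rows][:, None]
    return (back - radon.total_mass) / p


def frt(
    image: np.ndarray,
    p: int | None = None,
    wavelet: str = "db4",
    levels: int = 2,
) -> RidgeletCoefficients:
    """Finite ridgelet transform: 1-D DWT of every FRAT projection."""
    radon = frat(image, p)
    bands, pads = _dwt.wavedec(radon.projections, wavelet, levels)
    # split the batched sub-bands into a per-direction list
    coeffs = [[band[d] for band in bands] for d in range(radon.p + 1)]
    return RidgeletCoefficients(coeffs, wavelet, levels, radon.p, pads)


def frt_inverse(rc: RidgeletCoefficients) -> np.ndarray:
    """Invert the ridgelet transform exactly (inverse DWT, then inverse FRAT)."""
    bands = [
        np.stack([rc.coeffs[d][b] for d in range(rc.p + 1)])
        for b in range(rc.levels + 1)
    ]
    proj = _dwt.waverec(bands, rc.wavelet, rc.pads)
    return frat_inverse(RadonDomain(proj, rc.p))


def ridgelet_stats(rc: RidgeletCoefficients) -> np.ndarray:
    """Summary statistics of the ridgelet coefficients.

    For each direction and sub-band (coarse to fine): energy sum(c^2),
    mean absolute coefficient, and standard deviation, flattened
    direction-major.  Length = (p+1) * (levels+1) * 3.
    """
    out = []
    for direction in rc.coeffs:
        for band in direction:
            band = np.asarray(band)
            out.extend((float(np.sum(band**2)), float(np.mean(np.abs(band))), float(np.std(band))))
    return np.array(out)


def ridgelet_stat_names(p: int, levels: int) -> list[str]:
    """Feature names parallel to :func:`ridgelet_stats` output."""
    bands = [f"A{levels}"] + [f"D{lev}" for lev in range(levels, 0, -1)]
    return [
        f"frt_dir{d}_{band}_{stat}"
        for d in range(p + 1)
        for band in bands
        for stat in ("energy", "meanabs", "sd")
    ]
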