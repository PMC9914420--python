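"""Periodized orthogonal 1-D discrete wavelet transform.

Minimal multi-level DWT with exact reconstruction, used to transform each
finite-Radon projection.  Signals of odd length are extended by repeating the
last sample before each analysis step; the pad is tracked and dropped on
synthesis, so round trips are exact to machine precision for any length.

Filters are the standard orthogonal Daubechies families.  Only the wavelets
the pipeline actually offers are registered (haar, db2, db4).
"""

from __future__ import annotations

import numpy as np

__all__ = ["WAVELETS", "wavedec", "waverec", "dwt_step", "idwt_step"]

# Decomposition low-pass filters (ascending index).  High-pass and synthesis
# filters follow from the orthogonal quadrature-mirror relations.
_DEC_LO = {
    "haar": np.array([0.7071067811865476, 0.7071067811865476]),
    "db2": np.array(
        [
            -0.12940952255092145,
            0.22414386804185735,
            0.8365163037378079,
            0.48296291314469025,
        ]
    ),
    "db4": np.array(
        [
            -0.010597401784997278,
            0.032883011666982945,
            0.030841381835986965,
            -0.18703481171888114,
            -0.02798376941698385,
            0.6308807679295904,
            0.7148465705525415,
            0.23037781330885523,
        ]
    ),
}

WAVELETS = tuple(sorted(_DEC_LO))


def _filters(name: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        lo = _DEC_LO[name]
    except KeyError:
        raise ValueError(f"unknown wavelet {name!r}; available: {list(WAVELETS)}") from None
    k = np.arange(lo.size)
    hi = ((-1.0) ** k) * lo[::-1]
    return lo, hi


def dwt_step(x: np.ndarray, wavelet: str) -> tuple[np.ndarray, np.ndarray, bool]:
    """One circular analysis step along the last axis.

    Returns (approximation, detail, padded) where ``padded`` records whether
    an odd-length input was extended by one sample.
    """
    lo, hi = _filters(wavelet)
    x = np.asarray(x, dtype=np.float64)
    padded = x.shape[-1] % 2 == 1
    if padded:
        x = np.concatenate([x, x[..., -1:]], axis=-1)
    m = x.shape[-1]
    idx = (np.arange(lo.size)[None, :] + 2 * np.arange(m // 2)[:, None]) % m
    windows = x[..., idx]  # (..., m/2, L)
    return windows @ lo, windows @ hi, padded


def idwt_step(
    approx: np.ndarray, detail: np.ndarray, wavelet: str, padded: bool
) -> np.ndarray:
    """Exact inverse of :func:`dwt_step` along the last axis."""
    lo, hi = _filters(wavelet)
    approx = np.asarray(approx, dtype=np.float64)
    detail = np.asarray(detail, dtype=np.float64)
    if approx.shape != detail.shape:
        raise ValueError("approximation and detail sub-bands must share a shape")
    half = approx.shape[-1]
    m = 2 * half
    idx = (np.arange(lo.size)[None, :] + 2 * np.arange(half)[:, None]) % m  # (half, L)
    contrib = approx[..., None] * lo + detail[..., None] * hi  # (..., half, L)
    lead = approx.shape[:-1]
    out = np.zeros(lead + (m,))
    flat = contrib.reshape(lead + (-1,))
    np.add.at(out, (..., idx.ravel()), flat)
    if padded:
        out = out[..., :-1]
    return out


def wavedec(x: np.ndarray, wavelet: str, levels: int) -> tuple[list[np.ndarray], list[bool]]:
    """Multi-level decomposition along the last axis.

    Returns ``([cA_L, cD_L, ..., cD_1], pads)`` in coarse-to-fine order, plus
    the per-level odd-length pad flags needed for exact reconstruction.
    """
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    details: list[np.ndarray] = []
    pads: list[bool] = []
    approx = np.asarray(x, dtype=np.float64)
    for _ in range(levels):
        approx, d, padded = dwt_step(approx, wavelet)
        details.append(d)
        pads.append(padded)
    return [approx] + details[::-1], pads


def waverec(coeffs: list[np.ndarray], wavelet: str, pads: list[bool]) -> np.ndarray:
    """Inverse of :func:`wavedec`."""
    approx = coeffs[0]
    details = coeffs[1:]
    for d, padded in zip(details, pads[::-1]):
        approx = idwt_step(approx, d, wavelet, padded)
    return approx
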