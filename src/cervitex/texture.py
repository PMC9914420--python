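"""Texture feature extraction.

Three feature families drive the normal/abnormal decision, all computed on
the contrast-enhanced grayscale image:

* **GLRLM** — gray-level run-length matrices: counts of maximal runs of
  equal (re-quantized) gray level along 0/45/90/135 degrees, summarized by
  seven classical run-length statistics per orientation.
* **ELTP** — enhanced local ternary pattern: each pixel's ring of neighbors
  is coded -1/0/+1 against a data-driven center (the patch mean) and
  tolerance (the patch mean absolute deviation), then split into positive and
  negative binary channels whose histograms form the descriptor.  With the
  rotation-invariant mapping the descriptor is exactly invariant under
  quarter-turn rotations.
* **Moment invariants** — central moments to order 3 and the seven Hu
  rotation/scale/translation invariants.

:func:`assemble_features` concatenates the configured blocks (optionally
including ridgelet statistics) into the fixed-order vector the classifier
consumes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.measure import moments_central, moments_hu, moments_normalized

from . import ridgelet as _ridgelet

__all__ = [
    "GLRLM_FEATURE_NAMES",
    "GLRLM_ORIENTATIONS",
    "RunLengthMatrix",
    "ELTPDescriptor",
    "MomentInvariants",
    "FeatureConfig",
    "FeatureVector",
    "quantize_gray",
    "glrlm",
    "glrlm_features",
    "eltp_code",
    "eltp_descriptor",
    "moment_invariants",
    "assemble_features",
]

GLRLM_FEATURE_NAMES = ("SHE", "LOE", "GLNU", "RLNU", "RUP", "LGLRE", "HGLRE")
GLRLM_ORIENTATIONS = (0, 45, 90, 135)


# --------------------------------------------------------------------------
# gray-level run-length matrices
# --------------------------------------------------------------------------

def quantize_gray(image: np.ndarray, gray_bins: int, levels: int = 256) -> np.ndarray:
    """Uniformly re-quantize intensities in [0, levels) to ``gray_bins`` bins."""
    if gray_bins < 2:
        raise ValueError(f"gray_bins must be >= 2, got {gray_bins}")
    q = (np.asarray(image).astype(np.int64) * gray_bins) // levels
    return np.clip(q, 0, gray_bins - 1)


@dataclass
class RunLengthMatrix:
    """Run counts M(a, b): gray bin a (0-based) x run length b (1..q)."""

    counts: np.ndarray
    orientation: int
    gray_bins: int
    num_pixels: int

    @property
    def num_runs(self) -> int:
        return int(self.counts.sum())


def _orientation_lines(image: np.ndarray, orientation: int) -> list[np.ndarray]:
    h, w = image.shape
    if orientation == 0:
        return list(image)
    if orientation == 90:
        return list(image.T)
    if orientation == 135:
        return [image.diagonal(o) for o in range(-(h - 1), w)]
    if orientation == 45:
        flipped = np.fliplr(image)
        return [flipped.diagonal(o) for o in range(-(h - 1), w)]
    raise ValueError(f"unsupported orientation {orientation}; expected one of {GLRLM_ORIENTATIONS}")


def _run_encode(lines: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Maximal-run values and lengths over a set of 1-D lines.

    Lines are concatenated with a sentinel separator so a single boundary
    pass finds every run.
    """
    pieces = []
    for ln in lines:
        pieces.append(np.asarray(ln, dtype=np.int64))
        pieces.append(np.array([-1], dtype=np.int64))  # separator, never a gray bin
    seq = np.concatenate(pieces)
    boundaries = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries + 1, [seq.size]])
    values = seq[starts]
    lengths = ends - starts
    keep = values >= 0
    return values[keep], lengths[keep]


def glrlm(
    image: np.ndarray,
    orientation: int,
    gray_bins: int = 16,
    levels: int = 256,
) -> RunLengthMatrix:
    """Run-length matrix of ``image`` along one orientation.

    The image is re-quantized to ``gray_bins`` uniform bins first; pass
    ``gray_bins == levels`` for identity quantization.  Every pixel belongs to
    exactly one maximal run, so sum of b*M(a, b) equals the pixel count.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    binned = quantize_gray(image, gray_bins, levels)
    values, lengths = _run_encode(_orientation_lines(binned, orientation))
    qmax = max(image.shape)
    counts = np.zeros((gray_bins, qmax), dtype=np.int64)
    np.add.at(counts, (values, lengths - 1), 1)
    return RunLengthMatrix(counts, orientation, gray_bins, int(image.size))


def glrlm_features(M: RunLengthMatrix) -> np.ndarray:
    """The seven run-length statistics of a run-length matrix.

    Order: SHE, LOE, GLNU, RLNU, RUP, LGLRE, HGLRE.  Gray index ``a`` is
    1-based (bin 0 -> a=1) so the low/high gray-level emphases are defined for
    every bin; run length ``b`` is 1-based by construction.
    """
    counts = M.counts.astype(np.float64)
    n_runs = counts.sum()
    if n_runs == 0:
        raise ValueError("empty run-length matrix")
    a = np.arange(1, counts.shape[0] + 1, dtype=np.float64)[:, None]
    b = np.arange(1, counts.shape[1] + 1, dtype=np.float64)[None, :]
    she = np.sum(counts / b**2) / n_runs
    loe = np.sum(counts * b**2) / n_runs
    glnu = np.sum(counts.sum(axis=1) ** 2) / n_runs
    rlnu = np.sum(counts.sum(axis=0) ** 2) / n_runs
    rup = n_runs / M.num_pixels
    lglre = np.sum(counts / a**2) / n_runs
    hglre = np.sum(counts * a**2) / n_runs
    return np.array([she, loe, glnu, rlnu, rup, lglre, hglre])


def glrlm_feature_block(
    image: np.ndarray, gray_bins: int = 16, levels: int = 256
) -> tuple[np.ndarray, list[str]]:
    """All seven statistics at all four orientations (28 values)."""
    values = []
    names = []
    for orient in GLRLM_ORIENTATIONS:
        feats = glrlm_features(glrlm(image, orient, gray_bins, levels))
        values.append(feats)
        names.extend(f"glrlm_{orient}_{fn}" for fn in GLRLM_FEATURE_NAMES)
    return np.concatenate(values), names


# --------------------------------------------------------------------------
# enhanced local ternary pattern
# --------------------------------------------------------------------------

def eltp_code(
    neighbors: np.ndarray, ace: float, we: float, eps: float = 1e-6
) -> np.ndarray:
    """Ternary code of a neighbor ring against center ``ace``, tolerance ``we``.

    +1 where neighbor - ace >= we, -1 where neighbor - ace <= -we, else 0.
    ``we`` (the patch mean absolute deviation) is floored at ``eps`` so a
    constant patch codes to all zeros.
    """
    neighbors = np.asarray(neighbors, dtype=np.float64)
    if neighbors.size < 4:
        raise ValueError(f"need at least 4 neighbors, got {neighbors.size}")
    we = max(float(we), eps)
    diff = neighbors - float(ace)
    return np.where(diff >= we, 1, np.where(diff <= -we, -1, 0)).astype(np.int8)


def _ring_offsets(P: int, R: int) -> list[tuple[int, int]]:
    """Integer neighbor ring in counter-clockwise circular order.

    P=8 uses the square (chessboard) ring, P=4 the axial cross; both map onto
    themselves under quarter-turn rotations, which is what makes the
    rotation-invariant histogram exact on the pixel grid.
    """
    if P == 8:
        base = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
    elif P == 4:
        base = [(0, 1), (-1, 0), (0, -1), (1, 0)]
    else:
        raise ValueError(f"P={P} unsupported; exact grid rings exist for P in (4, 8)")
    return [(dy * R, dx * R) for dy, dx in base]


def _riu2_table(P: int) -> np.ndarray:
    """Map each P-bit pattern to its rotation-invariant uniform bin.

    Uniform patterns (<= 2 circular 0/1 transitions) map to their popcount
    (0..P); all others share bin P+1.
    """
    table = np.empty(2**P, dtype=np.int64)
    for pattern in range(2**P):
        bits = [(pattern >> k) & 1 for k in range(P)]
        transitions = sum(bits[k] != bits[(k + 1) % P] for k in range(P))
        table[pattern] = sum(bits) if transitions <= 2 else P + 1
    return table


@dataclass
class ELTPDescriptor:
    """Histograms of the positive and negative ELTP channels."""

    upper_hist: np.ndarray
    lower_hist: np.ndarray
    rotation_invariant: bool
    P: int
    R: int

    @property
    def n_coded(self) -> int:
        return int(self.upper_hist.sum())

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.upper_hist, self.lower_hist]).astype(np.float64)


def eltp_descriptor(
    image: np.ndarray,
    P: int = 8,
    R: int = 1,
    rotation_invariant: bool = True,
) -> ELTPDescriptor:
    """ELTP descriptor of an integer grayscale image.

    The center ``ace`` is the mean and the tolerance ``we`` the mean absolute
    deviation of the full (2R+1)x(2R+1) patch.  Comparisons are carried out in
    exact integer arithmetic (diff >= we scaled by the patch area squared), so
    the descriptor's rotation invariance and the upper/lower swap under
    intensity inversion hold exactly, with no floating-point boundary flips.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    h, w = image.shape
    if min(h, w) < 2 * R + 1:
        raise ValueError(f"image {image.shape} too small for radius R={R}")
    img = image.astype(np.int64)
    m = (2 * R + 1) ** 2
    windows = sliding_window_view(img, (2 * R + 1, 2 * R + 1))
    patch_sum = windows.sum(axis=(-2, -1))  # S = m * ace
    # B = sum |m*v_i - S| = m^2 * mean-absolute-deviation
    dev_sum = np.abs(m * windows - patch_sum[..., None, None]).sum(axis=(-2, -1))
    dev_sum = np.maximum(dev_sum, 1)  # MAD floor: constant patch codes to 0
    upper = np.zeros(patch_sum.shape, dtype=np.int64)
    lower = np.zeros(patch_sum.shape, dtype=np.int64)
    for k, (dy, dx) in enumerate(_ring_offsets(P, R)):
        nb = img[R + dy : h - R + dy, R + dx : w - R + dx]
        lhs = m * (m * nb - patch_sum)  # m^2 * (neighbor - ace)
        upper |= (lhs >= dev_sum).astype(np.int64) << k
        lower |= (lhs <= -dev_sum).astype(np.int64) << k
    if rotation_invariant:
        table = _riu2_table(P)
        upper, lower = table[upper], table[lower]
        nbins = P + 2
    else:
        nbins = 2**P
    return ELTPDescriptor(
        np.bincount(upper.ravel(), minlength=nbins),
        np.bincount(lower.ravel(), minlength=nbins),
        rotation_invariant,
        P,
        R,
    )


# --------------------------------------------------------------------------
# moment invariants
# --------------------------------------------------------------------------

@dataclass
class MomentInvariants:
    """Central moments to order 3 and the seven Hu invariants."""

    central_moments: np.ndarray  # (4, 4), index [a, b] = mu_{a,b}
    hu: np.ndarray  # (7,)


def moment_invariants(image: np.ndarray) -> MomentInvariants:
    """Central moments about the intensity centroid plus the Hu invariants.

    Central moments are translation-invariant by construction; the Hu set is
    additionally invariant under rotation and (after normalization) scale.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if image.sum() == 0:
        raise ValueError("zero-mass image has no centroid")
    mu = moments_central(image, order=3)
    hu = moments_hu(moments_normalized(mu))
    return MomentInvariants(mu, hu)


# --------------------------------------------------------------------------
# feature vector assembly
# --------------------------------------------------------------------------

VALID_BLOCKS = ("glrlm", "frt", "mif", "eltp")


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction configuration; its hash stamps every feature table."""

    blocks: tuple[str, ...] = VALID_BLOCKS
    gray_bins: int = 16
    levels: int = 256
    eltp_points: int = 8
    eltp_radius: int = 1
    eltp_rotation_invariant: bool = True
    frt_prime: int | None = None
    wavelet: str = "db4"
    frt_levels: int = 2

    def __post_init__(self) -> None:
        unknown = set(self.blocks) - set(VALID_BLOCKS)
        if unknown:
            raise ValueError(f"unknown feature blocks {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class FeatureVector:
    """Fixed-order feature values with parallel names and provenance hash."""

    values: np.ndarray
    names: list[str] = field(repr=False)
    config_hash: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("feature values and names differ in length")


def assemble_features(image: np.ndarray, config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Extract the configured feature blocks from an enhanced gray image.

    Block order is fixed (glrlm | frt | mif | eltp restricted to the
    configured subset) so vectors are comparable across a dataset.
    """
    values: list[np.ndarray] = []
    names: list[str] = []
    for block in VALID_BLOCKS:
        if block not in config.blocks:
            continue
        if block == "glrlm":
            v, n = glrlm_feature_block(image, config.gray_bins, config.levels)
        elif block == "frt":
            cropped, p = _ridgelet.prime_crop(image, config.frt_prime)
            rc = _ridgelet.frt(cropped, p, config.wavelet, config.frt_levels)
            v = _ridgelet.ridgelet_stats(rc)
            n = _ridgelet.ridgelet_stat_names(p, config.frt_levels)
        elif block == "mif":
            v = moment_invariants(image).hu
            n = [f"mif_hu{i}" for i in range(1, 8)]
        else:  # eltp
            desc = eltp_descriptor(
                image,
                config.eltp_points,
                config.eltp_radius,
                config.eltp_rotation_invariant,
            )
            v = desc.concatenated()
            n = [f"eltp_upper_{i}" for i in range(len(desc.upper_hist))] + [
                f"eltp_lower_{i}" for i in range(len(desc.lower_hist))
            ]
        values.append(np.asarray(v, dtype=np.float64))
        names.extend(n)
    if not values:
        raise ValueError("no feature blocks configured")
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in assembled vector")
    return FeatureVector(np.concatenate(values), names, config.config_hash())
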