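import numpy as np
import pytest

from cervitex.synthetic import SyntheticSpec, generate_dataset, worked_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return worked_fixtures()


@pytest.fixture(scope="session")
def small_dataset():
    """40 synthetic images with masks and labels, fixed seed."""
    spec = SyntheticSpec(seed=7)
    return generate_dataset(spec, 40)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent brute-force oracles, shared between unit and acceptance tests
# ---------------------------------------------------------------------------

def brute_force_ahe(image: np.ndarray, anchor_dy: int, anchor_dx: int, n: int, levels: int) -> np.ndarray:
    """Reference AHE: per-pixel loops, windowed CDF, index-clamped borders."""
    h, w = image.shape
    r = (n - 1) // 2
    out = np.zeros_like(image)
    for py in range(h):
        for px in range(w):
            cy, cx = py - anchor_dy, px - anchor_dx  # window center
            vals = []
            for wy in range(cy - r, cy + r + 1):
                for wx in range(cx - r, cx + r + 1):
                    vals.append(image[min(max(wy, 0), h - 1), min(max(wx, 0), w - 1)])
            vals = np.array(vals)
            a = image[py, px]
            cdf_a = int(np.sum(vals <= a))
            cdf_min = int(np.sum(vals == vals.min()))
            if cdf_min == n * n:
                out[py, px] = a
            else:
                v = np.floor((cdf_a - cdf_min) / (n * n - cdf_min) * (levels - 1) + 0.5)
                out[py, px] = min(max(int(v), 0), levels - 1)
    return out


def brute_force_runs(image: np.ndarray, orientation: int) -> dict[tuple[int, int], int]:
    """Reference maximal-run counter: walk every line pixel by pixel."""
    h, w = image.shape
    if orientation == 0:
        lines = [list(image[i, :]) for i in range(h)]
    elif orientation == 90:
        lines = [list(image[:, j]) for j in range(w)]
    elif orientation == 135:
        lines = [
            [image[i, j] for i in range(h) for j in range(w) if i - j == d]
            for d in range(-(w - 1), h)
        ]
    elif orientation == 45:
        lines = [
            [image[i, j] for i in range(h) for j in range(w) if i + j == s]
            for s in range(h + w - 1)
        ]
    else:
        raise ValueError(orientation)
    counts: dict[tuple[int, int], int] = {}
    for line in lines:
        if not line:
            continue
        run_val, run_len = line[0], 1
        for v in line[1:]:
            if v == run_val:
                run_len += 1
            else:
                counts[(int(run_val), run_len)] = counts.get((int(run_val), run_len), 0) + 1
                run_val, run_len = v, 1
        counts[(int(run_val), run_len)] = counts.get((int(run_val), run_len), 0) + 1
    return counts


def brute_force_glrlm_features(counts: dict[tuple[int, int], int], num_pixels: int) -> np.ndarray:
    """Reference run-length statistics from a {(gray, length): n} run dict."""
    n_runs = sum(counts.values())
    she = sum(m / b**2 for (_, b), m in counts.items()) / n_runs
    loe = sum(m * b**2 for (_, b), m in counts.items()) / n_runs
    by_gray: dict[int, int] = {}
    by_len: dict[int, int] = {}
    for (g, b), m in counts.items():
        by_gray[g] = by_gray.get(g, 0) + m
        by_len[b] = by_len.get(b, 0) + m
    glnu = sum(v**2 for v in by_gray.values()) / n_runs
    rlnu = sum(v**2 for v in by_len.values()) / n_runs
    rup = n_runs / num_pixels
    lglre = sum(m / (g + 1) ** 2 for (g, _), m in counts.items()) / n_runs
    hglre = sum(m * (g + 1) ** 2 for (g, _), m in counts.items()) / n_runs
    return np.array([she, loe, glnu, rlnu, rup, lglre, hglre])
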