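import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cervitex import _dwt
from cervitex.ridgelet import (
    RadonDomain,
    frat,
    frat_inverse,
    frt,
    frt_inverse,
    is_prime,
    largest_prime_leq,
    prime_crop,
    ridgelet_stats,
    ridgelet_stat_names,
)


class TestDWT:
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.integers(5, 40),
        st.sampled_from(_dwt.WAVELETS),
        st.integers(1, 3),
        st.integers(0, 2**31 - 1),
    )
    def test_round_trip(self, n, wavelet, levels, seed):
        x = np.random.default_rng(seed).normal(size=n)
        coeffs, pads = _dwt.wavedec(x, wavelet, levels)
        rec = _dwt.waverec(coeffs, wavelet, pads)
        assert np.allclose(rec, x, atol=1e-10)

    def test_constant_signal_details_vanish(self):
        x = np.full(16, 3.7)
        coeffs, _ = _dwt.wavedec(x, "db4", 2)
        for d in coeffs[1:]:
            assert np.allclose(d, 0, atol=1e-12)

    def test_linearity(self, rng):
        x, y = rng.normal(size=21), rng.normal(size=21)
        cx_, _ = _dwt.wavedec(x, "db2", 2)
        cy, _ = _dwt.wavedec(y, "db2", 2)
        cz, _ = _dwt.wavedec(2.0 * x - 3.0 * y, "db2", 2)
        for a, b, c in zip(cx_, cy, cz):
            assert np.allclose(2.0 * a - 3.0 * b, c, atol=1e-10)

    def test_unknown_wavelet(self):
        with pytest.raises(ValueError, match="unknown wavelet"):
            _dwt.wavedec(np.zeros(8), "sym5", 1)

    def test_batched_rows_match_single(self, rng):
        X = rng.normal(size=(4, 17))
        batch, pads = _dwt.wavedec(X, "db4", 2)
        for i in range(4):
            single, _ = _dwt.wavedec(X[i], "db4", 2)
            for b, s in zip(batch, single):
                assert np.allclose(b[i], s)


class TestFrat:
    def test_impulse_fixture(self, fixtures):
        fx = fixtures["impulse_3x3"]
        radon = frat(fx["image"], fx["p"])
        for row in radon.projections:
            assert np.sum(row == 1) == fx["hits_per_direction"]
            assert np.sum(row) == 1

    def test_projection_rows_conserve_mass(self, rng):
        img = rng.integers(0, 256, (17, 17)).astype(float)
        radon = frat(img)
        assert np.allclose(radon.projections.sum(axis=1), img.sum())

    def test_constant_image(self):
        img = np.full((5, 5), 3.0)
        radon = frat(img)
        assert np.allclose(radon.projections, 15.0)

    def test_every_pixel_once_per_direction(self, rng):
        """Each direction partitions the grid: p lines x p pixels."""
        img = np.ones((7, 7))
        radon = frat(img)
        assert np.allclose(radon.projections, 7.0)

    @pytest.mark.parametrize("shape", [(4, 4), (6, 5), (9, 9)])
    def test_bad_grid_rejected(self, shape):
        with pytest.raises(ValueError):
            frat(np.zeros(shape))


class TestFratInverse:
    @pytest.mark.parametrize("p", [3, 17, 61])
    def test_exact_round_trip(self, p, rng):
        img = rng.integers(0, 256, (p, p)).astype(float)
        rec = frat_inverse(frat(img))
        assert np.abs(rec - img).max() < 1e-9

    def test_zero_domain(self):
        radon = RadonDomain(np.zeros((4, 3)), 3)
        assert np.allclose(frat_inverse(radon), 0.0)

    def test_impulse_recovered(self, fixtures):
        fx = fixtures["impulse_3x3"]
        rec = frat_inverse(frat(fx["image"], fx["p"]))
        assert np.abs(rec - fx["image"]).max() < 1e-12

    def test_inconsistent_sums_rejected(self):
        proj = np.zeros((4, 3))
        proj[0, 0] = 5.0  # one direction carries mass the others lack
        with pytest.raises(ValueError, match="inconsistent"):
            frat_inverse(RadonDomain(proj, 3))

    def test_linearity(self, rng):
        x = rng.normal(size=(11, 11))
        y = rng.normal(size=(11, 11))
        rx, ry = frat(x), frat(y)
        rz = frat(1.5 * x + 2.0 * y)
        assert np.allclose(rz.projections, 1.5 * rx.projections + 2.0 * ry.projections)


class TestFrt:
    def test_constant_image_details_zero(self):
        rc = frt(np.full((11, 11), 9.0), wavelet="db4", levels=2)
        for direction in rc.coeffs:
            for band in direction[1:]:
                assert np.allclose(band, 0, atol=1e-9)

    def test_round_trip(self, rng):
        img = rng.integers(0, 256, (17, 17)).astype(float)
        rec = frt_inverse(frt(img, 17, "db4", 2))
        assert np.abs(rec - img).max() < 1e-8

    @pytest.mark.parametrize("k", [0, 3, None])
    def test_line_energy_concentration(self, k):
        """A bright finite line concentrates detail energy in its own direction."""
        p = 17
        img = np.zeros((p, p))
        if k is None:  # horizontal line -> last direction
            img[5, :] = 100.0
            expected_dir = p
        else:  # line {(i, (k*i + t) mod p)} -> direction k
            i = np.arange(p)
            img[i, (k * i + 4) % p] = 100.0
            expected_dir = k
        rc = frt(img, p, "db4", 2)
        energies = [
            sum(float(np.sum(band**2)) for band in direction[1:])
            for direction in rc.coeffs
        ]
        assert np.argmax(energies) == expected_dir
        others = [e for d, e in enumerate(energies) if d != expected_dir]
        assert energies[expected_dir] > max(others)

    def test_unknown_wavelet(self):
        with pytest.raises(ValueError):
            frt(np.zeros((5, 5)), wavelet="nope")


class TestRidgeletStats:
    def test_zero_image(self):
        stats = ridgelet_stats(frt(np.zeros((7, 7))))
        assert np.allclose(stats, 0.0)

    def test_scaling_quadruples_energy(self, rng):
        img = rng.normal(size=(11, 11))
        s1 = ridgelet_stats(frt(img))
        s2 = ridgelet_stats(frt(2.0 * img))
        energies = slice(0, None, 3)
        assert np.allclose(s2[energies], 4.0 * s1[energies])

    def test_length_and_names(self):
        p, levels = 7, 2
        stats = ridgelet_stats(frt(np.ones((p, p)), p, "haar", levels))
        names = ridgelet_stat_names(p, levels)
        assert len(stats) == (p + 1) * (levels + 1) * 3
        assert len(names) == len(stats)
        assert len(set(names)) == len(names)


class TestPrimeHelpers:
    @pytest.mark.parametrize("n,expected", [(61, 61), (64, 61), (17, 17), (4, 3), (2, 2)])
    def test_largest_prime(self, n, expected):
        assert largest_prime_leq(n) == expected

    def test_is_prime(self):
        primes = [n for n in range(2, 30) if is_prime(n)]
        assert primes == [2, 3, 5, 7, 11, 13, 17, 19, 23, 29]

    def test_prime_crop(self, rng):
        img = rng.integers(0, 255, (64, 70))
        cropped, p = prime_crop(img)
        assert p == 61 and cropped.shape == (61, 61)
        with pytest.raises(ValueError):
            prime_crop(img, 67)
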