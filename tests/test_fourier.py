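import numpy as np
import pytest

from epidermtex.fourier_tex import (
    FourierDescriptor,
    RingWedgePartition,
    centered_spectrum,
    circular_angular_descriptor,
    circular_descriptor,
    fourier_features,
    n_circular_features,
    spectrum_center,
)

from conftest import random_gray


def brute_circular(spectrum):
    """Independent disk-sum oracle: per-bin double loop."""
    M, N = spectrum.shape
    ci, cj = M // 2, N // 2
    G = min(M, N) // 2 - 1
    out = np.zeros(G)
    for g in range(1, G + 1):
        total = 0.0
        for i in range(M):
            for j in range(N):
                if np.hypot(i - ci, j - cj) <= g:
                    total += spectrum[i, j]
        out[g - 1] = total
    return out


def brute_sectors(spectrum, radii=(3, 6, 9, 12, 15, 18, 21, 24), n_ang=8):
    """Independent sector oracle classifying each bin by (distance, angle)."""
    M, N = spectrum.shape
    ci, cj = M // 2, N // 2
    out = np.zeros(len(radii) * n_ang)
    edges = (0.0,) + tuple(radii)
    for i in range(M):
        for j in range(N):
            r = np.hypot(i - ci, j - cj)
            if r == 0 or r > edges[-1]:
                continue
            ring = next(k for k in range(len(radii)) if edges[k] < r <= edges[k + 1])
            ang = np.arctan2(-(i - ci), j - cj) % (2 * np.pi)
            wedge = min(int(ang / (2 * np.pi / n_ang)), n_ang - 1)
            out[ring * n_ang + wedge] += spectrum[i, j]
    return out


class TestCenteredSpectrum:
    def test_constant_image_is_dc_only(self):
        img = np.full((8, 10), 7, dtype=np.int64)
        spec = centered_spectrum(img)
        ci, cj = spectrum_center(spec.shape)
        assert spec[ci, cj] == pytest.approx(8 * 10 * 7)
        spec[ci, cj] = 0
        assert np.allclose(spec, 0, atol=1e-9)

    def test_two_by_two_hand_dft(self):
        spec = centered_spectrum(np.array([[0, 255], [0, 255]]))
        assert spec[1, 1] == pytest.approx(510)  # shifted DC
        assert spec[1, 0] == pytest.approx(510)  # horizontal-frequency axis
        assert spec[0, 0] == pytest.approx(0) and spec[0, 1] == pytest.approx(0)

    def test_parseval_identity(self, rng):
        img = random_gray(rng, (17, 23))
        spec = centered_spectrum(img)
        assert np.sum(spec**2) == pytest.approx(
            17 * 23 * np.sum(img.astype(float) ** 2), rel=1e-6
        )


class TestCircularDescriptor:
    def test_length_formula(self):
        assert n_circular_features((2080, 1540)) == 769
        assert n_circular_features((256, 256)) == 127

    def test_constant_image_all_entries_dc(self):
        spec = centered_spectrum(np.full((12, 12), 3, dtype=np.int64))
        desc = circular_descriptor(spec)
        assert np.allclose(desc, 12 * 12 * 3, atol=1e-6)

    def test_matches_brute_force_disk_sums(self, rng):
        for _ in range(5):
            spec = centered_spectrum(random_gray(rng, (16, 16)))
            assert np.allclose(circular_descriptor(spec), brute_circular(spec), rtol=1e-9)

    def test_non_decreasing(self, rng):
        spec = centered_spectrum(random_gray(rng, (32, 20)))
        assert np.all(np.diff(circular_descriptor(spec)) >= 0)

    def test_too_small_spectrum_rejected(self):
        with pytest.raises(ValueError):
            circular_descriptor(np.ones((5, 40)))


class TestCircularAngularDescriptor:
    def test_default_partition_length(self, rng):
        spec = centered_spectrum(random_gray(rng, (64, 64)))
        assert circular_angular_descriptor(spec).shape == (64,)

    def test_constant_image_all_zero(self):
        spec = centered_spectrum(np.full((64, 64), 9, dtype=np.int64))
        assert np.allclose(circular_angular_descriptor(spec), 0, atol=1e-9)

    def test_matches_brute_force_sector_sums(self, rng):
        spec = centered_spectrum(random_gray(rng, (64, 64)))
        assert np.allclose(circular_angular_descriptor(spec), brute_sectors(spec), rtol=1e-9)

    def test_sectors_recompose_annulus_total(self, rng):
        spec = centered_spectrum(random_gray(rng, (64, 56)))
        ci, cj = spectrum_center(spec.shape)
        ii = np.arange(spec.shape[0])[:, None] - ci
        jj = np.arange(spec.shape[1])[None, :] - cj
        r = np.hypot(ii, jj)
        annulus = spec[(r > 0) & (r <= 24)].sum()
        assert circular_angular_descriptor(spec).sum() == pytest.approx(annulus, rel=1e-6)

    def test_rot90_permutes_wedges_within_rings(self, rng):
        img = random_gray(rng, (65, 65))  # odd size: rotation maps grid onto itself
        d0 = circular_angular_descriptor(centered_spectrum(img)).reshape(8, 8)
        d1 = circular_angular_descriptor(centered_spectrum(np.rot90(img))).reshape(8, 8)
        assert np.allclose(np.roll(d0, 2, axis=1), d1, rtol=1e-6)
        c0 = circular_descriptor(centered_spectrum(img))
        c1 = circular_descriptor(centered_spectrum(np.rot90(img)))
        assert np.allclose(c0, c1, rtol=1e-6)

    def test_partition_validation(self):
        with pytest.raises(ValueError):
            RingWedgePartition(ring_radii=(3, 3, 9))
        spec = centered_spectrum(np.full((16, 16), 1, dtype=np.int64))
        with pytest.raises(ValueError):
            circular_angular_descriptor(spec)  # outermost radius 24 > 8


class TestFourierFeatures:
    def test_concatenation_order_and_lengths(self, rng):
        img = random_gray(rng, (64, 64))
        circ = fourier_features(img, "circular")
        both = fourier_features(img, "circular+angular")
        assert len(circ) == 31 and len(both) == 31 + 64
        assert np.array_equal(both[:31], circ)

    def test_transformer_rejects_mixed_sizes(self, rng):
        est = FourierDescriptor(mode="circular")
        with pytest.raises(ValueError, match="mixed"):
            est.transform([random_gray(rng, (64, 64)), random_gray(rng, (32, 32))])

    def test_transformer_stacks_rows(self, rng):
        imgs = [random_gray(rng, (64, 64)) for _ in range(3)]
        out = FourierDescriptor(mode="circular+angular").fit(imgs).transform(imgs)
        assert out.shape == (3, 31 + 64)
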