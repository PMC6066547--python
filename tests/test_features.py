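"""Image-parameter extraction against definition-level oracles."""

import numpy as np
import pandas as pd
import pytest

from rivalmix.features import (
    EXTENDED_FEATURES,
    color_stats,
    extract_extended,
    extract_features,
    gradient_energy,
    local_contrast,
    select_least_correlated,
    spectral_band_energy,
    weighted_intensity_stats,
)
from tests.conftest import random_image


def luma(img):
    return img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114


class TestWeightedIntensityStats:
    def test_all_white(self):
        lum, con = weighted_intensity_stats(np.full((4, 4, 3), 255, np.uint8))
        assert lum == pytest.approx(255.0)
        assert con == pytest.approx(0.0)

    def test_pure_green(self):
        img = np.zeros((4, 4, 3), np.uint8)
        img[..., 1] = 255
        lum, con = weighted_intensity_stats(img)
        assert lum == pytest.approx(0.587 * 255)
        assert con == pytest.approx(0.0)

    def test_two_point_grays(self):
        img = np.zeros((2, 4, 3), np.uint8)
        img[0] = 255
        lum, con = weighted_intensity_stats(img)
        assert lum == pytest.approx(127.5)
        assert con == pytest.approx(127.5)


class TestGradientEnergy:
    def test_constant_zero(self):
        img = np.full((6, 6, 3), 42, np.uint8)
        for axis in ("horizontal", "vertical", "both"):
            assert gradient_energy(img, axis) == 0.0

    def test_horizontal_ramp(self):
        # gray ramp with step 10 along width on a 5x4 grid
        ramp = np.arange(4) * 10
        img = np.repeat(np.tile(ramp, (5, 1))[:, :, None], 3, axis=2).astype(np.uint8)
        assert gradient_energy(img, "horizontal") == pytest.approx(5 * 3 * 10**2)
        assert gradient_energy(img, "vertical") == pytest.approx(0.0)

    def test_random_against_bruteforce(self, rng):
        img = random_image(rng, 3, 3)
        y = luma(img.astype(float))
        h = sum(
            (y[i, j + 1] - y[i, j]) ** 2 for i in range(3) for j in range(2)
        )
        v = sum(
            (y[i + 1, j] - y[i, j]) ** 2 for i in range(2) for j in range(3)
        )
        assert gradient_energy(img, "horizontal") == pytest.approx(h, rel=1e-12)
        assert gradient_energy(img, "vertical") == pytest.approx(v, rel=1e-12)
        assert gradient_energy(img, "both") == pytest.approx(h + v, rel=1e-12)


class TestSpectralBandEnergy:
    def test_constant_dc_only(self):
        img = np.full((6, 8, 3), 10, np.uint8)
        c = luma(img.astype(float))[0, 0]
        assert spectral_band_energy(img, "low") == pytest.approx(c * 48, rel=1e-12)
        assert spectral_band_energy(img, "high") == pytest.approx(0.0, abs=1e-9)

    def test_checkerboard_all_high(self):
        # zero-mean +/-a checkerboard: single coefficient at the Nyquist corner
        board = 100 + 50 * ((-1.0) ** (np.add.outer(np.arange(4), np.arange(4))))
        img = np.repeat(board[:, :, None], 3, axis=2).astype(np.uint8)
        total_ac = spectral_band_energy(img, "high")
        assert spectral_band_energy(img, "low") == pytest.approx(
            abs(np.fft.fft2(luma(img.astype(float)))[0, 0]), rel=1e-12
        )
        assert total_ac > 0

    def test_random_against_dft_definition_oracle(self, rng):
        img = random_image(rng, 8, 8, high=16)
        y = luma(img.astype(float))
        h, w = y.shape
        # O(n^4) DFT by the definition sum, plus an independent band mask
        low = high = 0.0
        for u in range(h):
            for v in range(w):
                s = 0.0
                for m in range(h):
                    for n in range(w):
                        s += y[m, n] * np.exp(-2j * np.pi * (u * m / h + v * n / w))
                fu = (u if u <= h // 2 else u - h) / (h / 2)
                fv = (v if v <= w // 2 else v - w) / (w / 2)
                r = np.hypot(fu, fv)
                if r <= 0.25:
                    low += abs(s)
                if r >= 0.75:
                    high += abs(s)
        assert abs(spectral_band_energy(img, "low") - low) < 1e-9
        assert abs(spectral_band_energy(img, "high") - high) < 1e-9


class TestColorStats:
    def test_grayscale_has_no_chroma(self, rng):
        g = rng.integers(0, 256, (5, 5, 1))
        img = np.repeat(g, 3, axis=2).astype(np.uint8)
        colorfulness, saturation, *_ = color_stats(img)
        assert colorfulness == pytest.approx(0.0, abs=1e-9)
        assert saturation == pytest.approx(0.0)

    def test_pure_red_saturation(self):
        img = np.zeros((4, 4, 3), np.uint8)
        img[..., 0] = 255
        _, saturation, r, g, b = color_stats(img)
        assert saturation == pytest.approx(255.0)
        assert (r, g, b) == (255.0, 0.0, 0.0)

    def test_black_pixels_define_saturation_zero(self):
        img = np.zeros((4, 4, 3), np.uint8)
        _, saturation, *_ = color_stats(img)
        assert saturation == 0.0

    def test_yiq_magnitude_against_matrix_oracle(self):
        img = np.full((2, 2, 3), 0, np.uint8)
        img[..., 0], img[..., 1], img[..., 2] = 100, 50, 200
        M = np.array([[0.596, -0.274, -0.322], [0.211, -0.523, 0.312]])
        iq = M @ np.array([100.0, 50.0, 200.0])
        expected = 4 * np.sqrt(iq @ iq)  # 4 identical pixels
        colorfulness, *_ = color_stats(img)
        assert colorfulness == pytest.approx(expected, rel=1e-12)


class TestLocalContrast:
    def test_constant_zero(self):
        assert local_contrast(np.full((8, 8, 3), 9, np.uint8), 4) == 0.0

    def test_blockwise_constant_zero(self):
        img = np.zeros((8, 8, 3), np.uint8)
        img[:4, 4:] = 60
        img[4:, :4] = 120
        img[4:, 4:] = 200
        assert local_contrast(img, 4) == 0.0

    def test_random_against_per_block_loop(self, rng):
        img = random_image(rng, 8, 8)
        y = luma(img.astype(float))
        stds = [
            np.std(y[i : i + 4, j : j + 4])
            for i in (0, 4)
            for j in (0, 4)
        ]
        assert local_contrast(img, 4) == pytest.approx(np.mean(stds), rel=1e-12)

    def test_tile_out_of_range(self, rng):
        with pytest.raises(ValueError):
            local_contrast(random_image(rng, 8, 8), 9)


class TestAssembly:
    def test_constant_gray_zeros(self):
        vec = extract_extended(np.full((16, 16, 3), 128, np.uint8))
        for name in ("gradient", "global_contrast", "colorfulness", "saturation",
                     "local_contrast", "high_frequencies"):
            assert getattr(vec, name) == pytest.approx(0.0, abs=1e-9)

    def test_deterministic(self, rng):
        img = random_image(rng, 16, 16)
        assert extract_features(img) == extract_features(img.copy())

    def test_gradient_additivity(self, rng):
        vec = extract_extended(random_image(rng, 16, 16))
        assert vec.gradient == pytest.approx(
            vec.horizontal_gradient + vec.vertical_gradient, rel=1e-12
        )

    def test_scale_property(self, rng):
        base = random_image(rng, 16, 16, high=64)
        scaled = (base.astype(float) * 3).astype(np.uint8)
        f1, f3 = extract_extended(base), extract_extended(scaled)
        assert f3.gradient == pytest.approx(9 * f1.gradient, rel=1e-9)
        assert f3.low_frequencies == pytest.approx(3 * f1.low_frequencies, rel=1e-9)
        assert f3.high_frequencies == pytest.approx(3 * f1.high_frequencies, rel=1e-9)

    def test_transposition_swaps_directional_gradients_only(self, rng):
        img = random_image(rng, 12, 12)
        t = np.transpose(img, (1, 0, 2))
        a, b = extract_extended(img), extract_extended(t)
        assert a.horizontal_gradient == pytest.approx(b.vertical_gradient, rel=1e-12)
        assert a.vertical_gradient == pytest.approx(b.horizontal_gradient, rel=1e-12)
        for name in EXTENDED_FEATURES:
            if name in ("horizontal_gradient", "vertical_gradient"):
                continue
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-9)


class TestSelectLeastCorrelated:
    def test_duplicated_features_yield_one_per_copy_pair(self, rng):
        base = {f"f{i}": rng.normal(size=40) for i in range(6)}
        table = dict(base, **{f"c{i}": base[f"f{i}"].copy() for i in range(6)})
        selected, flagged = select_least_correlated(pd.DataFrame(table), 6)
        assert not flagged
        for i in range(6):
            assert (f"f{i}" in selected) != (f"c{i}" in selected)

    def test_k_equals_all(self, rng):
        table = pd.DataFrame({f"f{i}": rng.normal(size=10) for i in range(4)})
        selected, _ = select_least_correlated(table, 4)
        assert sorted(selected) == [f"f{i}" for i in range(4)]

    def test_negated_pair_k1(self, rng):
        x = rng.normal(size=20)
        selected, _ = select_least_correlated(pd.DataFrame({"a": x, "b": -x}), 1)
        assert len(selected) == 1

    def test_constant_column_flagged(self, rng):
        table = pd.DataFrame(
            {"a": rng.normal(size=15), "b": rng.normal(size=15),
             "c": np.ones(15)}
        )
        selected, flagged = select_least_correlated(table, 2)
        assert flagged == ["c"]
        assert "c" not in selected
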