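import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agnospec import (
    HistogramConfig,
    Peak,
    Spectrum,
    abundance_coordinate,
    bin_counts,
    featurize_spectrum,
    flatten,
    log_transform,
    normalize_counts,
)
from .conftest import random_spectrum
from .oracles import brute_force_feature_image

CFG = HistogramConfig()


class TestAbundanceCoordinate:
    def test_mean_log_peak_lands_at_offset_over_scale(self):
        a = 123.4
        assert abundance_coordinate(a, math.log(a)) == pytest.approx(0.5 / 9.2)

    def test_midpoint_and_top_of_range(self):
        # ln(a) - mean = 4.1 -> y = 0.5; ln(a) - mean = 8.7 -> y = 1.0
        assert abundance_coordinate(math.exp(4.1), 0.0) == pytest.approx(0.5)
        assert abundance_coordinate(math.exp(8.7), 0.0) == pytest.approx(1.0)

    def test_rejects_nonpositive_intensity(self):
        with pytest.raises(ValueError):
            abundance_coordinate(0.0, 0.0)


class TestBinning:
    def test_empty_spectrum_gives_zero_tensor(self):
        n = bin_counts(Spectrum("e", []), CFG)
        assert n.shape == (32, 32, 5) and n.sum() == 0

    def test_first_mass_bin_and_width(self):
        # bins of width 18.75 Da over [150, 750]
        assert CFG.mz_bin_width == 18.75
        n = bin_counts(Spectrum("one", [Peak(150.0, 1.0)]), CFG)
        i, j, k = np.argwhere(n)[0]
        assert i == 0
        n2 = bin_counts(Spectrum("two", [Peak(168.76, 1.0)]), CFG)
        assert np.argwhere(n2)[0][0] == 1

    def test_five_peak_hand_case_matches_brute_force(self):
        s = Spectrum(
            "hand",
            [
                Peak(150.0, 10.0),
                Peak(300.5, 1000.0),
                Peak(300.6, 999.0),
                Peak(555.5, 5.0),
                Peak(750.0, 80.0),
            ],
        )
        counts, _ = brute_force_feature_image(s, CFG)
        assert np.array_equal(bin_counts(s, CFG), np.array(counts))

    def test_out_of_window_peaks_do_not_count(self):
        s = Spectrum("out", [Peak(149.0, 10.0), Peak(200.0, 10.0), Peak(751.0, 10.0)])
        assert bin_counts(s, CFG).sum() == 1

    def test_count_conservation_on_random_spectra(self):
        rng = np.random.default_rng(11)
        s = random_spectrum(rng, 500)
        n = bin_counts(s, CFG)
        mean_log = float(np.mean(np.log(s.intensity)))
        y = (np.log(s.intensity) - mean_log + 0.5) / 9.2
        in_window = (s.mz >= 150) & (s.mz <= 750) & (y >= 0) & (y <= 1)
        assert n.sum() == in_window.sum()


class TestNormalize:
    def test_mass_column_normalization(self):
        cfg = HistogramConfig(n_mz_bins=3, n_abund_bins=1, n_kmd_bins=1)
        n = np.array([2, 0, 3]).reshape(3, 1, 1)
        N = normalize_counts(n, cfg)
        assert N[:, 0, 0] == pytest.approx([0.4, 0.0, 0.6], abs=1e-8)
        assert N.sum() == pytest.approx(1.0, abs=1e-8)

    def test_zero_column_stays_zero(self):
        N = normalize_counts(np.zeros(CFG.shape, dtype=int), CFG)
        assert np.all(N == 0.0)

    def test_nonzero_columns_sum_just_below_one(self):
        rng = np.random.default_rng(3)
        n = rng.integers(0, 20, CFG.shape)
        N = normalize_counts(n, CFG)
        tot = n.sum(axis=0)
        expected = tot / (tot + CFG.eps)
        assert N.sum(axis=0) == pytest.approx(expected)
        assert np.all(N.sum(axis=0) < 1.0)


class TestLogTransform:
    def test_floor_and_ceiling_values(self):
        assert log_transform(np.zeros(CFG.shape), CFG).flat[0] == pytest.approx(
            0.5 * math.log(0.1) + 1.25
        )
        top = log_transform(np.ones(CFG.shape), CFG).flat[0]
        assert top == pytest.approx(0.5 * math.log(1.1) + 1.25)
        assert top <= 1.3

    def test_monotone_in_normalized_value(self):
        cfg = HistogramConfig(n_mz_bins=1, n_abund_bins=1, n_kmd_bins=1)
        grid = np.linspace(0, 1, 101)
        vals = [log_transform(np.full(cfg.shape, g), cfg).item() for g in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_rejects_out_of_range_input(self):
        with pytest.raises(ValueError):
            log_transform(np.full(CFG.shape, 1.5), CFG)


class TestFeaturizePipeline:
    def test_empty_spectrum_gives_constant_floor_image(self):
        img = featurize_spectrum(Spectrum("e", []), CFG)
        assert img.n_peaks_used == 0
        assert np.allclose(img.values, 0.5 * math.log(0.1) + 1.25)

    def test_deterministic_for_identical_input(self):
        rng = np.random.default_rng(5)
        s = random_spectrum(rng, 300)
        a = featurize_spectrum(s, CFG)
        b = featurize_spectrum(Spectrum(s.sample_id, list(s.peaks)), CFG)
        assert np.array_equal(a.values, b.values)

    def test_values_within_transform_bounds(self):
        rng = np.random.default_rng(6)
        img = featurize_spectrum(random_spectrum(rng, 2000), CFG)
        assert img.values.min() >= 0.09871 - 1e-5
        assert img.values.max() <= 1.29766 + 1e-5

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=10, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = random_spectrum(rng, int(rng.integers(0, 800)))
        img = featurize_spectrum(s, CFG)
        counts, values = brute_force_feature_image(s, CFG)
        assert np.array_equal(img.counts, np.array(counts))
        np.testing.assert_allclose(img.values, np.array(values), rtol=0, atol=1e-12)

    @given(st.integers(0, 2**31 - 1),
           st.floats(min_value=1e-4, max_value=1e4))
    @settings(derandomize=True, max_examples=15, deadline=None)
    def test_intensity_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        s = random_spectrum(rng, 200)
        scaled = Spectrum(
            s.sample_id, [Peak(p.mz, p.intensity * scale) for p in s.peaks]
        )
        a, b = featurize_spectrum(s, CFG), featurize_spectrum(scaled, CFG)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.values, b.values)


class TestFlatten:
    def test_default_length_is_5120(self):
        img = featurize_spectrum(Spectrum("e", []), CFG)
        assert flatten(img).shape == (5120,)

    def test_flatten_reshape_inverse(self):
        rng = np.random.default_rng(9)
        img = featurize_spectrum(random_spectrum(rng, 400), CFG)
        assert np.array_equal(flatten(img).reshape(CFG.shape), img.values)

    def test_toy_config_product_rule_and_order(self):
        cfg = HistogramConfig(n_mz_bins=4, n_abund_bins=4, n_kmd_bins=2)
        tensor = np.arange(32).reshape(cfg.shape)
        vec = flatten(tensor)
        assert vec.shape == (32,)
        # mass-major: KMD index varies fastest
        assert vec[0] == tensor[0, 0, 0] and vec[1] == tensor[0, 0, 1]
        assert vec[2] == tensor[0, 1, 0]
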