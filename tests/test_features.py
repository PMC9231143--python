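import math

import numpy as np
import pytest

from mmgforce import DataError, FeatureError
from mmgforce import features as F
from mmgforce.signal_prep import WindowSample
from oracles import (
    apen_direct,
    lz76_parse,
    sampen_direct,
    ssc_enumeration,
    zc_enumeration,
)

FS = 1000.0


def sine(freq, n=1000, fs=FS, amp=1.0, phase=0.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


class TestTimeDomain:
    def test_sine_rms_and_mav(self):
        vals = F.time_domain(sine(10.0))
        assert vals["RMS"] == pytest.approx(1 / math.sqrt(2), abs=1e-3)
        assert vals["MAV"] == pytest.approx(2 / math.pi, abs=2e-3)

    def test_alternating_sequence_counts(self):
        x = np.tile([1.0, -1.0], 500)
        vals = F.time_domain(x)
        assert vals["ZC"] == 999
        assert vals["WL"] == pytest.approx(2.0 * 999)

    def test_zc_ssc_match_enumeration_on_sine(self):
        x = sine(10.0)
        vals = F.time_domain(x)
        assert vals["ZC"] == zc_enumeration(x)
        assert vals["SSC"] == ssc_enumeration(x)

    def test_zc_ssc_match_enumeration_on_random_signs(self, rng):
        """Exact agreement with the brute-force count, including the
        zero-treated-as-positive convention."""
        for _ in range(20):
            x = rng.choice([-1.0, 0.0, 1.0], size=200)
            if np.all(x == x[0]):
                continue
            vals = F.time_domain(x)
            assert vals["ZC"] == zc_enumeration(x)
            assert vals["SSC"] == ssc_enumeration(x)
            x2 = rng.normal(size=300)
            v2 = F.time_domain(x2)
            assert v2["ZC"] == zc_enumeration(x2)
            assert v2["SSC"] == ssc_enumeration(x2)

    def test_gaussian_kurtosis_near_three(self, rng):
        x = rng.standard_normal(100_000)
        assert F.time_domain(x)["kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_constant_window_rejected(self):
        with pytest.raises(FeatureError):
            F.time_domain(np.ones(100))


class TestFreqDomain:
    def test_pure_sine_centroid_and_median(self):
        vals = F.freq_domain(sine(10.0), FS)
        assert vals["MPF"] == pytest.approx(10.0, abs=0.5)
        assert vals["MDF"] == pytest.approx(10.0, abs=0.5)

    def test_two_tone_centroid(self):
        x = sine(10.0) + sine(30.0)
        assert F.freq_domain(x, FS)["MPF"] == pytest.approx(20.0, abs=1.0)

    def test_white_noise_centroid_near_quarter_fs(self, rng):
        x = rng.standard_normal(100_000)
        assert F.freq_domain(x, FS)["MPF"] == pytest.approx(250.0, rel=0.1)

    def test_all_zero_rejected(self):
        with pytest.raises(FeatureError):
            F.freq_domain(np.zeros(1000), FS)


class TestWaveletPacket:
    def test_total_energy_is_sum_of_bands(self, rng):
        vals = F.wavelet_packet(rng.standard_normal(1000))
        bands = sum(vals[f"WP{i}"] for i in range(1, 9))
        assert vals["WPE"] == pytest.approx(bands, rel=1e-12)

    def test_low_frequency_sine_in_first_band(self):
        vals = F.wavelet_packet(sine(20.0))  # node width 62.5 Hz at 1 kHz
        assert vals["WP1"] / vals["WPE"] > 0.8

    def test_white_noise_splits_evenly(self, rng):
        fracs = np.zeros(8)
        n_windows = 100
        for _ in range(n_windows):
            vals = F.wavelet_packet(rng.standard_normal(1000))
            fracs += [vals[f"WP{i}"] / vals["WPE"] for i in range(1, 9)]
        fracs /= n_windows
        np.testing.assert_allclose(fracs, 0.125, atol=0.05)

    def test_short_input_rejected(self):
        with pytest.raises(DataError):
            F.wavelet_packet(np.zeros(32))


class TestLempelZiv:
    def test_alternating_square_wave_parse(self):
        x = np.tile([1.0, -1.0], 500)
        s = F.binarize_median(x)
        assert F.lz76_complexity(s) == lz76_parse(s) == 3

    def test_matches_independent_parser_on_random_strings(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 200))
            s = "".join(rng.choice(["0", "1"], size=n))
            assert F.lz76_complexity(s) == lz76_parse(s)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(500)
        assert F.lempel_ziv(3.7 * x) == F.lempel_ziv(x)


class TestEntropies:
    def test_sampen_matches_direct_definition(self, rng):
        for _ in range(10):
            x = rng.standard_normal(300)
            assert F.sample_entropy(x) == pytest.approx(
                sampen_direct(x), abs=1e-10
            )

    def test_apen_matches_direct_definition(self, rng):
        for _ in range(10):
            x = rng.standard_normal(300)
            assert F.approximate_entropy(x) == pytest.approx(
                apen_direct(x), abs=1e-10
            )

    def test_white_noise_sampen_reference_value(self):
        """SampEn(2, 0.2 SD) of i.i.d. Gaussian noise at n=1000 sits near its
        published Monte-Carlo value of about 2.2."""
        vals = [
            F.sample_entropy(np.random.default_rng(s).standard_normal(1000))
            for s in range(30)
        ]
        assert np.mean(vals) == pytest.approx(2.2, abs=0.3)

    def test_periodic_signal_is_regular(self):
        x = sine(10.0, n=1000)
        assert F.sample_entropy(x) < 0.2
        assert F.approximate_entropy(x) < 0.25

    def test_entropy_ordering_noise_above_sine(self):
        """SampEn separates noise from a matched-SD sine (50 seeds)."""
        wins = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            noise = rng.standard_normal(500)
            tone = sine(10.0, n=500) * (np.std(noise) / np.std(sine(10.0, n=500)))
            wins += F.sample_entropy(noise) > F.sample_entropy(tone)
        assert wins >= 48

    def test_fuzzy_entropy_orders_like_sampen(self, rng):
        noise = rng.standard_normal(500)
        tone = sine(10.0, n=500)
        assert F.fuzzy_entropy(noise) > F.fuzzy_entropy(tone)

    def test_distribution_entropy_scale_invariant(self, rng):
        x = rng.standard_normal(500)
        assert F.distribution_entropy(5.0 * x) == pytest.approx(
            F.distribution_entropy(x), abs=1e-12
        )

    def test_constant_input_rejected(self):
        for fn in (F.sample_entropy, F.approximate_entropy, F.fuzzy_entropy,
                   F.distribution_entropy):
            with pytest.raises(FeatureError):
                fn(np.ones(200))


class TestFractalAndLyapunov:
    def test_line_graph_dimension_near_one(self):
        x = np.linspace(0.0, 1.0, 1000) + 1e-9 * np.sin(np.arange(1000))
        assert F.fractal_dimension(x) == pytest.approx(1.0, abs=0.1)

    def test_noise_rougher_than_sine(self):
        """Box-counting dimension of white noise exceeds a sine's (50 seeds)."""
        wins = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            wins += F.fractal_dimension(rng.standard_normal(1000)) > (
                F.fractal_dimension(sine(10.0, phase=rng.uniform(0, np.pi)))
            )
        assert wins >= 48

    def test_lyapunov_finite_on_band_limited_noise(self, rng):
        from mmgforce.signal_prep import bandpass_mmg

        x = bandpass_mmg(rng.standard_normal(2000), FS)[500:1500]
        val = F.largest_lyapunov(x)
        assert math.isfinite(val)

    def test_apen_of_near_constant_is_small(self, rng):
        x = 1.0 + 1e-6 * rng.standard_normal(300)
        assert F.approximate_entropy(x, r=0.2) < 0.05


class TestScaleBehaviour:
    def test_feature_scaling_contract(self, rng):
        """Multiplying a window by c > 0 scales amplitude features by c,
        energies by c^2, and leaves shape/location features unchanged."""
        x = rng.standard_normal(1000)
        c = 3.5
        a = F.extract_window(x, FS)
        b = F.extract_window(c * x, FS)
        for name in ("RMS", "SD", "MAV", "WL"):
            assert b[name] == pytest.approx(c * a[name], rel=1e-9)
        for name in ("kurtosis", "ZC", "SSC", "MPF", "MDF", "LZC", "DistEn"):
            assert b[name] == pytest.approx(a[name], rel=1e-9)
        for name in ("WPE", "WP1", "WP4", "WP8"):
            assert b[name] == pytest.approx(c**2 * a[name], rel=1e-9)


class TestAssembly:
    def test_three_channel_window_has_75_features(self, rng):
        w = WindowSample(rng.standard_normal((3, 1000)), 50.0, 0)
        fm = F.extract_all([w], FS, channel_labels=("RF", "VL", "VM"))
        assert fm.features.shape == (1, 75)
        assert fm.columns[0] == "RF_RMS"
        assert fm.columns[25] == "VL_RMS"

    def test_single_channel_window_has_25_features(self, rng):
        w = WindowSample(rng.standard_normal((1, 1000)), 50.0, 0)
        fm = F.extract_all([w], FS)
        assert fm.features.shape == (1, 25)

    def test_column_order_deterministic(self, rng):
        w = WindowSample(rng.standard_normal((3, 1000)), 50.0, 0)
        a = F.extract_all([w], FS, channel_labels=("RF", "VL", "VM"))
        b = F.extract_all([w], FS, channel_labels=("RF", "VL", "VM"))
        assert a.columns == b.columns
        assert a.columns == F.feature_names(("RF", "VL", "VM"))

    def test_error_carries_window_index(self):
        good = WindowSample(np.random.default_rng(0).standard_normal((1, 1000)),
                            1.0, 0)
        bad = WindowSample(np.ones((1, 1000)), 1.0, 0)
        with pytest.raises(FeatureError, match="window 1"):
            F.extract_all([good, bad], FS)

    def test_csv_round_trip(self, tmp_path, small_feature_matrix):
        path = tmp_path / "features.csv"
        small_feature_matrix.to_csv(path)
        back = F.FeatureMatrix.from_csv(path)
        assert back.columns == small_feature_matrix.columns
        np.testing.assert_allclose(back.force, small_feature_matrix.force)
        np.testing.assert_allclose(
            back.features.to_numpy(),
            small_feature_matrix.features.to_numpy(),
            rtol=1e-12,
        )

    def test_dataset_extraction_caps_windows_per_level(self, small_dataset):
        fm = F.extract_dataset(
            small_dataset, groups=("time",), windows_per_level=10
        )
        assert len(fm) == 8 * 10
        counts = fm.provenance.groupby("level").size()
        assert (counts == 10).all()
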