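"""Filtering, segmentation, resampling and standardization contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from sozdetect import (
    MultiChannelRecording,
    bandpass,
    binarize_labels,
    resample_window,
    segment,
    select_channels,
    standardize,
)
from sozdetect.montage import CANONICAL_SITES
from sozdetect.preprocess import (
    PreprocessConfig,
    _FILTER_ORDER,
    fit_column_stats,
    standardize_set,
)


def _single(data, sr=256.0, name="Cz"):
    return MultiChannelRecording(
        channel_names=[name], sampling_rate=sr, data=data[None, :]
    )


def _mid_amplitude(x):
    mid = x[len(x) // 4 : 3 * len(x) // 4]
    return np.abs(mid).max()


class TestBandpass:
    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(0, 20, 1 / 256)
        out = bandpass(_single(np.sin(2 * np.pi * 50 * t))).data[0]
        assert _mid_amplitude(out) <= 0.1

    def test_passband_sinusoid_preserved(self):
        t = np.arange(0, 20, 1 / 256)
        out = bandpass(_single(np.sin(2 * np.pi * 10 * t))).data[0]
        assert 0.9 <= _mid_amplitude(out) <= 1.1

    def test_dc_removed(self):
        out = bandpass(_single(np.ones(256 * 20))).data[0]
        assert _mid_amplitude(out) <= 0.1

    def test_designed_response_bounds(self):
        """Effective (zero-phase) response: <= -20 dB at DC and 50 Hz, +-1 dB in 2-30 Hz."""
        sos = sps.butter(
            _FILTER_ORDER, [0.53, 40.0], btype="bandpass", fs=256.0, output="sos"
        )
        freqs, h = sps.sosfreqz(sos, worN=8192, fs=256.0)
        mag_db = 2 * 20 * np.log10(np.maximum(np.abs(h), 1e-12))  # forward-backward
        assert mag_db[0] <= -20.0
        assert mag_db[np.argmin(np.abs(freqs - 50.0))] <= -20.0
        band = (freqs >= 2.0) & (freqs <= 30.0)
        assert np.all(np.abs(mag_db[band]) <= 1.0)

    def test_invalid_band_edges(self):
        rec = _single(np.zeros(512))
        with pytest.raises(ValueError):
            bandpass(rec, low=0.53, high=200.0)
        with pytest.raises(ValueError):
            bandpass(rec, low=45.0, high=40.0)


class TestSelectChannels:
    def _recording(self, names, sr=256.0, n=512, seed=0):
        rng = np.random.default_rng(seed)
        return MultiChannelRecording(
            channel_names=list(names), sampling_rate=sr,
            data=rng.standard_normal((len(names), n)),
        )

    def test_aux_channels_dropped(self):
        rec = self._recording(list(CANONICAL_SITES) + ["T1", "T2", "ECG", "EMG"])
        out = select_channels(rec)
        assert out.channel_names == list(CANONICAL_SITES)
        assert out.data.shape[0] == 21

    def test_missing_site_is_named_in_error(self):
        names = [s for s in CANONICAL_SITES if s != "Pz"]
        with pytest.raises(ValueError, match="Pz"):
            select_channels(self._recording(names))

    def test_order_normalized(self):
        shuffled = list(CANONICAL_SITES)[::-1]
        rec = self._recording(shuffled)
        out = select_channels(rec)
        assert out.channel_names == list(CANONICAL_SITES)
        np.testing.assert_array_equal(out.data[0], rec.data[shuffled.index("Fp1")])


class TestSegment:
    def test_4097_samples_make_23_windows_of_178(self):
        wins = segment(np.arange(4097, dtype=float), sampling_rate=178, window_seconds=1)
        assert wins.shape == (23, 178)

    def test_exact_division(self):
        wins = segment(np.zeros(7680), sampling_rate=256, window_seconds=1)
        assert wins.shape == (30, 256)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            segment(np.zeros(100), sampling_rate=178, window_seconds=1)

    @given(st.integers(min_value=178, max_value=2000))
    @settings(derandomize=True, max_examples=25)
    def test_conserves_samples(self, n):
        x = np.arange(n, dtype=float)
        wins = segment(x, sampling_rate=178, window_seconds=1)
        np.testing.assert_array_equal(wins.ravel(), x[: wins.size])
        assert wins.shape[0] == n // 178


class TestResample:
    def test_256_to_178(self):
        assert resample_window(np.random.default_rng(0).standard_normal(256)).shape == (178,)

    def test_identity_when_lengths_match(self):
        x = np.random.default_rng(1).standard_normal(178)
        np.testing.assert_array_equal(resample_window(x), x)

    def test_in_band_frequency_preserved(self):
        t = np.arange(0, 4, 1 / 256)
        x = np.sin(2 * np.pi * 5 * t)
        out = np.concatenate([
            resample_window(w) for w in x.reshape(4, 256)
        ])
        freqs = np.fft.rfftfreq(out.size, d=1 / 178)
        power = np.abs(np.fft.rfft(out)) ** 2
        power[0] = 0
        assert abs(freqs[np.argmax(power)] - 5.0) <= 0.5

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            resample_window(np.array([1.0]))


class TestStandardize:
    def test_small_example(self):
        res = standardize(np.array([1.0, 2.0, 3.0]))
        assert abs(res.x_prime.mean()) < 1e-12
        assert abs(res.x_prime.std() - 1.0) < 1e-12
        assert res.mu == 2.0

    def test_flat_window_maps_to_zeros(self):
        res = standardize(np.full(10, 5.0))
        np.testing.assert_array_equal(res.x_prime, np.zeros(10))
        assert res.sigma == 0.0

    @given(
        st.lists(
            st.floats(min_value=-1e4, max_value=1e4, allow_nan=False),
            min_size=2, max_size=200,
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_idempotent_and_unit_variance(self, values):
        x = np.asarray(values)
        once = standardize(x).x_prime
        twice = standardize(once).x_prime
        np.testing.assert_allclose(twice, once, atol=1e-9)
        if x.std() > 1e-6 * (1 + np.abs(x).max()):
            assert abs(once.mean()) < 1e-9
            assert abs(once.var() - 1.0) < 1e-6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            standardize(np.array([]))

    def test_per_column_mode_uses_frozen_stats(self):
        rng = np.random.default_rng(0)
        train = rng.standard_normal((50, 178)) * 3 + 1
        config = fit_column_stats(train, PreprocessConfig(standardization="per_column"))
        out = standardize_set(train, config)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-9)


class TestBinarize:
    def test_mapping(self):
        np.testing.assert_array_equal(
            binarize_labels(np.array([1, 2, 3, 4, 5])), [1, 0, 0, 0, 0]
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(binarize_labels(np.ones(5, dtype=int)), np.ones(5))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            binarize_labels(np.array([1, 6]))
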