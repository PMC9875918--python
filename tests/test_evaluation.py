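"""Lagged correlation, flattening, spectrograms, band power and tSNR."""

import numpy as np
import pytest

from conftest import make_subtr
from prepair.data import AcquisitionParams, EpiSeries, VoxelMask
from prepair.errors import ConfigurationError
from prepair.evaluate import (
    aliased_band_bins,
    band_power_proportion,
    flatten_to_subtr,
    harmonic_band_present,
    lagged_correlation,
    out_of_band_fluctuation,
    sliding_spectrogram,
    tsnr_gain,
)


class TestLaggedCorrelation:
    def test_identical_signals(self):
        x = np.sin(np.linspace(0, 40, 600))
        corr, lag = lagged_correlation(x, x, rate=6.0)
        assert corr == pytest.approx(1.0)
        assert lag == 0.0

    def test_known_delay_recovered(self):
        rate = 10.0
        t = np.arange(1200) / rate
        a = np.sin(2 * np.pi * 0.5 * t)
        b = np.sin(2 * np.pi * 0.5 * (t - 0.3))
        # |corr| of two sinusoids peaks every half period (1 s); keep the
        # search window tight enough that only the true delay fits
        corr, lag = lagged_correlation(a, b, rate, max_lag=0.45)
        assert abs(corr) == pytest.approx(1.0, abs=0.01)
        assert abs(lag - 0.3) <= 1.0 / rate

    @pytest.mark.parametrize("seed", range(20))
    def test_independent_noise_stays_weak(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=2000)
        b = rng.normal(size=2000)
        corr, _ = lagged_correlation(a, b, rate=6.0)
        assert abs(corr) < 0.3


class TestFlatten:
    def _series(self, data):
        nx, ny, n, nr = data.shape
        p = AcquisitionParams(tr_vol=1.0, n_slices=n, n_reps=nr)
        return EpiSeries(magnitude=data, params=p), p

    def test_uniform_volumes_give_constant_series(self):
        data = np.full((3, 3, 2, 10), 4.5)
        series, p = self._series(data)
        sub = flatten_to_subtr(series, p, VoxelMask(np.ones((3, 3, 2),
                                                            dtype=bool)))
        assert np.allclose(sub.samples, 4.5, atol=1e-12)
        assert len(sub) == 10 * 2

    def test_matches_average_then_interleave_oracle(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(1, 5, (2, 2, 3, 4))
        series, p = self._series(data)
        sub = flatten_to_subtr(series, p, VoxelMask(np.ones((2, 2, 3),
                                                            dtype=bool)))
        oracle = []
        for v in range(4):
            for z in range(3):
                oracle.append(data[:, :, z, v].mean())
        assert np.allclose(sub.samples, oracle, atol=1e-12)


class TestSpectrogram:
    def test_stationary_ridge(self):
        rate = 6.0
        t = np.arange(int(120 * rate)) / rate
        sig = make_subtr(np.sin(2 * np.pi * 0.3 * t), rate)
        spec = sliding_spectrogram(sig)
        ridge = spec.freqs[np.argmax(spec.power, axis=0)]
        assert np.allclose(ridge, 0.3, atol=0.05)
        peaks = spec.power.max(axis=0)
        assert peaks.std() / peaks.mean() < 0.10

    def test_chirp_ridge_increases(self):
        rate = 6.0
        t = np.arange(int(200 * rate)) / rate
        from scipy.signal import chirp

        sig = make_subtr(chirp(t, f0=0.2, f1=0.3, t1=t[-1]), rate)
        spec = sliding_spectrogram(sig)
        ridge = spec.freqs[np.argmax(spec.power, axis=0)]
        assert ridge[-1] > ridge[0]
        # monotone up to estimator quantization
        assert np.sum(np.diff(ridge) < -0.02) == 0

    def test_window_count_formula(self):
        rate = 6.0
        sig = make_subtr(np.random.default_rng(0).normal(size=int(300 * rate)),
                         rate)
        spec = sliding_spectrogram(sig, window=45.0, step=4.0)
        assert spec.power.shape[1] == (300 - 45) // 4 + 1 == 64

    def test_short_signal_rejected(self):
        sig = make_subtr(np.zeros(60), 6.0)
        with pytest.raises(ConfigurationError, match="smaller window"):
            sliding_spectrogram(sig)


def toy_4d(nr=200, tr=1.0, amp_fn=None, seed=0):
    """Small 4D array: constant background + optional per-voxel sinusoid."""
    rng = np.random.default_rng(seed)
    data = np.full((2, 2, 2, nr), 100.0) + rng.normal(0, 0.5, (2, 2, 2, nr))
    t = np.arange(nr) * tr
    if amp_fn is not None:
        for idx in np.ndindex(2, 2, 2):
            data[idx] += amp_fn(idx, t)
    params = AcquisitionParams(tr_vol=tr, n_slices=2, n_reps=nr)
    return data, params, VoxelMask(np.ones((2, 2, 2), dtype=bool))


class TestBandPower:
    BAND = [(0.2, 0.3)]

    def test_no_change_gives_zero(self):
        data, params, mask = toy_4d()
        out = band_power_proportion(data, data, params, mask, self.BAND)
        assert out.overall == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(out.per_slice, 0.0, atol=1e-12)

    def test_total_removal_near_one(self):
        sine = lambda idx, t: 3.0 * np.sin(2 * np.pi * 0.25 * t)
        before, params, mask = toy_4d(amp_fn=sine)
        after, *_ = toy_4d(amp_fn=None)
        out = band_power_proportion(before, after, params, mask, self.BAND)
        assert out.overall == pytest.approx(1.0, abs=0.02)

    def test_halved_amplitude_removes_three_quarters(self):
        before, params, mask = toy_4d(
            amp_fn=lambda i, t: 3.0 * np.sin(2 * np.pi * 0.25 * t))
        after, *_ = toy_4d(
            amp_fn=lambda i, t: 1.5 * np.sin(2 * np.pi * 0.25 * t))
        out = band_power_proportion(before, after, params, mask, self.BAND)
        assert out.overall == pytest.approx(0.75, abs=0.02)

    def test_invariant_to_global_scaling(self):
        before, params, mask = toy_4d(
            amp_fn=lambda i, t: 3.0 * np.sin(2 * np.pi * 0.25 * t))
        after, *_ = toy_4d(
            amp_fn=lambda i, t: 1.5 * np.sin(2 * np.pi * 0.25 * t))
        a = band_power_proportion(before, after, params, mask, self.BAND)
        b = band_power_proportion(7.0 * before, 7.0 * after, params, mask,
                                  self.BAND)
        assert b.overall == pytest.approx(a.overall, abs=1e-12)

    def test_aliased_band_maps_above_nyquist(self):
        # a 1.25 Hz band sampled at 1 Hz folds to 0.25 Hz
        freqs = np.fft.rfftfreq(200, 1.0)
        bins = aliased_band_bins(freqs, 1.0, [(1.2, 1.3)])
        assert freqs[bins].min() == pytest.approx(0.2, abs=0.01)
        assert freqs[bins].max() == pytest.approx(0.3, abs=0.01)


class TestOutOfBand:
    BAND = [(0.2, 0.3)]

    def test_no_change_gives_zero(self):
        data, params, mask = toy_4d()
        assert out_of_band_fluctuation(data, data, params, mask,
                                       self.BAND) == pytest.approx(0.0,
                                                                   abs=1e-12)

    def test_in_band_only_edit_leaves_out_of_band_alone(self):
        before, params, mask = toy_4d(
            amp_fn=lambda i, t: 3.0 * np.sin(2 * np.pi * 0.25 * t), seed=1)
        after, *_ = toy_4d(amp_fn=None, seed=1)
        assert abs(out_of_band_fluctuation(before, after, params, mask,
                                           self.BAND)) < 0.02

    def test_broadband_halving_detected(self):
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 1.0, (2, 2, 2, 200))
        before = 100.0 + noise
        after = 100.0 + 0.5 * noise
        params = AcquisitionParams(tr_vol=1.0, n_slices=2, n_reps=200)
        mask = VoxelMask(np.ones((2, 2, 2), dtype=bool))
        out = out_of_band_fluctuation(before, after, params, mask, self.BAND)
        assert out == pytest.approx(0.75, abs=0.02)


class TestHarmonicPresence:
    def test_visible_harmonic_detected(self):
        before, params, mask = toy_4d(
            amp_fn=lambda i, t: 2.0 * np.sin(2 * np.pi * 0.34 * t), seed=3)
        assert harmonic_band_present(before, params, mask, (0.30, 0.38))

    def test_pure_noise_band_not_detected(self):
        before, params, mask = toy_4d(seed=4)
        assert not harmonic_band_present(before, params, mask, (0.30, 0.38))


class TestTsnr:
    def test_no_change_gives_zero_gain(self):
        data, params, mask = toy_4d()
        rep = tsnr_gain(data, data, mask)
        finite = rep.gain_percent[np.isfinite(rep.gain_percent)]
        assert np.allclose(finite, 0.0, atol=1e-9)

    def test_sd_reduction_formula(self):
        rng = np.random.default_rng(6)
        nr = 4000
        noise = rng.normal(0, 1.0, nr)
        noise = (noise - noise.mean()) / noise.std()
        before = (100.0 + 5.0 * noise).reshape(1, 1, 1, nr)
        after = (100.0 + 4.0 * noise).reshape(1, 1, 1, nr)
        rep = tsnr_gain(before, after, VoxelMask(np.ones((1, 1, 1),
                                                         dtype=bool)))
        assert rep.tsnr_before[0, 0, 0] == pytest.approx(20.0)
        assert rep.tsnr_after[0, 0, 0] == pytest.approx(25.0)
        assert rep.gain_percent[0, 0, 0] == pytest.approx(25.0)

    def test_gain_sign_tracks_sd_change(self):
        rng = np.random.default_rng(7)
        before = 100.0 + rng.normal(0, 2.0, (3, 3, 1, 300))
        scale = np.linspace(0.5, 1.5, 9).reshape(3, 3, 1, 1)
        after = 100.0 + (before - 100.0) * scale
        mask = VoxelMask(np.ones((3, 3, 1), dtype=bool))
        rep = tsnr_gain(before, after, mask)
        sd_change = after.std(axis=3) - before.std(axis=3)
        assert np.all(np.sign(rep.gain_percent[sd_change != 0])
                      == -np.sign(sd_change[sd_change != 0]))

    def test_roi_summaries_have_percentiles(self):
        data, params, mask = toy_4d()
        rep = tsnr_gain(data, data, mask, rois={"blob": mask.mask})
        assert set(rep.roi_summaries["blob"]) == {"mean_gain_percent", "p25",
                                                  "p50", "p75"}
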