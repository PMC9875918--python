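"""Cycle phases, Fourier expansion, variance test and source selection."""

import numpy as np
import pytest

from conftest import make_subtr
from prepair.data import AcquisitionParams
from prepair.errors import ConfigurationError, InsufficientCyclesError
from prepair.identify import FundamentalEstimate, PhysioWaveform
from prepair.regressors import (
    CyclePhase,
    build_slicewise_regressors,
    cardiac_cycle_phase,
    detect_peaks,
    evaluate_variance_improvement,
    fourier_expansion,
    respiratory_cycle_phase,
    select_source,
)


def make_waveform(samples, rate, f0, kind="cardiac", source="magnitude"):
    samples = np.asarray(samples, dtype=float)
    est = FundamentalEstimate(f0=f0, band=(0.5 * f0, 1.5 * f0), kind=kind)
    return PhysioWaveform(samples=samples, rate=rate,
                          times=np.arange(len(samples)) / rate,
                          band=(f0 - 0.1, f0 + 0.1), kind=kind,
                          source=source, fundamental=est)


class TestDetectPeaks:
    def test_sinusoid_peak_times_and_count(self):
        rate = 50.0
        t = np.arange(int(60 * rate)) / rate
        wave = make_waveform(np.sin(2 * np.pi * t), rate, f0=1.0)
        peaks = detect_peaks(wave)
        assert len(peaks) == 60
        expected = 0.25 + np.arange(60)
        assert np.max(np.abs(peaks - expected)) <= 1.0 / (4 * rate)

    def test_amplitude_modulation_does_not_change_count(self):
        rate = 50.0
        t = np.arange(int(60 * rate)) / rate
        am = (1 + 0.5 * np.sin(2 * np.pi * 0.05 * t)) * np.sin(2 * np.pi * t)
        wave = make_waveform(am, rate, f0=1.0)
        assert len(detect_peaks(wave)) == 60

    def test_constant_signal_raises(self):
        wave = make_waveform(np.zeros(500), 50.0, f0=1.0)
        with pytest.raises(InsufficientCyclesError):
            detect_peaks(wave)


class TestCardiacCyclePhase:
    def test_midpoint_is_pi(self):
        ph = cardiac_cycle_phase(np.array([0.0, 1.0]), np.array([0.5]))
        assert ph.phi[0] == pytest.approx(np.pi)

    def test_quarter_cycle_is_half_pi(self):
        ph = cardiac_cycle_phase(np.array([0.0, 1.0, 2.0]), np.array([1.25]))
        assert ph.phi[0] == pytest.approx(np.pi / 2)

    def test_phase_resets_at_peaks(self):
        peaks = np.arange(5, dtype=float)
        ph = cardiac_cycle_phase(peaks, peaks)
        assert np.allclose(np.minimum(ph.phi, 2 * np.pi - ph.phi), 0.0,
                           atol=1e-9)

    def test_extrapolation_uses_nearest_period(self):
        ph = cardiac_cycle_phase(np.array([1.0, 2.0]), np.array([0.5, 2.5]))
        assert ph.phi[0] == pytest.approx(np.pi)  # half a period before start
        assert ph.phi[1] == pytest.approx(np.pi)

    def test_non_monotone_peaks_rejected(self):
        with pytest.raises(ConfigurationError):
            cardiac_cycle_phase(np.array([0.0, 2.0, 1.0]), np.array([0.5]))


class TestRespiratoryCyclePhase:
    def _sine_wave(self, rate=10.0, n=2000, f=0.25):
        t = np.arange(n) / rate
        return make_waveform(np.sin(2 * np.pi * f * t), rate, f0=f,
                             kind="resp", source="phase"), t

    def test_global_maximum_maps_to_pi(self):
        wave, t = self._sine_wave()
        i_max = int(np.argmax(wave.samples))
        ph = respiratory_cycle_phase(wave, np.array([t[i_max]]))
        assert ph.phi[0] == pytest.approx(np.pi, abs=0.1)

    def test_first_harmonic_tracks_shifted_waveform(self):
        # for a pure sinusoid sin(phi_retro) equals the quarter-cycle
        # shifted waveform, so their correlation is ~1
        wave, t = self._sine_wave()
        ph = respiratory_cycle_phase(wave, t)
        harm = np.sin(ph.phi)
        shifted = np.cos(2 * np.pi * 0.25 * t)
        r = np.corrcoef(harm[50:-50], shifted[50:-50])[0, 1]
        assert r > 0.95

    def test_sign_flip_shifts_phase_by_half_cycle(self):
        # H(-a) = 1 - H(a) and the derivative sign flips, so
        # phi_flipped = pi*(1-H)*(-s) = phi - pi (mod 2*pi)
        wave, t = self._sine_wave()
        flipped = make_waveform(-wave.samples, wave.rate, 0.25, kind="resp")
        q = t[200:1800]
        ph = respiratory_cycle_phase(wave, q).phi
        ph_f = respiratory_cycle_phase(flipped, q).phi
        d = np.angle(np.exp(1j * (ph_f - ph + np.pi)))
        # residuals are quantized by the 100-bin histogram (~pi/20 steps);
        # the wrong symmetry (2*pi - phi) would leave residuals of order pi
        assert np.percentile(np.abs(d), 90) < 0.3

    def test_zero_variance_waveform_rejected(self):
        wave = make_waveform(np.zeros(500), 10.0, 0.25, kind="resp")
        with pytest.raises(ConfigurationError):
            respiratory_cycle_phase(wave, np.array([1.0]))


class TestFourierExpansion:
    def test_zero_phase_columns(self):
        out = fourier_expansion(np.zeros(5))
        assert np.array_equal(out[:, 0], np.zeros(5))
        assert np.array_equal(out[:, 1], np.ones(5))
        assert out.shape == (5, 4)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(0, 2 * np.pi, 64)
        out = fourier_expansion(CyclePhase(phi=phi, times=np.arange(64.0),
                                           kind="resp"))
        oracle = np.column_stack([np.sin(phi), np.cos(phi),
                                  np.sin(2 * phi), np.cos(2 * phi)])
        assert np.allclose(out, oracle, atol=1e-14)

    def test_uniform_ramp_columns_average_to_zero(self):
        nr = 400
        phi = np.mod(np.linspace(0, 20 * 2 * np.pi, nr, endpoint=False),
                     2 * np.pi)
        out = fourier_expansion(phi)
        assert np.max(np.abs(out.mean(axis=0))) < 5.0 / nr


class TestVarianceImprovement:
    def _candidate(self, rate=6.0, n=1800, f0=1.0):
        t = np.arange(n) / rate
        return make_waveform(np.sin(2 * np.pi * f0 * t), rate, f0), t

    def test_perfect_fit_gives_one(self):
        cand, t = self._candidate()
        from prepair.regressors import _candidate_phase

        phase = _candidate_phase(cand, cand.times)
        x = fourier_expansion(phase)
        target = make_subtr(x @ np.array([2.0, -1.0, 0.5, 0.3]) + 7.0, 6.0)
        assert evaluate_variance_improvement(cand, target) == pytest.approx(
            1.0, abs=1e-9)

    def test_orthogonal_content_explains_almost_nothing(self):
        cand, t = self._candidate(n=2000)
        target = make_subtr(np.sin(2 * np.pi * 0.31 * t[:2000]), 6.0)
        assert evaluate_variance_improvement(cand, target) < 0.02

    def test_half_variance_mixture_recovered(self):
        # target = first-harmonic signal + independent noise of equal
        # variance, so the expected R^2 is 0.5
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cand, t = self._candidate(n=2000)
            s = np.sin(2 * np.pi * 1.0 * t[:2000] + 0.4)
            noise = rng.normal(0, s.std(), 2000)
            target = make_subtr(s + noise, 6.0)
            vals.append(evaluate_variance_improvement(cand, target))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_matches_projection_oracle(self):
        cand, t = self._candidate()
        rng = np.random.default_rng(5)
        y = rng.normal(size=len(t))
        target = make_subtr(y, 6.0)
        from prepair.regressors import _candidate_phase

        x = np.column_stack([np.ones(len(t)),
                             fourier_expansion(_candidate_phase(cand,
                                                                target.times))])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert evaluate_variance_improvement(cand, target) == pytest.approx(
            r2, abs=1e-9)


class TestSelectSource:
    def _pair(self, kind):
        rate, n = 6.0, 1800
        t = np.arange(n) / rate
        f0 = 0.25 if kind == "resp" else 1.0
        x = np.sin(2 * np.pi * f0 * t)
        mag = make_waveform(x, rate, f0, kind=kind, source="magnitude")
        ph = make_waveform(x, rate, f0, kind=kind, source="phase")
        return mag, ph, make_subtr(x + 0.01 * np.cos(t), rate)

    def test_identical_candidates_tie_break_by_kind(self):
        for kind, expected in (("resp", "phase"), ("cardiac", "magnitude")):
            mag, ph, target = self._pair(kind)
            sel = select_source(mag, ph, target, target)
            assert sel.source == expected
            assert sel.improvements["magnitude"] == pytest.approx(
                sel.improvements["phase"], abs=1e-12)

    def test_missing_candidate_selects_available(self):
        mag, _, target = self._pair("cardiac")
        sel = select_source(mag, None, target)
        assert sel.source == "magnitude"
        sel2 = select_source(None, make_waveform(mag.samples, mag.rate, 1.0,
                                                 source="phase"),
                             target, target)
        assert sel2.source == "phase"


class TestBuildSlicewise:
    def _waveforms(self, duration, rate=6.0):
        n = int(duration * rate)
        t = np.arange(n) / rate
        resp = make_waveform(np.sin(2 * np.pi * 0.25 * t), rate, 0.25,
                             kind="resp", source="phase")
        card = make_waveform(np.sin(2 * np.pi * 1.0 * t), rate, 1.0,
                             kind="cardiac", source="magnitude")
        return resp, card

    def test_sms_slices_share_regressors(self):
        params = AcquisitionParams(tr_vol=1.0, n_slices=4, n_reps=100,
                                   mb_factor=2)
        resp, card = self._waveforms(duration=100)
        rs = build_slicewise_regressors(resp, card, params)
        assert np.array_equal(rs.matrices[0], rs.matrices[2])
        assert np.array_equal(rs.matrices[1], rs.matrices[3])

    def test_shape_contract_and_bounds(self):
        params = AcquisitionParams(tr_vol=2.0, n_slices=26, n_reps=150)
        resp, card = self._waveforms(duration=300, rate=13 / 2.0)
        rs = build_slicewise_regressors(resp, card, params)
        assert rs.matrices.shape == (26, 150, 8)
        assert np.all(rs.matrices >= -1.0) and np.all(rs.matrices <= 1.0)
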