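"""Synthetic EPI time series with known physiological ground truth.

The generator emulates the noise anatomy of resting-state EPI as seen by
the extraction pipeline:

* a smooth ellipsoidal "brain" baseline with per-slice mean offsets (the
  source of the slice-reordering carrier at 1/tr_vol),
* slow per-slice cubic drift,
* quasi-periodic respiration: strong in phase (chest-motion B0 changes),
  weaker multiplicative modulation of the magnitude,
* quasi-periodic cardiac pulsation: multiplicative in magnitude, confined
  to a "vessel" subset of brain voxels, with a 30% second harmonic; weak in
  phase,
* an optional narrowband cold-head-pump line in phase with slice-dependent
  coupling (which is what creates reordering sidebands k/TR +/- f_pump),
* Gaussian thermal noise and optional phase wrapping.

Oscillators integrate a jittered instantaneous frequency (first-order
autoregressive jitter, coefficient 0.99 on a 0.1 s control grid), giving
narrow quasi-periodic spectral lines.  Everything is reproducible from the
seed, and the same oscillators drive the simulated external recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import (
    AcquisitionParams,
    EpiSeries,
    ExternalRecording,
    slice_acquisition_times,
)
from .errors import ConfigurationError

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "simulate_epi",
    "simulate_external",
    "default_config",
    "aliasing_config",
    "sideband_config",
    "source_separation_config",
]

EXTERNAL_DT = 1.0 / 400.0  # PMU-style recording interval, seconds
_AR_COEF = 0.99
_AR_DT = 0.1  # control-grid spacing of the frequency jitter, seconds


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters of one synthetic EPI run.

    Amplitude conventions: ``*_mag_frac`` are fractional modulations of the
    local baseline intensity; ``*_phase_amp`` are radians.  Defaults emulate
    a calm resting subject at a field/protocol where thermal tSNR is ~100:
    2% global respiratory modulation, 6% cardiac pulsatility in a sparse
    (15%) vessel compartment, 0.2 rad respiratory phase excursion, and a
    weak 0.13 Hz pump line in phase.  ``noise_sd_mag`` is set for a
    mask-mean thermal tSNR of ~100 (the baseline blob averages ~0.55 of its
    peak over the brain mask), a regime where physiological lines dominate
    their spectral bands.  Frequency jitter SDs (stationary) are small,
    matching a regular breather/heart; raise them for irregular physiology.
    """

    nx: int = 32
    ny: int = 32
    n_slices: int = 12
    mb_factor: int = 2
    tr_vol: float = 1.0
    n_reps: int = 300
    # respiration: (base Hz, jitter SD Hz, phase amp rad, magnitude fraction)
    resp_freq: float = 0.25
    resp_jitter_sd: float = 0.003
    resp_phase_amp: float = 0.2
    resp_mag_frac: float = 0.02
    # cardiac: (base Hz, jitter SD Hz, vessel magnitude fraction, phase amp rad)
    card_freq: float = 1.17
    card_jitter_sd: float = 0.003
    card_mag_frac: float = 0.06
    card_phase_amp: float = 0.02
    # cold-head pump line (phase only); None disables it
    pump_freq: float | None = 0.13
    pump_phase_amp: float = 0.05
    pump_slice_cv: float = 0.5
    pump_profile: str = "random"  # "random" | "cosine" (over excitation groups)
    resp_slice_cv: float = 0.3
    drift_amp: float = 5.0
    noise_sd_mag: float = 5.0
    noise_sd_phase: float = 0.05
    wrap_phase: bool = False
    vessel_fraction: float = 0.15
    baseline: float = 1000.0
    slice_offset_sd: float = 30.0
    phase_offset_sd: float = 0.3
    seed: int = 0

    @property
    def params(self) -> AcquisitionParams:
        return AcquisitionParams(tr_vol=self.tr_vol, n_slices=self.n_slices,
                                 n_reps=self.n_reps, mb_factor=self.mb_factor)

    def __post_init__(self):
        ns = self.n_slices // max(self.mb_factor, 1)
        nyq = ns / (2.0 * self.tr_vol)
        for name, f in (("resp_freq", self.resp_freq),
                        ("card_freq", self.card_freq)):
            if not (0 < f < nyq):
                raise ConfigurationError(
                    f"{name}={f} Hz must lie below the sub-TR Nyquist "
                    f"{nyq:.3f} Hz")
        if not (0.0 <= self.vessel_fraction <= 1.0):
            raise ConfigurationError("vessel_fraction must be in [0, 1]")
        for name in ("resp_phase_amp", "resp_mag_frac", "card_mag_frac",
                     "card_phase_amp", "pump_phase_amp", "noise_sd_mag",
                     "noise_sd_phase"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")


@dataclass
class GroundTruth:
    """True physiological waveforms of a simulated run.

    ``*_fine`` arrays live on the 1/400 s external-recording grid;
    ``*_at_slices`` are the same oscillators sampled at every slice
    acquisition time (``(N, NR)``, matching the injected modulation).
    """

    fine_times: np.ndarray
    resp_fine: np.ndarray
    card_fine: np.ndarray
    resp_phase_fine: np.ndarray
    card_phase_fine: np.ndarray
    resp_at_slices: np.ndarray
    card_at_slices: np.ndarray
    vessel_mask: np.ndarray
    brain_mask: np.ndarray
    seed: int


def _oscillator(rng: np.random.Generator, base: float, jitter_sd: float,
                fine_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-periodic unit oscillator phase and instantaneous frequency.

    Instantaneous frequency = base + AR(1) jitter with stationary SD
    ``jitter_sd``, integrated to phase with a random initial phase.
    """
    duration = fine_times[-1]
    n_c = int(np.ceil(duration / _AR_DT)) + 2
    innov_sd = jitter_sd * np.sqrt(1.0 - _AR_COEF ** 2)
    x = np.empty(n_c)
    x[0] = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
    steps = rng.normal(0.0, innov_sd, n_c - 1) if jitter_sd > 0 else np.zeros(n_c - 1)
    for k in range(1, n_c):
        x[k] = _AR_COEF * x[k - 1] + steps[k - 1]
    coarse_t = np.arange(n_c) * _AR_DT
    jitter = np.interp(fine_times, coarse_t, x)
    freq = np.maximum(base + jitter, 0.02)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    dt = fine_times[1] - fine_times[0]
    phase = phi0 + 2.0 * np.pi * np.concatenate(
        ([0.0], np.cumsum(freq[:-1]) * dt))
    return phase, freq


def _slice_profile(rng: np.random.Generator, cfg: SynthConfig, cv: float,
                   profile: str) -> np.ndarray:
    """Per-slice coupling strengths 1 + cv * u for a modulator.

    ``"random"`` draws independent u per slice; ``"cosine"`` varies as a
    cosine over excitation-group rank (a worst-case pattern that survives
    SMS averaging with a guaranteed carrier Fourier coefficient, used by
    the sideband stress scenario).
    """
    n = cfg.n_slices
    if profile == "cosine":
        rank = cfg.params.group_of_slice
        ns = cfg.params.ns
        return 1.0 + cv * np.cos(2.0 * np.pi * rank / ns)
    if profile == "random":
        return 1.0 + cv * rng.uniform(-1.0, 1.0, n)
    raise ConfigurationError(f"unknown slice profile {profile!r}")


def simulate_epi(config: SynthConfig) -> tuple[EpiSeries, GroundTruth]:
    """Generate a magnitude+phase EPI series and its ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    params = cfg.params
    t_mat = slice_acquisition_times(params)  # (N, NR)
    duration = cfg.n_reps * cfg.tr_vol
    fine_times = np.arange(0.0, duration + EXTERNAL_DT, EXTERNAL_DT)

    resp_phase, _ = _oscillator(rng, cfg.resp_freq, cfg.resp_jitter_sd,
                                fine_times)
    card_phase, _ = _oscillator(rng, cfg.card_freq, cfg.card_jitter_sd,
                                fine_times)
    resp_fine = np.sin(resp_phase)
    card_fine = np.sin(card_phase) + 0.3 * np.sin(2.0 * card_phase)
    pump_phi0 = rng.uniform(0.0, 2.0 * np.pi)

    # geometry: smooth blob baseline, brain mask, per-slice offsets
    x = (np.arange(cfg.nx) - (cfg.nx - 1) / 2.0) / (0.35 * cfg.nx)
    y = (np.arange(cfg.ny) - (cfg.ny - 1) / 2.0) / (0.35 * cfg.ny)
    zc = (cfg.n_slices - 1) / 2.0
    z_mod = 1.0 - 0.3 * (((np.arange(cfg.n_slices) - zc) / max(zc, 1.0)) ** 2)
    blob = np.exp(-(x[:, None] ** 2 + y[None, :] ** 2))
    baseline3d = cfg.baseline * blob[:, :, None] * z_mod[None, None, :]
    brain = baseline3d > 0.3 * cfg.baseline
    slice_offsets = rng.normal(0.0, cfg.slice_offset_sd, cfg.n_slices)
    for z in range(cfg.n_slices):
        baseline3d[:, :, z][brain[:, :, z]] += slice_offsets[z]
    air_floor = 2.0 * cfg.noise_sd_mag
    baseline3d = np.maximum(baseline3d, air_floor)

    phase_offsets = rng.normal(0.0, cfg.phase_offset_sd, cfg.n_slices)
    g_resp = _slice_profile(rng, cfg, cfg.resp_slice_cv, "random")
    g_pump = _slice_profile(rng, cfg, cfg.pump_slice_cv, cfg.pump_profile)

    vessel = np.zeros_like(brain)
    brain_idx = np.flatnonzero(brain)
    n_vessel = int(round(cfg.vessel_fraction * len(brain_idx)))
    if n_vessel:
        chosen = rng.choice(brain_idx, size=n_vessel, replace=False)
        vessel.flat[chosen] = True

    drift_coef = rng.normal(0.0, cfg.drift_amp, (cfg.n_slices, 4))

    resp_at = np.empty_like(t_mat)
    card_at = np.empty_like(t_mat)
    for z in range(cfg.n_slices):
        resp_at[z] = np.interp(t_mat[z], fine_times, resp_fine)
        card_at[z] = np.interp(t_mat[z], fine_times, card_fine)

    shape = (cfg.nx, cfg.ny, cfg.n_slices, cfg.n_reps)
    noise_mag = rng.normal(0.0, cfg.noise_sd_mag, shape)
    noise_phase = rng.normal(0.0, cfg.noise_sd_phase, shape)

    magnitude = np.empty(shape)
    phase = np.empty(shape)
    tnorm = 2.0 * t_mat / duration - 1.0  # (N, NR) in ~[-1, 1]
    for z in range(cfg.n_slices):
        r_t = resp_at[z]
        c_t = card_at[z]
        drift_t = (drift_coef[z, 0] + drift_coef[z, 1] * tnorm[z]
                   + drift_coef[z, 2] * tnorm[z] ** 2
                   + drift_coef[z, 3] * tnorm[z] ** 3)
        mod = (1.0 + cfg.resp_mag_frac * r_t[None, None, :]
               + cfg.card_mag_frac * c_t[None, None, :]
               * vessel[:, :, z, None])
        magnitude[:, :, z, :] = (baseline3d[:, :, z, None] * mod
                                 + drift_t[None, None, :]
                                 + noise_mag[:, :, z, :])
        ph_t = (phase_offsets[z]
                + g_resp[z] * cfg.resp_phase_amp * r_t
                + cfg.card_phase_amp * c_t)
        if cfg.pump_freq is not None:
            ph_t = ph_t + (g_pump[z] * cfg.pump_phase_amp
                           * np.sin(2.0 * np.pi * cfg.pump_freq * t_mat[z]
                                    + pump_phi0))
        phase[:, :, z, :] = ph_t[None, None, :] + noise_phase[:, :, z, :]
    np.maximum(magnitude, 0.0, out=magnitude)
    if cfg.wrap_phase:
        phase = np.angle(np.exp(1j * phase))

    series = EpiSeries(magnitude=magnitude, params=params, phase=phase)
    truth = GroundTruth(
        fine_times=fine_times, resp_fine=resp_fine, card_fine=card_fine,
        resp_phase_fine=resp_phase, card_phase_fine=card_phase,
        resp_at_slices=resp_at, card_at_slices=card_at,
        vessel_mask=vessel, brain_mask=brain, seed=cfg.seed)
    return series, truth


def simulate_external(truth: GroundTruth, noise_sd: float = 0.02,
                      seed: int | None = None) -> ExternalRecording:
    """Simulated belt/plethysmograph recording at 1/400 s intervals.

    ``noise_sd`` is additive noise as a fraction of each waveform's RMS;
    with 0 the samples equal the ground truth exactly.
    """
    rng = np.random.default_rng(truth.seed + 10007 if seed is None else seed)
    resp = truth.resp_fine.copy()
    card = truth.card_fine.copy()
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd * np.sqrt(np.mean(resp ** 2)),
                                 len(resp))
        card = card + rng.normal(0.0, noise_sd * np.sqrt(np.mean(card ** 2)),
                                 len(card))
    return ExternalRecording(resp=resp, cardiac=card, dt=EXTERNAL_DT, t0=0.0)


def default_config(seed: int = 0, **overrides) -> SynthConfig:
    """The reference study conditions (32x32x12, NS=6, TR 1 s, NR 300)."""
    return replace(SynthConfig(seed=seed), **overrides) if overrides \
        else SynthConfig(seed=seed)


def aliasing_config(seed: int = 0) -> SynthConfig:
    """Cardiac 1.25 Hz at TR 2 s: aliased at the volume rate (Nyquist 0.25 Hz),
    critically sampled at the sub-TR rate (NS=10)."""
    return SynthConfig(seed=seed, tr_vol=2.0, n_slices=20, mb_factor=2,
                       n_reps=150, resp_freq=0.22, card_freq=1.25)


def sideband_config(seed: int = 0) -> SynthConfig:
    """Sideband stress scenario at TR 0.7 s (48 slices, MB 8, NS 6).

    A strong 0.13 Hz pump line in phase with a cosine coupling profile over
    excitation groups puts a sideband at 1/0.7 - 0.13 ~ 1.30 Hz that
    carries far more power than the weak true cardiac line at 1.0 Hz.
    """
    return SynthConfig(seed=seed, nx=24, ny=24, n_slices=48, mb_factor=8,
                       tr_vol=0.7, n_reps=450, card_freq=1.0,
                       card_phase_amp=0.02, resp_phase_amp=0.3,
                       pump_phase_amp=0.25, pump_slice_cv=0.8,
                       pump_profile="cosine")


def source_separation_config(seed: int = 0) -> SynthConfig:
    """Respiration present in phase only, cardiac in magnitude only."""
    return replace(SynthConfig(seed=seed), resp_mag_frac=0.0,
                   card_phase_amp=0.0)
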