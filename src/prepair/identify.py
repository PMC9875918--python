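"""Identification of respiratory and cardiac fundamentals in sub-TR signals.

The sub-TR series contains, besides the physiological lines f_R and f_C,
a slice-reordering carrier at 1/tr_vol and its harmonics.  Amplitude
modulation of that carrier by low-frequency disturbances (respiration, the
scanner's cold-head helium pump) produces sidebands at

    S = k / tr_vol +/- f_m,   k = 1, 2, ...

which can carry more power than the true cardiac line and must not be
mistaken for it.  The search therefore zeroes narrow notches at all
predicted sidebands (rather than band-pass filtering, which would also
attenuate nearby signal of interest) and iterates until the strongest
remaining in-band peak is found.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, NoFundamentalError, PrepairWarning
from .extract import SubTrSignal

__all__ = [
    "PowerSpectrum",
    "FundamentalEstimate",
    "PhysioWaveform",
    "RESP_BAND_HZ",
    "CARDIAC_BAND_HZ",
    "RESP_HALFWIDTH_HZ",
    "CARDIAC_HALFWIDTH_HZ",
    "PUMP_BAND_HZ",
    "band_prefilter",
    "periodogram",
    "sideband_frequencies",
    "estimate_pump_frequency",
    "find_fundamental",
    "narrowband_extract",
]

# Typical physiological search ranges: [9-30] cycles/min for respiration,
# [42-96] beats/min for cardiac, converted to Hz.
RESP_BAND_HZ = (9.0 / 60.0, 30.0 / 60.0)
CARDIAC_BAND_HZ = (42.0 / 60.0, 96.0 / 60.0)
# Narrowband halfwidths around the fundamentals (average within-run spread
# of physiological rates): 2.5 cycles/min and 6.5 beats/min.
RESP_HALFWIDTH_HZ = 2.5 / 60.0
CARDIAC_HALFWIDTH_HZ = 6.5 / 60.0
# Search range for the cold-head pump line, which sits below the
# respiratory band for typical volume TRs.
PUMP_BAND_HZ = (0.08, 0.2)


@dataclass
class PowerSpectrum:
    """One-sided power spectrum with equally spaced frequencies."""

    freqs: np.ndarray
    power: np.ndarray
    resolution: float

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ConfigurationError("freqs and power must share shape")


@dataclass
class FundamentalEstimate:
    """An identified physiological fundamental frequency.

    ``excluded`` lists the (center, halfwidth) notches that were actually
    zeroed during the search; ``f0`` never lies inside any of them.
    """

    f0: float
    band: tuple[float, float]
    kind: str  # "resp" | "cardiac"
    excluded: list[tuple[float, float]] = field(default_factory=list)
    n_iterations: int = 1


@dataclass
class PhysioWaveform:
    """A narrowband physiological waveform at the sub-TR rate."""

    samples: np.ndarray
    rate: float
    times: np.ndarray
    band: tuple[float, float]
    kind: str
    source: str
    fundamental: FundamentalEstimate

    def in_band_power_fraction(self) -> float:
        """Fraction of spectral power inside ``band`` (should be >= 0.95)."""
        x = self.samples - self.samples.mean()
        freqs, pxx = sps.periodogram(x, fs=self.rate, window="boxcar",
                                     detrend=False, scaling="spectrum")
        total = pxx.sum()
        if total == 0:
            return 0.0
        sel = (freqs >= self.band[0]) & (freqs <= self.band[1])
        return float(pxx[sel].sum() / total)


def _butter_sos(band: tuple[float, float], rate: float, order: int = 2):
    nyq = rate / 2.0
    lo, hi = band
    if not (0 < lo < hi < nyq):
        raise ConfigurationError(
            f"band [{lo}, {hi}] Hz must lie inside (0, {nyq}) Hz "
            f"(Nyquist of rate {rate} Hz)")
    return sps.butter(order, band, btype="bandpass", fs=rate, output="sos")


def bandpass_zero_phase(samples: np.ndarray, rate: float,
                        band: tuple[float, float], order: int = 2) -> np.ndarray:
    """Forward-backward (zero-phase) second-order Butterworth band-pass."""
    sos = _butter_sos(band, rate, order)
    return sps.sosfiltfilt(sos, samples)


def band_prefilter(signal: SubTrSignal, band: tuple[float, float],
                   kind: str = "resp") -> SubTrSignal:
    """Prefilter the sub-TR series to a physiological band.

    Zero-phase second-order Butterworth so that waveform timing stays
    aligned with the slice acquisition times.
    """
    res = signal.rate / len(signal)
    if band[1] - band[0] <= 2 * res:
        raise ConfigurationError(
            f"band width {band[1] - band[0]:.4f} Hz must exceed twice the "
            f"spectral resolution {res:.4f} Hz")
    filtered = bandpass_zero_phase(signal.samples, signal.rate, band)
    return SubTrSignal(samples=filtered, rate=signal.rate,
                       times=signal.times, source=signal.source)


def periodogram(signal: SubTrSignal) -> PowerSpectrum:
    """One-sided power spectrum after mean removal (boxcar window).

    With the ``spectrum`` scaling used here the powers sum to the
    time-domain variance (Parseval), and a unit sinusoid at a bin frequency
    carries power 0.5 in its bin.
    """
    if len(signal) < 16:
        raise ConfigurationError("need at least 16 samples for a periodogram")
    x = signal.samples - signal.samples.mean()
    freqs, pxx = sps.periodogram(x, fs=signal.rate, window="boxcar",
                                 detrend=False, scaling="spectrum")
    return PowerSpectrum(freqs=freqs, power=pxx,
                         resolution=signal.rate / len(signal))


def sideband_frequencies(tr_vol: float, modulators, band: tuple[float, float],
                         k_max: int | None = None) -> list[float]:
    """Predicted reordering sidebands ``k/tr_vol +/- f_m`` inside ``band``.

    ``k`` runs over carrier harmonics; by default all ``k`` with
    ``k/tr_vol - max(f_m) < band[1]``, capped at 4.
    """
    mods = [float(m) for m in modulators if m is not None]
    if any(m <= 0 for m in mods):
        raise ConfigurationError("modulator frequencies must be positive")
    if not mods:
        return []
    f_carrier = 1.0 / tr_vol
    if k_max is None:
        k_max = int(np.floor((band[1] + max(mods)) / f_carrier))
        k_max = max(1, min(k_max, 4))
    out = []
    for k in range(1, k_max + 1):
        for fm in mods:
            for s in (k * f_carrier - fm, k * f_carrier + fm):
                if band[0] <= s <= band[1]:
                    out.append(s)
    return sorted(set(out))


def _refine_peak(freqs: np.ndarray, power: np.ndarray, idx: int) -> float:
    """Quadratic (parabolic) interpolation on log-power around a peak bin."""
    if idx <= 0 or idx >= len(power) - 1:
        return float(freqs[idx])
    p = power[idx - 1:idx + 2]
    if np.any(p <= 0):
        return float(freqs[idx])
    lp = np.log(p)
    denom = lp[0] - 2 * lp[1] + lp[2]
    if denom >= 0:
        return float(freqs[idx])
    delta = 0.5 * (lp[0] - lp[2]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    df = freqs[1] - freqs[0]
    return float(freqs[idx] + delta * df)


def find_fundamental(spectrum: PowerSpectrum, band: tuple[float, float],
                     exclusions=None, kind: str = "resp") -> FundamentalEstimate:
    """Iteratively locate the physiological fundamental inside ``band``.

    The strongest in-band bin is accepted unless it falls inside one of the
    ``(center, halfwidth)`` exclusion notches (predicted sidebands, pump
    line); in that case the notch is zeroed and the search repeats.  The
    accepted peak is refined by quadratic interpolation on log-power.
    """
    exclusions = list(exclusions or [])
    freqs, power = spectrum.freqs, spectrum.power.copy()
    if band[0] < freqs[0] or band[1] > freqs[-1]:
        raise ConfigurationError(f"band {band} outside spectrum range")
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise NoFundamentalError(f"no spectral bin inside band {band}")
    zeroed: list[tuple[float, float]] = []
    n_iter = 0
    while True:
        n_iter += 1
        masked = np.where(in_band, power, 0.0)
        idx = int(np.argmax(masked))
        if masked[idx] <= 0:
            raise NoFundamentalError(
                f"all in-band power removed by exclusions in band {band}; "
                "widen the search band")
        f_peak = freqs[idx]
        hit = next(((c, h) for c, h in exclusions if abs(f_peak - c) <= h), None)
        if hit is None:
            f0 = _refine_peak(freqs, power, idx)
            # keep the refined value outside every supplied notch
            for c, h in exclusions:
                if abs(f0 - c) <= h:
                    f0 = float(f_peak)
                    break
            f0 = float(np.clip(f0, band[0], band[1]))
            return FundamentalEstimate(f0=f0, band=(float(band[0]), float(band[1])),
                                       kind=kind, excluded=zeroed,
                                       n_iterations=n_iter)
        c, h = hit
        power[np.abs(freqs - c) <= h] = 0.0
        if hit not in zeroed:
            zeroed.append(hit)


def estimate_pump_frequency(phase_subtr: SubTrSignal,
                            pump_band: tuple[float, float] = PUMP_BAND_HZ,
                            resp_fundamental: float | None = None,
                            resp_halfwidth: float = RESP_HALFWIDTH_HZ,
                            prominence_factor: float = 3.0) -> float | None:
    """Detect the cold-head helium pump line in a phase-derived series.

    Presence is decided on a Welch-averaged spectrum: the strongest bin
    inside ``pump_band`` (minus the respiratory notch
    ``f_R +/- resp_halfwidth`` once f_R is known) must exceed
    ``prominence_factor`` times the median in-band power.  Averaging
    matters: on a raw single-taper periodogram the bin powers of pure noise
    are exponentially distributed and their in-band maximum routinely
    exceeds 3x the median, which would make the detector fire on pump-free
    data.  When present, the line frequency is refined on the
    full-resolution periodogram within one Welch bin.  ``None`` means no
    pump line (a valid outcome; the disturbance is scanner-dependent).
    """
    x = phase_subtr.samples - phase_subtr.samples.mean()
    nper = max(64, len(x) // 4)
    w_freqs, w_pxx = sps.welch(x, fs=phase_subtr.rate, window="hann",
                               nperseg=min(nper, len(x)),
                               noverlap=min(nper, len(x)) // 2,
                               detrend=False, scaling="spectrum")
    sel = (w_freqs >= pump_band[0]) & (w_freqs <= pump_band[1])
    if resp_fundamental is not None:
        sel &= np.abs(w_freqs - resp_fundamental) > resp_halfwidth
    if sel.sum() < 3:
        return None
    p = w_pxx[sel]
    med = np.median(p)
    if med <= 0 or p.max() < prominence_factor * med:
        return None
    f_coarse = w_freqs[sel][int(np.argmax(p))]
    w_res = w_freqs[1] - w_freqs[0]
    spec = periodogram(phase_subtr)
    fine = np.abs(spec.freqs - f_coarse) <= w_res
    if resp_fundamental is not None:
        fine &= np.abs(spec.freqs - resp_fundamental) > resp_halfwidth
    if not fine.any():
        return float(f_coarse)
    idx = np.flatnonzero(fine)[int(np.argmax(spec.power[fine]))]
    return _refine_peak(spec.freqs, spec.power, idx)


def narrowband_extract(signal: SubTrSignal, estimate: FundamentalEstimate,
                       halfwidth: float) -> PhysioWaveform:
    """Zero-phase band-pass around the fundamental, ``f0 +/- halfwidth``.

    The band is clipped (with a warning) if it touches 0 or the Nyquist
    frequency.
    """
    nyq = signal.rate / 2.0
    res = signal.rate / len(signal)
    lo = estimate.f0 - halfwidth
    hi = estimate.f0 + halfwidth
    clipped = False
    if lo < res:
        lo, clipped = res, True
    if hi > 0.999 * nyq:
        hi, clipped = 0.999 * nyq, True
    if clipped:
        warnings.warn(
            f"narrowband [{estimate.f0 - halfwidth:.3f}, "
            f"{estimate.f0 + halfwidth:.3f}] Hz clipped to "
            f"[{lo:.3f}, {hi:.3f}] Hz", PrepairWarning, stacklevel=2)
    filtered = bandpass_zero_phase(signal.samples, signal.rate, (lo, hi))
    return PhysioWaveform(samples=filtered, rate=signal.rate,
                          times=signal.times, band=(lo, hi),
                          kind=estimate.kind, source=signal.source,
                          fundamental=estimate)
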