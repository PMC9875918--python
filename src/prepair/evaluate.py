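"""Assessment battery: waveform agreement, spectral metrics and tSNR.

Voxelwise spectra are computed at the volume TR (per-voxel sampling rate
``1/tr_vol``); physiological bands above the volume Nyquist are mapped to
their aliased frequencies before band-power integration, because single
voxels cannot be super-sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .data import AcquisitionParams, EpiSeries, ExternalRecording, VoxelMask
from .errors import ConfigurationError, PrepairWarning
from .extract import SliceSignal, SubTrSignal, reorder_to_subtr
from .identify import PhysioWaveform, bandpass_zero_phase

__all__ = [
    "Spectrogram",
    "BandPowerResult",
    "BandPowerReport",
    "TsnrReport",
    "lagged_correlation",
    "resample_external",
    "waveform_external_correlation",
    "flatten_to_subtr",
    "sliding_spectrogram",
    "aliased_band_bins",
    "band_power_proportion",
    "out_of_band_fluctuation",
    "harmonic_band_present",
    "evaluation_bands",
    "tsnr_gain",
]


@dataclass
class Spectrogram:
    """Sliding-window power spectra: ``power[freq, window]``."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray

    def to_db(self) -> np.ndarray:
        floor = self.power[self.power > 0].min() if (self.power > 0).any() else 1.0
        return 10.0 * np.log10(np.maximum(self.power, floor * 1e-3))


@dataclass
class BandPowerResult:
    """Band-power removal proportions for one band set."""

    per_slice: np.ndarray
    overall: float
    bands: list
    n_zero_power: int = 0


@dataclass
class BandPowerReport:
    """Removal proportions per noise kind plus the out-of-band fluctuation."""

    resp: BandPowerResult
    cardiac: BandPowerResult
    out_of_band: float


@dataclass
class TsnrReport:
    """Temporal SNR before/after and percentage gain, with ROI summaries."""

    tsnr_before: np.ndarray
    tsnr_after: np.ndarray
    gain_percent: np.ndarray
    roi_summaries: dict = field(default_factory=dict)
    n_zero_sd: int = 0


def lagged_correlation(a: np.ndarray, b: np.ndarray, rate: float,
                       max_lag: float = 5.0) -> tuple[float, float]:
    """Maximum-magnitude normalized cross-correlation over lags.

    ``a`` and ``b`` must share the sampling ``rate`` (resample/filter the
    external recording first, see :func:`resample_external`).  Returns the
    signed correlation with the largest magnitude over lags in
    ``[-max_lag, +max_lag]`` seconds, and that lag (positive lag: ``b``
    delayed relative to ``a``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("signals must share length")
    n = len(a)
    max_shift = int(round(max_lag * rate))
    if n - max_shift < 32:
        max_shift = max(0, n - 32)
        warnings.warn("lag range clipped to keep >= 32 overlapping samples",
                      PrepairWarning, stacklevel=2)
    best = (0.0, 0.0)
    for shift in range(-max_shift, max_shift + 1):
        if shift >= 0:
            x, y = a[:n - shift] if shift else a, b[shift:]
        else:
            x, y = a[-shift:], b[:n + shift]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        c = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
        if abs(c) > abs(best[0]):
            best = (c, shift / rate)
    return best


def resample_external(recording: ExternalRecording, kind: str,
                      times: np.ndarray, rate: float,
                      band: tuple[float, float] | None = None) -> np.ndarray:
    """Resample one external channel to sub-TR times, optionally band-passed.

    Linear interpolation to ``times``, then (if ``band`` is given) the same
    zero-phase second-order Butterworth band-pass the physiological
    waveforms received, so the comparison is matched.
    """
    samples = recording.resp if kind == "resp" else recording.cardiac
    x = np.interp(times, recording.times, samples)
    if band is not None:
        x = bandpass_zero_phase(x, rate, band)
    return x


def waveform_external_correlation(waveform: PhysioWaveform,
                                  recording: ExternalRecording,
                                  max_lag: float = 5.0) -> tuple[float, float]:
    """Lag-aware correlation of a waveform with the matched external channel."""
    ext = resample_external(recording, waveform.kind, waveform.times,
                            waveform.rate, band=waveform.band)
    return lagged_correlation(waveform.samples, ext, waveform.rate, max_lag)


def flatten_to_subtr(data: np.ndarray | EpiSeries, params: AcquisitionParams,
                     mask: VoxelMask) -> SubTrSignal:
    """Plain slice mean + acquisition-order reordering, without detrending.

    Used to visualize the noise content of (un)corrected magnitude data as
    a single slice-TR-sampled series.
    """
    arr = data.magnitude if isinstance(data, EpiSeries) else np.asarray(data)
    n, nr = params.n_slices, params.n_reps
    rows = np.empty((n, nr))
    last = None
    for z in range(n):
        sel = mask.mask[:, :, z]
        if sel.any():
            rows[z] = arr[:, :, z, :][sel].mean(axis=0)
            last = z
        else:
            rows[z] = np.nan
    if last is None:
        raise ConfigurationError("mask is empty in every slice")
    for z in range(n):
        if np.isnan(rows[z, 0]):
            nonempty = [k for k in range(n) if not np.isnan(rows[k, 0])]
            src = min(nonempty, key=lambda k: abs(k - z))
            rows[z] = rows[src]
    sig = SliceSignal(rows, params.tr_vol, "magnitude")
    return reorder_to_subtr(sig, params)


def sliding_spectrogram(signal: SubTrSignal, window: float = 45.0,
                        step: float = 4.0) -> Spectrogram:
    """Sliding-window Welch spectra (45 s windows, 4 s steps by default).

    Each window is split into three 50%-overlapping Hann-tapered segments
    whose mean-removed periodograms are averaged, trading a little
    resolution for variance reduction within each window.
    """
    n = len(signal)
    w = int(round(window * signal.rate))
    s = max(1, int(round(step * signal.rate)))
    if w > n:
        raise ConfigurationError(
            f"signal duration {n / signal.rate:.1f} s is shorter than the "
            f"{window:.1f} s window; use a smaller window")
    nper = w // 2
    starts = range(0, n - w + 1, s)
    powers, centers = [], []
    freqs = None
    for i in starts:
        seg = signal.samples[i:i + w]
        f, pxx = sps.welch(seg, fs=signal.rate, window="hann", nperseg=nper,
                           noverlap=nper // 2, detrend="constant",
                           scaling="spectrum")
        freqs = f
        powers.append(pxx)
        centers.append(signal.times[i] + window / 2.0)
    return Spectrogram(times=np.array(centers), freqs=freqs,
                       power=np.array(powers).T)


def aliased_band_bins(freqs: np.ndarray, fs: float,
                      bands) -> np.ndarray:
    """Boolean mask of volume-rate bins reachable by aliasing from ``bands``.

    A bin frequency ``g`` is in-band iff some integer ``k >= 0`` puts
    ``k*fs + g`` or ``k*fs - g`` inside one of the bands.  The DC bin is
    never included.
    """
    sel = np.zeros(len(freqs), dtype=bool)
    for lo, hi in bands:
        kmax = int(np.ceil(hi / fs)) + 1
        for k in range(kmax + 1):
            sel |= (k * fs + freqs >= lo) & (k * fs + freqs <= hi)
            sel |= (k * fs - freqs >= lo) & (k * fs - freqs <= hi)
    sel[0] = False
    return sel


def _voxel_band_power(data: np.ndarray, mask: np.ndarray,
                      bins: np.ndarray) -> np.ndarray:
    """Summed spectral power of masked voxels over the selected bins."""
    y = data[mask]  # (nvox, NR)
    y = y - y.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(y, axis=1)) ** 2
    return spec[:, bins].sum(axis=1)


def band_power_proportion(before: np.ndarray, after: np.ndarray,
                          params: AcquisitionParams, mask: VoxelMask,
                          bands, weighting: str = "power") -> BandPowerResult:
    """Proportion of in-band power removed between uncorrected and corrected data.

    Per voxel ``1 - P_after / P_before`` with P summed over the (aliased)
    band bins of the voxel's volume-rate periodogram, then averaged over
    each slice.  With ``weighting="power"`` (default) the slice average
    weights voxels by their in-band power before correction, i.e. it equals
    the relative change of the slice-pooled in-band power;
    ``weighting="uniform"`` averages the per-voxel proportions directly
    (voxels with zero in-band power are excluded and counted).  1 means
    total removal, 0 no change, negative values added noise.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ConfigurationError("before/after must share shape")
    nr = params.n_reps
    fs = 1.0 / params.tr_vol
    freqs = np.fft.rfftfreq(nr, params.tr_vol)
    bins = aliased_band_bins(freqs, fs, bands)
    per_slice = np.full(params.n_slices, np.nan)
    tot_b = tot_a = 0.0
    n_zero = 0
    for z in range(params.n_slices):
        sel = mask.mask[:, :, z]
        if not sel.any():
            continue
        pb = _voxel_band_power(before[:, :, z, :], sel, bins)
        pa = _voxel_band_power(after[:, :, z, :], sel, bins)
        ok = pb > 0
        n_zero += int((~ok).sum())
        if not ok.any():
            continue
        if weighting == "power":
            per_slice[z] = 1.0 - pa[ok].sum() / pb[ok].sum()
        elif weighting == "uniform":
            per_slice[z] = float(np.mean(1.0 - pa[ok] / pb[ok]))
        else:
            raise ConfigurationError(f"unknown weighting {weighting!r}")
        tot_b += pb[ok].sum()
        tot_a += pa[ok].sum()
    if weighting == "power":
        overall = 1.0 - tot_a / tot_b if tot_b > 0 else np.nan
    else:
        valid = per_slice[np.isfinite(per_slice)]
        overall = float(valid.mean()) if len(valid) else np.nan
    return BandPowerResult(per_slice=per_slice, overall=float(overall),
                           bands=list(bands), n_zero_power=n_zero)


def out_of_band_fluctuation(before: np.ndarray, after: np.ndarray,
                            params: AcquisitionParams, mask: VoxelMask,
                            bands, weighting: str = "power") -> float:
    """Relative power change outside the physiological bands (signed).

    Same statistic as :func:`band_power_proportion` computed over the
    complement of the (aliased) physiological bands; values near zero mean
    the correction preserved out-of-band signal.
    """
    nr = params.n_reps
    fs = 1.0 / params.tr_vol
    freqs = np.fft.rfftfreq(nr, params.tr_vol)
    in_bins = aliased_band_bins(freqs, fs, bands)
    out_bins = ~in_bins
    out_bins[0] = False
    tot_b = tot_a = 0.0
    props = []
    for z in range(params.n_slices):
        sel = mask.mask[:, :, z]
        if not sel.any():
            continue
        pb = _voxel_band_power(np.asarray(before)[:, :, z, :], sel, out_bins)
        pa = _voxel_band_power(np.asarray(after)[:, :, z, :], sel, out_bins)
        ok = pb > 0
        if not ok.any():
            continue
        if weighting == "power":
            props.append(1.0 - pa[ok].sum() / pb[ok].sum())
        else:
            props.append(float(np.mean(1.0 - pa[ok] / pb[ok])))
        tot_b += pb[ok].sum()
        tot_a += pa[ok].sum()
    if weighting == "power":
        return float(1.0 - tot_a / tot_b) if tot_b > 0 else np.nan
    return float(np.mean(props)) if props else np.nan


def harmonic_band_present(before: np.ndarray, params: AcquisitionParams,
                          mask: VoxelMask, band: tuple[float, float],
                          factor: float = 1.2) -> bool:
    """Data-driven test for a visible second-harmonic band.

    The (aliased) band's mean pooled power density over masked voxels is
    compared with a robust background: the median per-bin pooled density
    over all non-DC, non-drift bins outside the band.  The harmonic counts
    as present iff its density exceeds ``factor`` times that background.
    A flanking-band comparison would be confounded whenever the aliased
    cardiac fundamental folds next to the harmonic, which happens at
    ordinary volume TRs.
    """
    nr = params.n_reps
    fs = 1.0 / params.tr_vol
    freqs = np.fft.rfftfreq(nr, params.tr_vol)
    bins = aliased_band_bins(freqs, fs, [band])
    if not bins.any():
        return False
    arr = np.asarray(before, dtype=float)
    pooled = np.zeros(len(freqs))
    for z in range(params.n_slices):
        sel = mask.mask[:, :, z]
        if not sel.any():
            continue
        y = arr[:, :, z, :][sel]
        y = y - y.mean(axis=1, keepdims=True)
        pooled += (np.abs(np.fft.rfft(y, axis=1)) ** 2).sum(axis=0)
    background_bins = ~bins & (freqs > max(0.05, 2.0 * fs / nr))
    if not background_bins.any() or pooled[background_bins].sum() <= 0:
        return False
    background = np.median(pooled[background_bins])
    if background <= 0:
        return False
    density_ratio = pooled[bins].mean() / background
    return bool(density_ratio > factor)


def evaluation_bands(f0: float, halfwidth: float, before: np.ndarray,
                     params: AcquisitionParams, mask: VoxelMask) -> list:
    """Fundamental band plus the second-harmonic band when present in the data."""
    bands = [(f0 - halfwidth, f0 + halfwidth)]
    harm = (2 * f0 - halfwidth, 2 * f0 + halfwidth)
    if harmonic_band_present(before, params, mask, harm):
        bands.append(harm)
    return bands


def tsnr_gain(before: np.ndarray, after: np.ndarray, mask: VoxelMask,
              rois: dict | None = None) -> TsnrReport:
    """Temporal SNR (mean/SD over time) before and after, and its % gain.

    ``gain_percent = 100 * (after - before) / before`` where tSNR_before is
    positive; zero-SD voxels are excluded and counted.  Optional named ROI
    masks get mean gain and 25/50/75th percentiles.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ConfigurationError("before/after must share shape")
    with np.errstate(invalid="ignore", divide="ignore"):
        sd_b = before.std(axis=3)
        sd_a = after.std(axis=3)
        t_b = np.where(sd_b > 0, before.mean(axis=3) / sd_b, 0.0)
        t_a = np.where(sd_a > 0, after.mean(axis=3) / sd_a, 0.0)
        gain = np.where((t_b > 0) & (sd_a > 0),
                        100.0 * (t_a - t_b) / t_b, np.nan)
    n_zero = int(((sd_b == 0) | (sd_a == 0)).sum())
    summaries = {}
    roi_masks = {"mask": mask.mask}
    if rois:
        roi_masks.update(rois)
    for name, roi in roi_masks.items():
        vals = gain[roi & np.isfinite(gain)]
        if len(vals) == 0:
            continue
        summaries[name] = {
            "mean_gain_percent": float(vals.mean()),
            "p25": float(np.percentile(vals, 25)),
            "p50": float(np.percentile(vals, 50)),
            "p75": float(np.percentile(vals, 75)),
        }
    return TsnrReport(tsnr_before=t_b, tsnr_after=t_a, gain_percent=gain,
                      roi_summaries=summaries, n_zero_sd=n_zero)
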