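"""End-to-end orchestration: identify, select, model, correct, assess.

`run_prepair` performs the full regressor-estimation and correction chain
on an :class:`~prepair.data.EpiSeries`; `assess_correction` computes the
spectral and tSNR quality metrics of the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correct import CorrectionResult, regress_out_physio
from .data import EpiSeries, VoxelMask
from .errors import ConfigurationError
from .evaluate import (
    BandPowerReport,
    TsnrReport,
    band_power_proportion,
    evaluation_bands,
    out_of_band_fluctuation,
    tsnr_gain,
)
from .extract import (
    SubTrSignal,
    compute_high_snr_mask,
    detrend_slice_signals,
    reorder_to_subtr,
    slice_average,
    threshold_mask,
    unwrap_phase_temporal,
)
from .identify import (
    CARDIAC_BAND_HZ,
    CARDIAC_HALFWIDTH_HZ,
    PUMP_BAND_HZ,
    RESP_BAND_HZ,
    RESP_HALFWIDTH_HZ,
    FundamentalEstimate,
    PhysioWaveform,
    band_prefilter,
    estimate_pump_frequency,
    find_fundamental,
    narrowband_extract,
    periodogram,
    sideband_frequencies,
)
from .regressors import (
    KindSelection,
    RegressorSet,
    SourceSelection,
    build_slicewise_regressors,
    select_source,
)

__all__ = ["PrepairConfig", "SourceIdentification", "PrepairResult",
           "run_prepair", "identify_physio", "assess_correction"]


@dataclass(frozen=True)
class PrepairConfig:
    """Tunable parameters of the identification/correction chain.

    Bands and halfwidths are Hz (the CLI accepts cpm/bpm and converts).
    ``notch_halfwidth_hz=None`` uses max(2 spectral bins, 0.01 Hz), wide
    enough to cover leakage of a drifting modulator without eating the
    cardiac band.
    """

    resp_band: tuple[float, float] = RESP_BAND_HZ
    cardiac_band: tuple[float, float] = CARDIAC_BAND_HZ
    resp_halfwidth: float = RESP_HALFWIDTH_HZ
    cardiac_halfwidth: float = CARDIAC_HALFWIDTH_HZ
    pump_band: tuple[float, float] = PUMP_BAND_HZ
    pump_prominence: float = 3.0
    cardiac_widen: float = 0.10
    notch_halfwidth_hz: float | None = None
    k_max: int | None = None
    mask_mode: str = "snr"  # "snr" | "threshold"
    mask_threshold: float = 3000.0
    drift_order: int = 3
    target_mode: str = "same_source"  # or "magnitude"
    phase_convention: str = "default"  # or "peaks"
    temporal_unwrap: bool = True


@dataclass
class SourceIdentification:
    """Fundamentals and narrowband waveforms derived from one data source."""

    subtr: SubTrSignal
    resp_fundamental: FundamentalEstimate
    cardiac_fundamental: FundamentalEstimate
    resp_waveform: PhysioWaveform
    cardiac_waveform: PhysioWaveform
    pump_hz: float | None = None


@dataclass
class PrepairResult:
    """Everything produced by one run of the pipeline."""

    mask: VoxelMask
    magnitude: SourceIdentification
    phase: SourceIdentification | None
    selection: SourceSelection
    regressors: RegressorSet
    correction: CorrectionResult
    config: PrepairConfig

    @property
    def resp_waveform(self) -> PhysioWaveform:
        src = self.selection.resp_source
        return (self.phase if src == "phase" else self.magnitude).resp_waveform

    @property
    def cardiac_waveform(self) -> PhysioWaveform:
        src = self.selection.cardiac_source
        return (self.phase if src == "phase"
                else self.magnitude).cardiac_waveform

    def metadata(self) -> dict:
        meta = {
            "resp_source": self.selection.resp_source,
            "cardiac_source": self.selection.cardiac_source,
            "resp_f0_hz": self.resp_waveform.fundamental.f0,
            "cardiac_f0_hz": self.cardiac_waveform.fundamental.f0,
            "resp_improvements": self.selection.resp.improvements,
            "cardiac_improvements": self.selection.cardiac.improvements,
        }
        if self.phase is not None:
            meta["pump_hz"] = self.phase.pump_hz
        return meta


def identify_physio(subtr: SubTrSignal, cfg: PrepairConfig, tr_vol: float,
                    is_phase: bool = False) -> SourceIdentification:
    """Steps (e)-(g) for one sub-TR source: prefilter, find f_R and f_C
    with sideband/pump exclusions, extract the narrowband waveforms.

    Respiration is identified first (its fundamental defines cardiac-band
    exclusions); the pump line is searched in phase-derived data only.  The
    cardiac search runs on a band widened by ``cardiac_widen`` so unusual
    rhythms near the band edges are not lost, and exclusion notches are
    zeroed in the spectrum rather than filtered, to spare nearby signal.
    """
    res = subtr.rate / len(subtr)
    notch_hw = cfg.notch_halfwidth_hz
    if notch_hw is None:
        notch_hw = max(2.0 * res, 0.01)

    resp_pref = band_prefilter(subtr, cfg.resp_band, kind="resp")
    resp_spec = periodogram(resp_pref)
    resp_est = find_fundamental(resp_spec, cfg.resp_band, kind="resp")

    pump = None
    if is_phase:
        pump = estimate_pump_frequency(
            subtr, pump_band=cfg.pump_band,
            resp_fundamental=resp_est.f0, resp_halfwidth=cfg.resp_halfwidth,
            prominence_factor=cfg.pump_prominence)
        if pump is not None and abs(pump - resp_est.f0) > notch_hw:
            # re-identify respiration with the pump line notched out, in
            # case the pump dominated the low end of the respiratory band
            resp_est = find_fundamental(resp_spec, cfg.resp_band,
                                        exclusions=[(pump, notch_hw)],
                                        kind="resp")

    lo, hi = cfg.cardiac_band
    w = cfg.cardiac_widen
    nyq = subtr.rate / 2.0
    wband = (max(lo * (1.0 - w), 2.0 * res), min(hi * (1.0 + w), 0.99 * nyq))
    card_pref = band_prefilter(subtr, wband, kind="cardiac")
    card_spec = periodogram(card_pref)
    modulators = [resp_est.f0] + ([pump] if pump is not None else [])
    sidebands = sideband_frequencies(tr_vol, modulators, wband, cfg.k_max)
    exclusions = [(s, notch_hw) for s in sidebands]
    card_est = find_fundamental(card_spec, wband, exclusions, kind="cardiac")

    resp_wave = narrowband_extract(subtr, resp_est, cfg.resp_halfwidth)
    card_wave = narrowband_extract(subtr, card_est, cfg.cardiac_halfwidth)
    return SourceIdentification(subtr=subtr, resp_fundamental=resp_est,
                                cardiac_fundamental=card_est,
                                resp_waveform=resp_wave,
                                cardiac_waveform=card_wave, pump_hz=pump)


def run_prepair(series: EpiSeries, config: PrepairConfig | None = None,
                mask: VoxelMask | None = None) -> PrepairResult:
    """Full chain: mask, extract sub-TR signals, identify physiology per
    source, select the better source per noise kind, build slice-wise
    regressors and regress the noise out of the magnitude data."""
    cfg = config or PrepairConfig()
    if mask is None:
        if cfg.mask_mode == "snr":
            mask = compute_high_snr_mask(series.magnitude)
        elif cfg.mask_mode == "threshold":
            mask = threshold_mask(series.magnitude, cfg.mask_threshold)
        else:
            raise ConfigurationError(f"unknown mask_mode {cfg.mask_mode!r}")

    work = series
    if series.phase is not None and cfg.temporal_unwrap:
        work = EpiSeries(magnitude=series.magnitude, params=series.params,
                         phase=unwrap_phase_temporal(series.phase))

    mag_rows, phase_rows = slice_average(work, mask)
    mag_subtr = reorder_to_subtr(detrend_slice_signals(mag_rows),
                                 series.params)
    mag_id = identify_physio(mag_subtr, cfg, series.params.tr_vol,
                             is_phase=False)
    phase_id = None
    if phase_rows is not None:
        phase_subtr = reorder_to_subtr(detrend_slice_signals(phase_rows),
                                       series.params)
        phase_id = identify_physio(phase_subtr, cfg, series.params.tr_vol,
                                   is_phase=True)

    def _sel(kind: str) -> KindSelection:
        mag_c = getattr(mag_id, f"{kind}_waveform")
        ph_c = getattr(phase_id, f"{kind}_waveform") if phase_id else None
        return select_source(mag_c, ph_c, mag_subtr,
                             phase_id.subtr if phase_id else None,
                             target_mode=cfg.target_mode)

    selection = SourceSelection(resp=_sel("resp"), cardiac=_sel("cardiac"))
    resp_wave = (phase_id if selection.resp_source == "phase"
                 else mag_id).resp_waveform
    card_wave = (phase_id if selection.cardiac_source == "phase"
                 else mag_id).cardiac_waveform
    regressors = build_slicewise_regressors(
        resp_wave, card_wave, series.params,
        sources={"resp": selection.resp_source,
                 "cardiac": selection.cardiac_source},
        improvements={"resp": selection.resp.improvements,
                      "cardiac": selection.cardiac.improvements},
        phase_convention=cfg.phase_convention)
    correction = regress_out_physio(series, regressors, mask,
                                    drift_order=cfg.drift_order)
    return PrepairResult(mask=mask, magnitude=mag_id, phase=phase_id,
                         selection=selection, regressors=regressors,
                         correction=correction, config=cfg)


@dataclass
class EvalReport:
    """Band-power and tSNR assessment of one corrected run."""

    band_power: BandPowerReport
    tsnr: TsnrReport
    bands: dict = field(default_factory=dict)


def assess_correction(series: EpiSeries, result: PrepairResult,
                      weighting: str = "power",
                      rois: dict | None = None) -> EvalReport:
    """Quality metrics of a correction: proportion of physiological band
    power removed (second harmonics included when visible in the data),
    out-of-band power fluctuation, and tSNR gain."""
    params = series.params
    before = series.magnitude
    after = result.correction.corrected
    cfg = result.config
    resp_bands = evaluation_bands(result.resp_waveform.fundamental.f0,
                                  cfg.resp_halfwidth, before, params,
                                  result.mask)
    card_bands = evaluation_bands(result.cardiac_waveform.fundamental.f0,
                                  cfg.cardiac_halfwidth, before, params,
                                  result.mask)
    resp_bp = band_power_proportion(before, after, params, result.mask,
                                    resp_bands, weighting=weighting)
    card_bp = band_power_proportion(before, after, params, result.mask,
                                    card_bands, weighting=weighting)
    oob = out_of_band_fluctuation(before, after, params, result.mask,
                                  resp_bands + card_bands,
                                  weighting=weighting)
    report = BandPowerReport(resp=resp_bp, cardiac=card_bp, out_of_band=oob)
    tsnr = tsnr_gain(before, after, result.mask, rois=rois)
    return EvalReport(band_power=report, tsnr=tsnr,
                      bands={"resp": resp_bands, "cardiac": card_bands})
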