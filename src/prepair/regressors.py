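"""Cycle phases, Fourier regressors and magnitude-vs-phase source selection.

Physiological noise is modelled retrospectively as sines and cosines of the
first two harmonics of the cardiac and respiratory cycle phases, evaluated
at each slice's own acquisition times (slice-wise RETROICOR-style
regressors).  The cardiac phase advances linearly between detected waveform
peaks; the respiratory phase follows the amplitude-histogram convention
(phase proportional to the empirical CDF of the belt amplitude, signed by
the derivative), which distinguishes inspiration from expiration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .data import AcquisitionParams, slice_acquisition_times
from .errors import (
    ConfigurationError,
    InsufficientCyclesError,
    PrepairWarning,
)
from .extract import SubTrSignal
from .identify import FundamentalEstimate, PhysioWaveform

__all__ = [
    "CyclePhase",
    "RegressorSet",
    "KindSelection",
    "SourceSelection",
    "detect_peaks",
    "cardiac_cycle_phase",
    "respiratory_cycle_phase",
    "fourier_expansion",
    "evaluate_variance_improvement",
    "select_source",
    "build_slicewise_regressors",
]

TWO_PI = 2.0 * np.pi


@dataclass
class CyclePhase:
    """Cycle-phase values in [0, 2*pi) at given times."""

    phi: np.ndarray
    times: np.ndarray
    kind: str

    def __post_init__(self):
        self.phi = np.mod(np.asarray(self.phi, dtype=float), TWO_PI)
        self.times = np.asarray(self.times, dtype=float)
        if self.phi.shape != self.times.shape:
            raise ConfigurationError("phi and times must share shape")


@dataclass
class RegressorSet:
    """Per-slice design matrices of the eight physiological regressors.

    ``matrices`` is ``(N, NR, 8)`` with columns
    ``resp sin/cos of harmonics 1-2`` then ``cardiac sin/cos of 1-2``;
    simultaneously excited slices share identical matrices.
    """

    matrices: np.ndarray
    sources: dict
    fundamentals: dict
    improvements: dict | None = None

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[2] != 8:
            raise ConfigurationError("matrices must be (N, NR, 8)")

    @property
    def n_slices(self) -> int:
        return self.matrices.shape[0]


@dataclass
class KindSelection:
    """Outcome of the magnitude-vs-phase comparison for one noise kind."""

    kind: str
    source: str  # "magnitude" | "phase"
    improvements: dict = field(default_factory=dict)


@dataclass
class SourceSelection:
    """Chosen data source per noise kind with the variance improvements."""

    resp: KindSelection
    cardiac: KindSelection

    @property
    def resp_source(self) -> str:
        return self.resp.source

    @property
    def cardiac_source(self) -> str:
        return self.cardiac.source


def detect_peaks(waveform: PhysioWaveform) -> np.ndarray:
    """Times of local maxima of a narrowband waveform.

    Peaks are separated by at least half the fundamental period and must be
    prominent above a quarter of the waveform's RMS amplitude; peak times
    are refined by parabolic interpolation of the three samples around each
    maximum.
    """
    x = waveform.samples
    f0 = waveform.fundamental.f0
    dt = 1.0 / waveform.rate
    rms = float(np.sqrt(np.mean(x ** 2)))
    if rms == 0:
        raise InsufficientCyclesError("constant waveform has no peaks")
    min_dist = max(1, int(round(0.5 / f0 * waveform.rate)))
    idx, _ = sps.find_peaks(x, distance=min_dist, prominence=0.25 * rms)
    if len(idx) < 2:
        raise InsufficientCyclesError(
            f"found {len(idx)} peaks; need at least 2 cycles")
    times = waveform.times[idx].astype(float)
    # parabolic refinement of each peak position
    interior = (idx > 0) & (idx < len(x) - 1)
    ii = idx[interior]
    denom = x[ii - 1] - 2 * x[ii] + x[ii + 1]
    ok = denom < 0
    delta = np.zeros(len(ii))
    delta[ok] = 0.5 * (x[ii - 1] - x[ii + 1])[ok] / denom[ok]
    delta = np.clip(delta, -0.5, 0.5)
    times[interior] = times[interior] + delta * dt
    return times


def cardiac_cycle_phase(peaks: np.ndarray, query_times: np.ndarray) -> CyclePhase:
    """Cardiac phase: 0 at each peak, advancing linearly to 2*pi at the next.

    Outside the peak range the nearest inter-peak period is extrapolated.
    """
    peaks = np.asarray(peaks, dtype=float)
    if len(peaks) < 2:
        raise InsufficientCyclesError("need at least two peaks")
    if np.any(np.diff(peaks) <= 0):
        raise ConfigurationError("peak times must be strictly increasing")
    t = np.asarray(query_times, dtype=float)
    # continuous cycle index: c(peak_k) = k, linear in between
    cycle = np.interp(t, peaks, np.arange(len(peaks), dtype=float))
    before = t < peaks[0]
    after = t > peaks[-1]
    if before.any():
        p0 = peaks[1] - peaks[0]
        cycle[before] = (t[before] - peaks[0]) / p0
    if after.any():
        p1 = peaks[-1] - peaks[-2]
        cycle[after] = (len(peaks) - 1) + (t[after] - peaks[-1]) / p1
    return CyclePhase(phi=TWO_PI * np.mod(cycle, 1.0), times=t, kind="cardiac")


def respiratory_cycle_phase(waveform: PhysioWaveform, query_times: np.ndarray,
                            n_bins: int = 100) -> CyclePhase:
    """Respiratory phase by the amplitude-histogram convention.

    ``phi(t) = pi * H(a(t)) * sgn(da/dt)`` mapped into [0, 2*pi), where H is
    the empirical cumulative histogram (``n_bins`` bins) of the waveform
    amplitude.  Deep inspiration maps to phi = pi regardless of the
    derivative sign.
    """
    a = waveform.samples
    if len(a) < 100:
        raise ConfigurationError("waveform too short for a stable histogram")
    if np.ptp(a) == 0:
        raise ConfigurationError("zero-variance waveform has no cycle phase")
    t = np.asarray(query_times, dtype=float)
    counts, edges = np.histogram(a, bins=n_bins)
    cdf = np.cumsum(counts) / counts.sum()
    a_q = np.interp(t, waveform.times, a)
    bins = np.clip(np.searchsorted(edges[1:-1], a_q), 0, n_bins - 1)
    h = cdf[bins]
    da = np.gradient(a, waveform.times)
    sign = np.where(np.interp(t, waveform.times, da) >= 0, 1.0, -1.0)
    return CyclePhase(phi=np.mod(np.pi * h * sign, TWO_PI), times=t, kind="resp")


def fourier_expansion(phase, n_harmonics: int = 2) -> np.ndarray:
    """Columns ``[sin k*phi, cos k*phi]`` for k = 1..n_harmonics."""
    phi = phase.phi if isinstance(phase, CyclePhase) else np.asarray(phase,
                                                                     dtype=float)
    cols = []
    for k in range(1, n_harmonics + 1):
        cols.append(np.sin(k * phi))
        cols.append(np.cos(k * phi))
    return np.column_stack(cols)


def _candidate_phase(candidate: PhysioWaveform, query_times: np.ndarray,
                     phase_convention: str = "default") -> CyclePhase:
    """Cycle phase of a candidate waveform at arbitrary times.

    Cardiac uses peak-to-peak linear phase; respiration the
    amplitude-histogram convention (``phase_convention="peaks"`` forces
    peak-to-peak for both kinds).
    """
    if candidate.kind == "cardiac" or phase_convention == "peaks":
        peaks = detect_peaks(candidate)
        ph = cardiac_cycle_phase(peaks, query_times)
        return CyclePhase(phi=ph.phi, times=ph.times, kind=candidate.kind)
    return respiratory_cycle_phase(candidate, query_times)


def evaluate_variance_improvement(candidate: PhysioWaveform,
                                  target: SubTrSignal,
                                  phase_convention: str = "default") -> float:
    """Fraction of the target's variance explained by the candidate's regressors.

    The candidate's two-harmonic Fourier regressors are evaluated at the
    target's sub-TR times and fitted to the target by least squares with an
    intercept; returns R^2 = 1 - SS_resid / SS_total.
    """
    if len(candidate.samples) != len(target.samples):
        raise ConfigurationError("candidate and target must share length")
    phase = _candidate_phase(candidate, target.times, phase_convention)
    x = np.column_stack([np.ones(len(target.samples)),
                         fourier_expansion(phase)])
    y = target.samples
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        warnings.warn(f"rank-deficient design (rank {rank} of {x.shape[1]}); "
                      "improvement computed on the reduced rank",
                      PrepairWarning, stacklevel=2)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum(resid ** 2)) / ss_tot


def select_source(mag_candidate: PhysioWaveform | None,
                  phase_candidate: PhysioWaveform | None,
                  mag_target: SubTrSignal,
                  phase_target: SubTrSignal | None = None,
                  target_mode: str = "same_source") -> KindSelection:
    """Choose the magnitude- or phase-derived waveform for one noise kind.

    With ``target_mode="same_source"`` (default) each candidate is scored
    by the variance it removes from its own source's sub-TR signal; with
    ``"magnitude"`` both are scored against the magnitude signal.  Ties
    within 1e-9 break to phase for respiration and magnitude for cardiac,
    matching the empirically better source for each kind.
    """
    if mag_candidate is None and phase_candidate is None:
        raise ConfigurationError("need at least one candidate waveform")
    kind = (mag_candidate or phase_candidate).kind
    improvements: dict = {}
    if mag_candidate is not None:
        improvements["magnitude"] = evaluate_variance_improvement(
            mag_candidate, mag_target)
    if phase_candidate is not None:
        tgt = phase_target if (target_mode == "same_source"
                               and phase_target is not None) else mag_target
        improvements["phase"] = evaluate_variance_improvement(
            phase_candidate, tgt)
    if mag_candidate is None:
        return KindSelection(kind=kind, source="phase", improvements=improvements)
    if phase_candidate is None:
        return KindSelection(kind=kind, source="magnitude",
                             improvements=improvements)
    diff = improvements["phase"] - improvements["magnitude"]
    if abs(diff) <= 1e-9:
        source = "phase" if kind == "resp" else "magnitude"
    else:
        source = "phase" if diff > 0 else "magnitude"
    return KindSelection(kind=kind, source=source, improvements=improvements)


def build_slicewise_regressors(resp_waveform: PhysioWaveform,
                               cardiac_waveform: PhysioWaveform,
                               params: AcquisitionParams,
                               sources: dict | None = None,
                               improvements: dict | None = None,
                               phase_convention: str = "default") -> RegressorSet:
    """Evaluate both cycle phases at every slice's acquisition times.

    Returns the ``(N, NR, 8)`` stack of per-slice design matrices; slices
    excited simultaneously share identical regressors.  Query times outside
    the waveform support are extrapolated from the nearest cycle with a
    warning.
    """
    t_mat = slice_acquisition_times(params)
    if (t_mat.min() < resp_waveform.times[0] - 1.0 / resp_waveform.rate
            or t_mat.max() > resp_waveform.times[-1] + 1.0 / resp_waveform.rate):
        warnings.warn("slice times extend beyond the waveform support; "
                      "nearest-cycle extrapolation used",
                      PrepairWarning, stacklevel=2)
    n, nr = t_mat.shape
    mats = np.empty((n, nr, 8))
    card_peaks = detect_peaks(cardiac_waveform)
    for g, grp in enumerate(params.slice_order):
        times = t_mat[grp[0]]
        resp_phi = _candidate_phase(resp_waveform, times, phase_convention)
        card_phi = cardiac_cycle_phase(card_peaks, times)
        block = np.hstack([fourier_expansion(resp_phi),
                           fourier_expansion(card_phi)])
        for s in grp:
            mats[s] = block
    return RegressorSet(
        matrices=mats,
        sources=sources or {"resp": resp_waveform.source,
                            "cardiac": cardiac_waveform.source},
        fundamentals={"resp": resp_waveform.fundamental,
                      "cardiac": cardiac_waveform.fundamental},
        improvements=improvements,
    )
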