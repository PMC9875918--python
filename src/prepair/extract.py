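"""Sub-TR signal extraction from 4D EPI data.

The pipeline condenses the 4D series into one scalar time series per data
source (magnitude, phase) sampled at the slice repetition interval:

1. select high-SNR voxels,
2. average each slice over the mask (magnitude-weighted mean for phase),
3. remove the slice dependence with a third-order polynomial per slice,
4. reorder the per-slice series according to the slice acquisition order,
   averaging simultaneously excited (SMS) slices, giving a series of length
   ``NR * NS`` at rate ``NS / tr_vol``.

The reordered series critically samples cardiac fluctuations that are
aliased at the volume TR, which is the point of the whole construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import AcquisitionParams, EpiSeries, VoxelMask, slice_acquisition_times
from .errors import (
    ConfigurationError,
    EmptyMaskError,
    InsufficientSamplesError,
    PrepairWarning,
)

__all__ = [
    "SliceSignal",
    "SubTrSignal",
    "compute_high_snr_mask",
    "threshold_mask",
    "unwrap_phase_temporal",
    "slice_average",
    "detrend_slice_signals",
    "reorder_to_subtr",
    "unreorder_from_subtr",
]


@dataclass
class SliceSignal:
    """Per-slice scalar time series sampled at the volume TR.

    ``values`` is ``[n_rows, NR]`` with rows in spatial slice order
    (``n_rows = N``) or, after SMS reduction, group order (``n_rows = NS``).
    """

    values: np.ndarray
    tr_vol: float
    source: str  # "magnitude" | "phase"
    detrended: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("SliceSignal values must be 2D [rows, NR]")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("SliceSignal contains non-finite values")


@dataclass
class SubTrSignal:
    """One scalar series at the sub-TR sampling rate ``NS / tr_vol``."""

    samples: np.ndarray
    rate: float
    times: np.ndarray
    source: str

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.samples.shape != self.times.shape:
            raise ConfigurationError("samples and times must share shape")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.samples)


def compute_high_snr_mask(magnitude: np.ndarray, fraction: float = 0.2,
                          percentile: float = 98.0,
                          reference: str = "temporal_mean") -> VoxelMask:
    """High-SNR voxel mask: temporal mean above ``fraction`` of a robust maximum.

    The robust maximum is the ``percentile``-th percentile (linear
    interpolation convention) of the temporal-mean image; with
    ``reference="all_values"`` it is taken over all voxel-time values
    instead.  A voxel is included iff its temporal mean exceeds
    ``fraction * P``.
    """
    mag = np.asarray(magnitude, dtype=float)
    if mag.ndim != 4 or mag.shape[3] < 2:
        raise InsufficientSamplesError("need a 4D array with >= 2 time points")
    tmean = mag.mean(axis=3)
    if reference == "temporal_mean":
        robust_max = np.percentile(tmean, percentile)
    elif reference == "all_values":
        robust_max = np.percentile(mag, percentile)
    else:
        raise ConfigurationError(f"unknown reference {reference!r}")
    mask = tmean > fraction * robust_max
    if not mask.any():
        raise EmptyMaskError("high-SNR criterion selected no voxels "
                             "(all-zero magnitude?)")
    return VoxelMask(mask=mask)


def threshold_mask(magnitude: np.ndarray, threshold: float = 3000.0) -> VoxelMask:
    """Fixed-intensity mask: temporal mean above an absolute threshold.

    Useful for partial-coverage acquisitions (e.g. brainstem slabs) where a
    relative criterion would discard voxels of interest.
    """
    tmean = np.asarray(magnitude, dtype=float).mean(axis=3)
    mask = tmean > threshold
    if not mask.any():
        raise EmptyMaskError(f"no voxel exceeds intensity {threshold}")
    return VoxelMask(mask=mask)


def unwrap_phase_temporal(phase: np.ndarray) -> np.ndarray:
    """Per-voxel temporal phase unwrap along the last axis.

    Successive differences are adjusted by multiples of 2*pi so that each
    step is at most pi in magnitude; the first sample is unchanged.  This is
    a fallback for when spatially unwrapped phase is unavailable; it cannot
    fix wraps faster than half a cycle per sample.
    """
    return np.unwrap(np.asarray(phase, dtype=float), axis=-1)


def slice_average(series: EpiSeries, mask: VoxelMask
                  ) -> tuple[SliceSignal, SliceSignal | None]:
    """Average masked voxels per slice and time point.

    Magnitude rows are plain means; phase rows are magnitude-weighted means
    ``sum(m * phi) / sum(m)`` over the same mask (phase should already be
    unwrapped).  Slices whose mask is empty are filled with the nearest
    non-empty slice's row and flagged with a warning.
    """
    if mask.mask.shape != series.spatial_shape:
        raise ConfigurationError("mask shape does not match the series")
    n, nr = series.params.n_slices, series.params.n_reps
    mag = series.magnitude
    phase = series.phase
    mag_rows = np.full((n, nr), np.nan)
    phase_rows = np.full((n, nr), np.nan) if phase is not None else None
    empty = []
    for z in range(n):
        sel = mask.mask[:, :, z]
        if not sel.any():
            empty.append(z)
            continue
        m = mag[:, :, z, :][sel]           # (nvox, NR)
        mag_rows[z] = m.mean(axis=0)
        if phase is not None:
            p = phase[:, :, z, :][sel]
            w = m.sum(axis=0)
            phase_rows[z] = (m * p).sum(axis=0) / w
    if empty:
        nonempty = np.setdiff1d(np.arange(n), empty)
        if len(nonempty) == 0:
            raise EmptyMaskError("mask is empty in every slice")
        warnings.warn(
            f"slices {empty} have no masked voxels; filled from nearest slice",
            PrepairWarning, stacklevel=2)
        for z in empty:
            src = nonempty[np.argmin(np.abs(nonempty - z))]
            mag_rows[z] = mag_rows[src]
            if phase_rows is not None:
                phase_rows[z] = phase_rows[src]
    mag_sig = SliceSignal(mag_rows, series.params.tr_vol, "magnitude")
    phase_sig = (SliceSignal(phase_rows, series.params.tr_vol, "phase")
                 if phase_rows is not None else None)
    return mag_sig, phase_sig


def detrend_slice_signals(signal: SliceSignal, order: int = 3) -> SliceSignal:
    """Fit and subtract a degree-``order`` polynomial from each row.

    Removes the slice-dependent baseline and slow scanner drift over the
    full run duration; residual rows have (numerically) zero mean and zero
    projection onto the polynomial basis.
    """
    nr = signal.values.shape[1]
    if nr < order + 2:
        raise InsufficientSamplesError(
            f"need at least {order + 2} time points to fit order {order}, got {nr}")
    # scaled time for conditioning; the fitted subspace is unchanged
    x = np.linspace(-1.0, 1.0, nr)
    basis = np.polynomial.polynomial.polyvander(x, order)  # (NR, order+1)
    coef, *_ = np.linalg.lstsq(basis, signal.values.T, rcond=None)
    resid = signal.values - (basis @ coef).T
    return SliceSignal(resid, signal.tr_vol, signal.source, detrended=True)


def reorder_to_subtr(signal: SliceSignal, params: AcquisitionParams) -> SubTrSignal:
    """Reorder per-slice series into one sub-TR series.

    Rows of simultaneously excited slices are averaged (unweighted) to NS
    group rows; within each volume the groups are interleaved in temporal
    rank order, yielding ``NR * NS`` samples at rate ``NS / tr_vol`` with
    times from :func:`slice_acquisition_times`.
    """
    n, nr = signal.values.shape
    if n != params.n_slices:
        raise ConfigurationError(
            f"signal has {n} rows, params expect N={params.n_slices}")
    if nr != params.n_reps:
        raise ConfigurationError(
            f"signal has {nr} columns, params expect NR={params.n_reps}")
    ns = params.ns
    group_rows = np.empty((ns, nr))
    for g, grp in enumerate(params.slice_order):
        group_rows[g] = signal.values[list(grp)].mean(axis=0)
    # interleave: sample index v*NS + g  ->  group g, volume v
    samples = group_rows.T.reshape(nr * ns)
    t_mat = slice_acquisition_times(params)
    group_times = t_mat[[grp[0] for grp in params.slice_order], :]  # (NS, NR)
    times = group_times.T.reshape(nr * ns)
    return SubTrSignal(samples=samples, rate=params.subtr_rate,
                       times=times, source=signal.source)


def unreorder_from_subtr(signal: SubTrSignal, params: AcquisitionParams
                         ) -> SliceSignal:
    """Inverse of :func:`reorder_to_subtr` for MB=1 (a pure interleave)."""
    if params.mb_factor != 1:
        raise ConfigurationError("un-reordering is only defined for MB=1")
    ns, nr = params.ns, params.n_reps
    group_rows = signal.samples.reshape(nr, ns).T
    rows = np.empty_like(group_rows)
    for g, grp in enumerate(params.slice_order):
        rows[grp[0]] = group_rows[g]
    return SliceSignal(rows, params.tr_vol, signal.source)
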