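"""Core data containers and slice-acquisition timing.

The pipeline works on 4D echo-planar imaging (EPI) series stored as
``[x, y, z, t]`` arrays (0-based, slice axis third).  Acquisition metadata is
carried by :class:`AcquisitionParams`; times are seconds, frequencies Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DimensionMismatchError

__all__ = [
    "AcquisitionParams",
    "EpiSeries",
    "ExternalRecording",
    "VoxelMask",
    "default_slice_order",
    "slice_acquisition_times",
]


def default_slice_order(n_slices: int, mb_factor: int) -> tuple[tuple[int, ...], ...]:
    """Sequential-ascending SMS slice order.

    Excitation group ``g`` (temporal rank ``g``) contains slices
    ``{g, g + NS, ..., g + (MB-1)*NS}`` with ``NS = N/MB`` excitations per
    volume TR, the standard ordering for sequential ascending multiband
    acquisitions.
    """
    if n_slices % mb_factor:
        raise ConfigurationError(
            f"n_slices={n_slices} is not divisible by mb_factor={mb_factor}"
        )
    ns = n_slices // mb_factor
    return tuple(
        tuple(g + k * ns for k in range(mb_factor)) for g in range(ns)
    )


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition geometry and timing of one EPI run.

    Parameters
    ----------
    tr_vol : float
        Volume repetition time, seconds.
    n_slices : int
        Number of slices N (z extent of the arrays).
    n_reps : int
        Number of repetitions NR (t extent of the arrays).
    mb_factor : int
        Multiband/SMS factor MB; ``NS = N / MB`` excitations per TR.
    slice_order : tuple of tuples, optional
        Excitation groups in temporal order within one TR; each group lists
        the slice indices excited simultaneously.  Defaults to sequential
        ascending with SMS grouping (see :func:`default_slice_order`).
    slice_offsets : tuple of float, optional
        Excitation time of each group within the TR, seconds.  Defaults to
        uniform spacing ``g * tr_vol / NS`` with zero dead time.
    """

    tr_vol: float
    n_slices: int
    n_reps: int
    mb_factor: int = 1
    slice_order: tuple[tuple[int, ...], ...] | None = None
    slice_offsets: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.tr_vol <= 0:
            raise ConfigurationError("tr_vol must be positive")
        if self.n_reps < 1 or self.n_slices < 1 or self.mb_factor < 1:
            raise ConfigurationError("n_reps, n_slices and mb_factor must be >= 1")
        if self.n_slices % self.mb_factor:
            raise ConfigurationError(
                f"n_slices={self.n_slices} not divisible by mb_factor={self.mb_factor}"
            )
        ns = self.n_slices // self.mb_factor
        if self.slice_order is None:
            object.__setattr__(
                self, "slice_order", default_slice_order(self.n_slices, self.mb_factor)
            )
        else:
            order = tuple(tuple(int(s) for s in grp) for grp in self.slice_order)
            object.__setattr__(self, "slice_order", order)
        if len(self.slice_order) != ns:
            raise ConfigurationError(
                f"slice_order has {len(self.slice_order)} groups, expected NS={ns}"
            )
        seen = sorted(s for grp in self.slice_order for s in grp)
        if seen != list(range(self.n_slices)):
            raise ConfigurationError(
                "slice_order must contain every slice index 0..N-1 exactly once"
            )
        if any(len(grp) != self.mb_factor for grp in self.slice_order):
            raise ConfigurationError("every excitation group must have MB members")
        if self.slice_offsets is not None:
            offs = tuple(float(o) for o in self.slice_offsets)
            if len(offs) != ns:
                raise ConfigurationError("slice_offsets must have one entry per group")
            if any(not (0 <= o < self.tr_vol) for o in offs):
                raise ConfigurationError("slice_offsets must lie in [0, tr_vol)")
            if any(b <= a for a, b in zip(offs, offs[1:])):
                raise ConfigurationError("slice_offsets must be strictly increasing")
            object.__setattr__(self, "slice_offsets", offs)

    @property
    def ns(self) -> int:
        """Number of excitation groups per TR, ``NS = N / MB``."""
        return self.n_slices // self.mb_factor

    @property
    def subtr_rate(self) -> float:
        """Sub-TR sampling rate ``NS / tr_vol``, Hz."""
        return self.ns / self.tr_vol

    @property
    def group_offsets(self) -> np.ndarray:
        """Excitation time of each group within the TR, seconds."""
        if self.slice_offsets is not None:
            return np.asarray(self.slice_offsets, dtype=float)
        return np.arange(self.ns) * (self.tr_vol / self.ns)

    @property
    def group_of_slice(self) -> np.ndarray:
        """Temporal rank of the excitation group of each slice."""
        rank = np.empty(self.n_slices, dtype=int)
        for g, grp in enumerate(self.slice_order):
            for s in grp:
                rank[s] = g
        return rank


def slice_acquisition_times(params: AcquisitionParams) -> np.ndarray:
    """Acquisition time of every slice in every volume.

    Returns an ``(N, NR)`` matrix with
    ``t[s, v] = v * tr_vol + offset(group(s))``; simultaneously excited
    slices share a row of identical times.
    """
    offsets = params.group_offsets[params.group_of_slice]
    vols = np.arange(params.n_reps) * params.tr_vol
    return offsets[:, None] + vols[None, :]


@dataclass
class EpiSeries:
    """A 4D magnitude (+ optional phase) EPI time series with its metadata.

    ``magnitude`` is nonnegative in arbitrary units, ``phase`` is radians
    (wrapped or unwrapped, as stored).  Arrays are ``[x, y, z, t]`` with
    ``z == N`` and ``t == NR``.
    """

    magnitude: np.ndarray
    params: AcquisitionParams
    phase: np.ndarray | None = None

    def __post_init__(self):
        m = np.asarray(self.magnitude)
        if m.ndim != 4:
            raise DimensionMismatchError(
                f"magnitude must be 4D [x, y, z, t], got {m.ndim}D"
            )
        if m.shape[2] != self.params.n_slices:
            raise DimensionMismatchError(
                f"z axis has {m.shape[2]} slices, params expect {self.params.n_slices}"
            )
        if m.shape[3] != self.params.n_reps:
            raise DimensionMismatchError(
                f"t axis has {m.shape[3]} volumes, params expect {self.params.n_reps}"
            )
        if np.any(m < 0):
            raise ConfigurationError("magnitude values must be nonnegative")
        if self.phase is not None:
            p = np.asarray(self.phase)
            if p.shape != m.shape:
                ax = next(
                    i for i, (a, b) in enumerate(zip(m.shape, p.shape)) if a != b
                )
                raise DimensionMismatchError(
                    f"phase shape {p.shape} differs from magnitude {m.shape} "
                    f"on axis {ax}"
                )
        self.magnitude = m

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape[:3]


@dataclass
class VoxelMask:
    """Boolean 3D voxel selection ``[x, y, z]``."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.ndim != 3 or m.dtype != bool:
            raise DimensionMismatchError("mask must be a 3D boolean array")
        self.mask = m

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def empty_slices(self) -> np.ndarray:
        """Indices of slices (z) containing no selected voxel."""
        per_slice = self.mask.sum(axis=(0, 1))
        return np.flatnonzero(per_slice == 0)


@dataclass
class ExternalRecording:
    """Respiratory-belt and plethysmograph samples at a fixed interval.

    ``t0`` is the time of the first sample relative to the first excitation.
    """

    resp: np.ndarray
    cardiac: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self):
        self.resp = np.asarray(self.resp, dtype=float)
        self.cardiac = np.asarray(self.cardiac, dtype=float)
        if self.dt <= 0:
            raise ConfigurationError("sampling interval dt must be positive")
        if self.resp.shape != self.cardiac.shape:
            raise DimensionMismatchError("resp and cardiac must have equal length")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.resp))
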