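"""Voxelwise, slice-wise removal of the modelled physiological noise.

Each voxel's time series is regressed on its slice's eight physiological
regressors after these have been orthogonalized against an intercept +
polynomial drift basis; only the fitted physiological part is subtracted.
Drift and mean are retained in the data, so the correction alters in-band
physiological content only and the per-voxel variance can never increase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import EpiSeries, VoxelMask
from .errors import ConfigurationError, PrepairWarning
from .regressors import RegressorSet

__all__ = ["CorrectionResult", "regress_out_physio"]


@dataclass
class CorrectionResult:
    """Corrected 4D magnitude with the per-voxel variance fraction removed."""

    corrected: np.ndarray
    r2_map: np.ndarray
    design_info: list


def _drift_basis(nr: int, order: int) -> np.ndarray:
    # Legendre basis on [-1, 1]: well conditioned, first column constant
    x = np.linspace(-1.0, 1.0, nr)
    return np.polynomial.legendre.legvander(x, order)


def regress_out_physio(series: EpiSeries, regressors: RegressorSet,
                       mask: VoxelMask, drift_order: int = 3) -> CorrectionResult:
    """Remove fitted physiological noise from masked voxels, slice by slice.

    For every slice the physiological columns are orthogonalized against
    the drift basis, then each masked voxel is fitted by ordinary least
    squares on [drift basis + orthogonalized physio columns] and only the
    physiological fit is subtracted.  ``r2_map`` holds the fraction of each
    voxel's (mean-removed) variance carried by the subtracted part; voxels
    outside the mask are returned bit-identical to the input.
    """
    n, nr = series.params.n_slices, series.params.n_reps
    if regressors.n_slices != n:
        raise ConfigurationError(
            f"regressors cover {regressors.n_slices} slices, series has {n}")
    if regressors.matrices.shape[1] != nr:
        raise ConfigurationError(
            f"regressors have {regressors.matrices.shape[1]} volumes, "
            f"series has {nr}")
    if mask.mask.shape != series.spatial_shape:
        raise ConfigurationError("mask shape does not match the series")
    corrected = series.magnitude.copy()
    r2_map = np.zeros(series.spatial_shape)
    design_info = []
    drift = _drift_basis(nr, drift_order)
    for z in range(n):
        sel = mask.mask[:, :, z]
        x_raw = regressors.matrices[z]  # (NR, 8)
        # orthogonalize physio columns against the retained drift basis
        coef, *_ = np.linalg.lstsq(drift, x_raw, rcond=None)
        x = x_raw - drift @ coef
        norms = np.linalg.norm(x, axis=0)
        keep = norms > 1e-10 * max(1.0, norms.max())
        if not np.all(keep):
            dropped = list(np.flatnonzero(~keep))
            warnings.warn(
                f"slice {z}: dropped dependent physiological columns {dropped}",
                PrepairWarning, stacklevel=2)
        x = x[:, keep]
        rank = int(np.linalg.matrix_rank(x)) if x.shape[1] else 0
        design_info.append({"slice": z, "n_columns": int(keep.sum()),
                            "rank": rank})
        if not sel.any() or x.shape[1] == 0:
            continue
        y = series.magnitude[:, :, z, :][sel].T  # (NR, nvox)
        # x is orthogonal to drift (incl. the constant), so the physio
        # coefficients of the joint fit equal the fit on x alone
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        fit = x @ beta
        corrected[:, :, z, :][sel] = (y - fit).T
        ss_tot = np.sum((y - y.mean(axis=0)) ** 2, axis=0)
        ss_fit = np.sum(fit ** 2, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(ss_tot > 0, ss_fit / ss_tot, 0.0)
        r2_map[:, :, z][sel] = np.clip(r2, 0.0, 1.0)
    return CorrectionResult(corrected=corrected, r2_map=r2_map,
                            design_info=design_info)
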