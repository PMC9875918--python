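"""NIfTI, table and sidecar I/O.

NIfTI images are read/written with nibabel; arrays are kept in the canonical
``[x, y, z, t]`` order as stored and saved as float64 so that synthetic
write/read round-trips are lossless.  Regressor and recording tables are
tab-separated text with a JSON sidecar for metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .data import AcquisitionParams, EpiSeries, ExternalRecording, VoxelMask
from .errors import DimensionMismatchError, FormatError, TableParseError

__all__ = [
    "load_epi_series",
    "save_epi_series",
    "load_mask",
    "save_map",
    "load_external_recording",
    "write_external_recording",
    "write_regressor_table",
    "read_regressor_table",
    "REGRESSOR_COLUMNS",
]

REGRESSOR_COLUMNS = [
    "resp_sin1", "resp_cos1", "resp_sin2", "resp_cos2",
    "card_sin1", "card_cos1", "card_sin2", "card_cos2",
]


def _load_4d(path) -> tuple[np.ndarray, nib.Nifti1Image]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D volumetric image, got {data.ndim}D")
    return data.astype(np.float64, copy=False), img


def load_epi_series(magnitude_path, phase_path=None,
                    params: AcquisitionParams | None = None) -> EpiSeries:
    """Load a 4D magnitude (and optional co-registered phase) NIfTI pair.

    Phase is left untouched (wrapped or unwrapped as stored).  Shapes are
    checked against each other and against ``params`` when given.
    """
    mag, _ = _load_4d(magnitude_path)
    phase = None
    if phase_path is not None:
        phase, _ = _load_4d(phase_path)
        if phase.shape != mag.shape:
            ax = next(i for i, (a, b) in enumerate(zip(mag.shape, phase.shape))
                      if a != b)
            raise DimensionMismatchError(
                f"phase shape {phase.shape} differs from magnitude {mag.shape} "
                f"on axis {ax}")
    if params is None:
        raise ValueError("acquisition params are required to build an EpiSeries")
    return EpiSeries(magnitude=mag, params=params, phase=phase)


def save_epi_series(series: EpiSeries, magnitude_path, phase_path=None,
                    affine: np.ndarray | None = None) -> None:
    aff = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(series.magnitude.astype(np.float64), aff)
    img.set_data_dtype(np.float64)
    nib.save(img, str(magnitude_path))
    if phase_path is not None and series.phase is not None:
        pimg = nib.Nifti1Image(series.phase.astype(np.float64), aff)
        pimg.set_data_dtype(np.float64)
        nib.save(pimg, str(phase_path))


def load_mask(path) -> VoxelMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask image, got {data.ndim}D")
    return VoxelMask(mask=data > 0)


def save_map(array: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a 3D map (mask, tSNR, gain, R^2) as NIfTI."""
    aff = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), aff)
    img.set_data_dtype(np.float64)
    nib.save(img, str(path))


def load_external_recording(path, dt: float, t0: float = 0.0) -> ExternalRecording:
    """Read a two-column (resp, cardiac) numeric text table sampled at ``dt``.

    A single non-numeric first line is accepted as a header; any later
    non-numeric row raises :class:`TableParseError` with its line number.
    """
    resp, cardiac = [], []
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    rows = [(i, ln.strip()) for i, ln in enumerate(lines, start=1) if ln.strip()]
    if not rows:
        raise TableParseError(f"{path}: file contains no data rows")
    # optional header
    first_fields = rows[0][1].replace(",", "\t").split()
    try:
        [float(x) for x in first_fields]
    except ValueError:
        start = 1
    if len(rows) == start:
        raise TableParseError(f"{path}: file contains no data rows")
    for lineno, line in rows[start:]:
        fields = line.replace(",", "\t").split()
        if len(fields) < 2:
            raise TableParseError(f"{path}: expected two columns", lineno)
        try:
            r, c = float(fields[0]), float(fields[1])
        except ValueError:
            raise TableParseError(f"{path}: non-numeric row", lineno) from None
        resp.append(r)
        cardiac.append(c)
    return ExternalRecording(resp=np.array(resp), cardiac=np.array(cardiac),
                             dt=dt, t0=t0)


def write_external_recording(recording: ExternalRecording, path) -> None:
    df = pd.DataFrame({"resp": recording.resp, "cardiac": recording.cardiac})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_regressor_table(regressors, path) -> None:
    """Write a RegressorSet as one long-format TSV plus a JSON sidecar.

    The table has ``N * NR`` rows and columns ``slice, volume`` followed by
    the eight physiological regressor columns (sin/cos of the first two
    harmonics of the respiratory and cardiac cycle phases).  The sidecar
    records the chosen sources, fundamentals and bands.
    """
    mats = regressors.matrices  # (N, NR, 8)
    n, nr, _ = mats.shape
    df = pd.DataFrame(mats.reshape(n * nr, 8), columns=REGRESSOR_COLUMNS)
    df.insert(0, "volume", np.tile(np.arange(nr), n))
    df.insert(0, "slice", np.repeat(np.arange(n), nr))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = Path(str(path)).with_suffix(".json")
    meta = {
        "software": "prepair",
        "version": __version__,
        "columns": REGRESSOR_COLUMNS,
        "sources": regressors.sources,
        "fundamentals_hz": {
            kind: est.f0 for kind, est in regressors.fundamentals.items()
            if est is not None
        },
        "bands_hz": {
            kind: list(est.band) for kind, est in regressors.fundamentals.items()
            if est is not None
        },
    }
    if regressors.improvements is not None:
        meta["variance_improvements"] = regressors.improvements
    sidecar.write_text(json.dumps(meta, indent=2))


def read_regressor_table(path) -> tuple[np.ndarray, dict]:
    """Read back a regressor table written by :func:`write_regressor_table`.

    Returns the ``(N, NR, 8)`` matrix stack and the sidecar metadata dict
    (empty if the sidecar is missing).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("slice", "volume", *REGRESSOR_COLUMNS)
               if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing columns {missing}")
    n = int(df["slice"].max()) + 1
    nr = int(df["volume"].max()) + 1
    if len(df) != n * nr:
        raise TableParseError(f"{path}: expected {n * nr} rows, found {len(df)}")
    df = df.sort_values(["slice", "volume"], kind="stable")
    mats = df[REGRESSOR_COLUMNS].to_numpy().reshape(n, nr, 8)
    sidecar = Path(str(path)).with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return mats, meta
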