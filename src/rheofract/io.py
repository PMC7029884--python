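"""Delimited-text formats for time series, oscillatory sweeps and fits.

One fixed dialect, no unit inference: comma-separated values, ``#``-prefixed
metadata header carrying a JSON document, columns named with their units —
``time_s``, ``strain``, ``stress_pa`` for time series and ``omega_rad_s``,
``g_storage_pa``, ``g_loss_pa`` for oscillatory records.  Values are written
with 17 significant digits, so a write/read round trip reproduces float64
exactly.  A creep record may omit the stress column (strain-only); the
reader then marks stress as absent rather than guessing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .response import MechanicalTimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_oscillatory",
    "write_oscillatory",
    "MissingColumnError",
    "NonNumericDataError",
    "NonMonotonicTimeError",
    "RheoIOError",
]

_FLOAT_FMT = "%.17g"
_META_PREFIX = "# meta: "


class RheoIOError(ValueError):
    """Base class for file-format errors."""


class MissingColumnError(RheoIOError):
    pass


class NonNumericDataError(RheoIOError):
    pass


class NonMonotonicTimeError(RheoIOError):
    pass


def write_timeseries(series: MechanicalTimeSeries, path) -> None:
    """Write a (time, strain, stress) record in the package dialect."""
    path = Path(path)
    cols = {"time_s": series.time}
    if series.strain is not None:
        cols["strain"] = series.strain
    if series.stress is not None:
        cols["stress_pa"] = series.stress
    frame = pd.DataFrame(cols)
    with path.open("w") as fh:
        fh.write("# rheofract timeseries v1\n")
        if series.meta:
            fh.write(_META_PREFIX + json.dumps(series.meta) + "\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _read_table(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            if line.startswith(_META_PREFIX):
                meta = json.loads(line[len(_META_PREFIX):])
        else:
            body.append(line)
    from io import StringIO

    # round_trip parsing: the default fast parser is off by an ulp, which
    # would break bitwise write/read reproducibility
    frame = pd.read_csv(StringIO("".join(body)), float_precision="round_trip")
    return frame, meta


def _numeric(frame: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(frame[col], errors="coerce")
    if vals.isna().any() and not frame[col].isna().any():
        bad = frame[col][vals.isna()].iloc[0]
        raise NonNumericDataError(f"{path}: non-numeric cell {bad!r} in column {col}")
    if vals.isna().any():
        raise NonNumericDataError(f"{path}: empty cells in column {col}")
    return vals.to_numpy(dtype=float)


def read_timeseries(path) -> MechanicalTimeSeries:
    """Read and validate a time-series file.

    Raises ``MissingColumnError`` (no time column), ``NonNumericDataError``
    or ``NonMonotonicTimeError`` as distinct failures.  Strain-only creep
    records are accepted with stress marked absent (``None``).
    """
    frame, meta = _read_table(path)
    if "time_s" not in frame.columns:
        raise MissingColumnError(f"{path}: required column time_s is missing")
    if "strain" not in frame.columns and "stress_pa" not in frame.columns:
        raise MissingColumnError(f"{path}: need at least one of strain, stress_pa")
    time = _numeric(frame, "time_s", path)
    if np.any(np.diff(time) < 0):
        raise NonMonotonicTimeError(f"{path}: time_s must be non-decreasing")
    strain = _numeric(frame, "strain", path) if "strain" in frame.columns else None
    stress = _numeric(frame, "stress_pa", path) if "stress_pa" in frame.columns else None
    return MechanicalTimeSeries(time=time, strain=strain, stress=stress, meta=meta)


def write_oscillatory(omega, g_storage, g_loss, path, meta: dict | None = None) -> None:
    """Write an oscillatory sweep (omega_rad_s, g_storage_pa, g_loss_pa)."""
    path = Path(path)
    frame = pd.DataFrame(
        {"omega_rad_s": omega, "g_storage_pa": g_storage, "g_loss_pa": g_loss}
    )
    with path.open("w") as fh:
        fh.write("# rheofract oscillatory v1\n")
        if meta:
            fh.write(_META_PREFIX + json.dumps(meta) + "\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_oscillatory(path):
    """Read an oscillatory sweep; returns ``(omega, g_storage, g_loss, meta)``."""
    frame, meta = _read_table(path)
    for col in ("omega_rad_s", "g_storage_pa", "g_loss_pa"):
        if col not in frame.columns:
            raise MissingColumnError(f"{path}: required column {col} is missing")
    w = _numeric(frame, "omega_rad_s", path)
    if np.any(np.diff(w) < 0):
        raise NonMonotonicTimeError(f"{path}: omega_rad_s must be non-decreasing")
    return (
        w,
        _numeric(frame, "g_storage_pa", path),
        _numeric(frame, "g_loss_pa", path),
        meta,
    )
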