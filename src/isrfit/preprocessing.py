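"""Sparse OGTT records and the dense interpolated glucose input.

An oral glucose tolerance test yields glucose, insulin and c-peptide
concentrations at a handful of times over roughly three hours.  Glucose
drives the secretion models as an exogenous input, so it must be present at
every used time and is resampled to a dense grid with a cubic spline;
insulin and c-peptide may have missing entries (stored as NaN) which are
simply excluded from fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .models import Trajectory, convert_glucose  # noqa: F401  (re-exported for convenience)

__all__ = [
    "OGTTRecord",
    "GlucoseInput",
    "OGTTFormatError",
    "load_ogtt",
    "write_ogtt",
    "interpolate_glucose",
    "drop_timepoint",
]

CSV_COLUMNS = ("time_min", "glucose", "insulin", "cpeptide")

#: minimum number of glucose knots for cubic interpolation
MIN_GLUCOSE_POINTS = 4


class OGTTFormatError(ValueError):
    """Raised when an OGTT table violates the record invariants."""


@dataclass(frozen=True)
class OGTTRecord:
    """One subject's sparse OGTT measurements.

    ``insulin`` and ``cpeptide`` use NaN for missing entries; ``glucose``
    must be complete.  Times are minutes relative to the glucose dose
    (negative = fasting baseline draw).
    """

    times: np.ndarray
    glucose: np.ndarray
    insulin: Optional[np.ndarray] = None
    cpeptide: Optional[np.ndarray] = None
    subject_id: str = ""
    glucose_unit: str = "mg/dl"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        glucose = np.asarray(self.glucose, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "glucose", glucose)
        n = times.size
        if times.ndim != 1:
            raise OGTTFormatError("times must be a 1-d array")
        if np.any(np.diff(times) <= 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
            raise OGTTFormatError(f"times must be strictly increasing (violated at row {bad})")
        if glucose.shape != times.shape:
            raise OGTTFormatError("glucose length must match times")
        if np.any(~np.isfinite(glucose)):
            bad = int(np.flatnonzero(~np.isfinite(glucose))[0])
            raise OGTTFormatError(f"glucose missing/non-finite at row {bad}")
        if np.any(glucose < 0):
            bad = int(np.flatnonzero(glucose < 0)[0])
            raise OGTTFormatError(f"negative glucose at row {bad}")
        if n < MIN_GLUCOSE_POINTS:
            raise OGTTFormatError(
                f"need at least {MIN_GLUCOSE_POINTS} glucose points for cubic interpolation, got {n}"
            )
        for name in ("insulin", "cpeptide"):
            series = getattr(self, name)
            if series is None:
                continue
            series = np.asarray(series, dtype=float)
            object.__setattr__(self, name, series)
            if series.shape != times.shape:
                raise OGTTFormatError(f"{name} length must match times")
            finite = series[np.isfinite(series)]
            if np.any(finite < 0):
                raise OGTTFormatError(f"negative {name} concentration")
        if self.glucose_unit not in ("mg/dl", "mg/L"):
            raise OGTTFormatError(f"unsupported glucose unit {self.glucose_unit!r}")

    def has_species(self, species: str) -> bool:
        series = self._series(species)
        return series is not None and bool(np.any(np.isfinite(series)))

    def species_values(self, species: str) -> Tuple[np.ndarray, np.ndarray]:
        """Measurement times and values for one species, missing entries dropped."""
        series = self._series(species)
        if series is None:
            return np.empty(0), np.empty(0)
        mask = np.isfinite(series)
        return self.times[mask], series[mask]

    def _series(self, species: str) -> Optional[np.ndarray]:
        if species not in ("insulin", "cpeptide"):
            raise ValueError(f"unknown species {species!r}")
        return getattr(self, species)


@dataclass(frozen=True)
class GlucoseInput:
    """Dense interpolated glucose trajectory used as the model input.

    Callable on any time (scalar or array) within ``span``; the underlying
    cubic spline passes exactly through every measured knot and negative
    excursions from spline overshoot are clipped at zero.
    """

    grid_times: np.ndarray
    values: np.ndarray
    interpolant: CubicSpline
    span: Tuple[float, float]

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < self.span[0] - 1e-9) or np.any(t_arr > self.span[1] + 1e-9):
            raise ValueError(f"time outside the interpolation span {self.span}")
        return np.clip(self.interpolant(t_arr), 0.0, None)


def load_ogtt(path, glucose_unit: str = "mg/dl") -> OGTTRecord:
    """Read a sparse OGTT record from CSV.

    Expected header columns: ``time_min, glucose, insulin, cpeptide``
    (insulin / cpeptide cells may be empty).  An optional leading comment
    line ``# key=value, ...`` may carry ``glucose_unit`` and ``subject_id``
    metadata, overriding the ``glucose_unit`` argument.
    """
    path = Path(path)
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        for part in first.lstrip("#").split(","):
            if "=" in part:
                k, v = part.split("=", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, skiprows=skip)
    missing = {"time_min", "glucose"} - set(df.columns)
    if missing:
        raise OGTTFormatError(f"missing required columns: {sorted(missing)}")
    try:
        return OGTTRecord(
            times=df["time_min"].to_numpy(float),
            glucose=df["glucose"].to_numpy(float),
            insulin=df["insulin"].to_numpy(float) if "insulin" in df.columns else None,
            cpeptide=df["cpeptide"].to_numpy(float) if "cpeptide" in df.columns else None,
            subject_id=meta.get("subject_id", path.stem),
            glucose_unit=meta.get("glucose_unit", glucose_unit),
        )
    except OGTTFormatError as exc:
        raise OGTTFormatError(f"{path}: {exc}") from None


def write_ogtt(rec: OGTTRecord, path) -> None:
    """Write a record to CSV with a metadata comment line (inverse of load_ogtt)."""
    df = pd.DataFrame({"time_min": rec.times, "glucose": rec.glucose})
    for name in ("insulin", "cpeptide"):
        series = getattr(rec, name)
        if series is not None:
            df[name] = series
    with open(path, "w") as fh:
        fh.write(f"# glucose_unit={rec.glucose_unit}, subject_id={rec.subject_id}\n")
        df.to_csv(fh, index=False)


def interpolate_glucose(rec: OGTTRecord, step: float = 1.0, bc_type: str = "natural") -> GlucoseInput:
    """Cubic-spline resampling of the sparse glucose samples.

    ``bc_type`` is ``"natural"`` (zero second derivative at the ends, the
    default, which avoids overshoot at the sparse record ends) or
    ``"not-a-knot"``.  The grid covers the full measured span at the
    requested step; no extrapolation beyond the first/last sample.
    """
    if step <= 0:
        raise ValueError("interpolation step must be > 0")
    spline = CubicSpline(rec.times, rec.glucose, bc_type=bc_type)
    t0, t1 = float(rec.times[0]), float(rec.times[-1])
    n = int(np.floor((t1 - t0) / step + 1e-9))
    grid = t0 + step * np.arange(n + 1)
    if grid[-1] < t1 - 1e-9:
        grid = np.append(grid, t1)
    values = spline(grid)
    if np.any(values < 0):
        warnings.warn(
            "interpolated glucose went negative (spline overshoot); clipping at 0",
            stacklevel=2,
        )
        values = np.clip(values, 0.0, None)
    return GlucoseInput(grid_times=grid, values=values, interpolant=spline, span=(t0, t1))


def drop_timepoint(rec: OGTTRecord, t: float) -> OGTTRecord:
    """Remove one sample time with all its measurements, returning a new record.

    Used for leave-one-point-out screening: the glucose gap left behind is
    bridged by the interpolant of the remaining samples.
    """
    match = np.isclose(rec.times, t)
    if not np.any(match):
        raise KeyError(f"time {t} min is not a sample time of the record")
    keep = ~match
    return replace(
        rec,
        times=rec.times[keep],
        glucose=rec.glucose[keep],
        insulin=None if rec.insulin is None else rec.insulin[keep],
        cpeptide=None if rec.cpeptide is None else rec.cpeptide[keep],
    )
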