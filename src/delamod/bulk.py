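"""Bulk (through-polymer) diffusivity from the tilted-plate experiment.

A copper indicator plate slanted inside a cuvette is covered by a polymer
cast whose thickness grows linearly along the plate,

    h(y) = offset + y * tan(tilt),

so one specimen samples many membrane thicknesses at once.  Position ``y``
blackens when the corroding species has traversed the layer above it; per
the Einstein-Smoluchowski relation the traversal time of a membrane of
thickness ``h`` is ``t = h^2 / (2 D)``, so

    D_i = h(y_i)^2 / (2 (t_i - lag)),

with an optional lag for the initial uptake transient.  The average over
the interval where corrosion migrates linearly along the plate is the
reported bulk diffusivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "PlateGeometry",
    "layer_thickness",
    "einstein_smoluchowski",
    "estimate_bulk_D",
    "BulkDiffusionModel",
    "BulkDiffusionResults",
]

_SEC_PER_MIN = 60.0
_CM_PER_MM = 0.1


@dataclass(frozen=True)
class PlateGeometry:
    """Cuvette geometry: layer offset (mm), plate tilt (deg), plate length (mm).

    The study's cuvette had an offset of 1 mm and a 30 degree tilt.
    """

    offset: float = 1.0
    tilt_deg: float = 30.0
    plate_length: float = 40.0

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if not (0 <= self.tilt_deg <= 89):
            raise ValueError("tilt_deg must be in [0, 89]")
        if self.plate_length <= 0:
            raise ValueError("plate_length must be positive")


def layer_thickness(geom: PlateGeometry, y) -> np.ndarray:
    """Polymer thickness h(y) = offset + y tan(tilt), mm; y in [0, plate_length]."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > geom.plate_length):
        raise ValueError(
            f"y must lie in [0, {geom.plate_length}] mm")
    return geom.offset + y * np.tan(np.deg2rad(geom.tilt_deg))


def einstein_smoluchowski(h: float, t: float) -> float:
    """Diffusivity from a traversal: D = h^2 / (2 t).

    ``h`` in cm and ``t`` in seconds give D in cm²/s.
    """
    if t <= 0:
        raise ValueError("traversal time must be positive")
    if h < 0:
        raise ValueError("thickness must be >= 0")
    return h * h / (2.0 * t)


def _r2_linear(x: np.ndarray, y: np.ndarray) -> float:
    """R² of the ordinary least-squares line y ~ x (1.0 for zero y-variance)."""
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        return 1.0
    vx = float(np.sum((x - x.mean()) ** 2))
    if vx == 0:
        return 0.0
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / vx)
    sse = float(np.sum((y - y.mean() - slope * (x - x.mean())) ** 2))
    return 1.0 - sse / sstot


def _linear_interval(y: np.ndarray, t: np.ndarray, r2_min: float = 0.98,
                     min_pts: int = 3) -> tuple[int, int]:
    """Maximal contiguous run where onset vs position is linear.

    For each start index the window is expanded while the OLS fit keeps
    R² >= ``r2_min``; the longest such run wins (earliest on ties).
    Returns inclusive (i0, i1).
    """
    n = len(y)
    best = (0, min_pts - 1)
    best_len = 0
    for i0 in range(0, n - min_pts + 1):
        i1 = i0 + min_pts - 1
        last_ok = None
        while i1 < n and _r2_linear(y[i0:i1 + 1], t[i0:i1 + 1]) >= r2_min:
            last_ok = i1
            i1 += 1
        if last_ok is not None and (last_ok - i0 + 1) > best_len:
            best = (i0, last_ok)
            best_len = last_ok - i0 + 1
    if best_len < min_pts:
        raise ValueError(
            f"no contiguous run of >= {min_pts} positions with linear onset "
            f"(R² >= {r2_min})")
    return best


@dataclass
class BulkDiffusionResults:
    """Fitted bulk diffusivity and its provenance.

    ``D_bar`` is the arithmetic mean of the per-position diffusivities
    over the linear interval, cm²/s.
    """

    D_bar: float
    lag_min: float
    lag_mode: str
    interval: tuple[int, int]
    mask: np.ndarray
    table: pd.DataFrame
    r2_interval: float
    geom: PlateGeometry

    @property
    def D_per_position(self) -> np.ndarray:
        return self.table["D_cm2_s"].to_numpy()

    def summary(self) -> str:
        i0, i1 = self.interval
        lines = [
            "Bulk diffusion (tilted-plate) fit",
            "=" * 45,
            f"positions:            {len(self.table)}",
            f"linear interval:      rows {i0}..{i1} "
            f"(y = {self.table['y_mm'][i0]:.2f}..{self.table['y_mm'][i1]:.2f} mm, "
            f"R² = {self.r2_interval:.4f})",
            f"lag ({self.lag_mode}):{'':8s}{self.lag_min:.2f} min",
            f"D̄ (mean over interval): {self.D_bar:.4e} cm²/s",
            f"per-position D range:  {np.nanmin(self.D_per_position):.3e} "
            f".. {np.nanmax(self.D_per_position):.3e} cm²/s",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "D_bar_cm2_s": self.D_bar,
            "lag_min": self.lag_min,
            "lag_mode": self.lag_mode,
            "interval_rows": list(self.interval),
            "r2_interval": self.r2_interval,
            "geometry": {"offset_mm": self.geom.offset,
                         "tilt_deg": self.geom.tilt_deg,
                         "plate_length_mm": self.geom.plate_length},
            "per_position": self.table.to_dict(orient="list"),
        }


def estimate_bulk_D(onsets: pd.DataFrame, geom: PlateGeometry,
                    lag: Union[str, float] = "fit") -> BulkDiffusionResults:
    """Estimate the average bulk diffusivity from an onset table.

    Parameters
    ----------
    onsets : DataFrame with columns ``y_mm`` (position along the plate)
        and ``onset_min`` (first visible corrosion), ordered by position.
    geom : PlateGeometry mapping position to layer thickness.
    lag : "fit" (default) to take the lag from the intercept of the
        onset-vs-h² regression over the linear interval, or a fixed lag
        in minutes.

    Raises on degenerate geometry (no thickness variation), onsets not
    trending upward, or a lag that leaves non-positive diffusion times.
    """
    for col in ("y_mm", "onset_min"):
        if col not in onsets.columns:
            raise ValueError(f"onset table is missing column '{col}'")
    y = onsets["y_mm"].to_numpy(dtype=float)
    t_min = onsets["onset_min"].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 positions")
    if np.any(np.diff(y) <= 0):
        raise ValueError("positions y_mm must be strictly increasing")
    if np.ptp(t_min) == 0 or np.ptp(layer_thickness(geom, y)) == 0:
        raise ValueError(
            "degenerate regression: onsets/thickness do not vary along the "
            "plate (tilt = 0?)")
    if np.polyfit(y, t_min, 1)[0] <= 0:
        raise ValueError("onset times do not increase along the plate")

    h_mm = layer_thickness(geom, y)
    h_cm = h_mm * _CM_PER_MM
    i0, i1 = _linear_interval(y, t_min)
    mask = np.zeros(len(y), dtype=bool)
    mask[i0:i1 + 1] = True
    r2_int = _r2_linear(y[mask], t_min[mask])

    if isinstance(lag, str):
        if lag != "fit":
            raise ValueError("lag must be a number (minutes) or 'fit'")
        # t = lag + h^2 / (2 D): intercept of the onset vs h² line
        h2 = h_cm[mask] ** 2
        coef = np.polyfit(h2, t_min[mask] * _SEC_PER_MIN, 1)
        if coef[0] <= 0:
            raise ValueError(
                "onset vs thickness² regression has non-positive slope; "
                "cannot fit a lag")
        lag_s = float(coef[1])
        lag_mode = "fit"
    else:
        lag_s = float(lag) * _SEC_PER_MIN
        lag_mode = "fixed"

    t_s = t_min * _SEC_PER_MIN
    bad = np.flatnonzero(mask & (t_s <= lag_s))
    if bad.size:
        rows = ", ".join(
            f"row {i} (y = {y[i]:.2f} mm, onset = {t_min[i]:.1f} min)"
            for i in bad)
        raise ValueError(
            f"lag of {lag_s / 60:.2f} min leaves non-positive diffusion time "
            f"for: {rows}")

    D = np.full(len(y), np.nan)
    ok = t_s > lag_s
    D[ok] = h_cm[ok] ** 2 / (2.0 * (t_s[ok] - lag_s))
    table = pd.DataFrame({"y_mm": y, "h_mm": h_mm, "onset_min": t_min,
                          "D_cm2_s": D, "in_linear_interval": mask})
    D_bar = float(np.mean(D[mask]))
    return BulkDiffusionResults(D_bar, lag_s / _SEC_PER_MIN, lag_mode,
                                (i0, i1), mask, table, r2_int, geom)


class BulkDiffusionModel:
    """Membrane-traversal model of the tilted-plate experiment.

    Construct from an onset table and plate geometry, then :meth:`fit`.

    >>> model = BulkDiffusionModel(onsets, PlateGeometry(1.0, 30.0, 40.0))
    >>> res = model.fit()          # doctest: +SKIP
    >>> print(res.summary())       # doctest: +SKIP
    """

    def __init__(self, onsets: pd.DataFrame, geom: PlateGeometry) -> None:
        self.onsets = onsets.reset_index(drop=True)
        self.geom = geom

    @classmethod
    def from_csv(cls, path: str | Path, geom: PlateGeometry) -> "BulkDiffusionModel":
        return cls(pd.read_csv(path), geom)

    def fit(self, lag: Union[str, float] = "fit") -> BulkDiffusionResults:
        return estimate_bulk_D(self.onsets, self.geom, lag=lag)
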