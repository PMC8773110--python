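"""Front-position time series: the shared container of the pipeline.

A :class:`FrontTrace` records the corrosion-front penetration length ``s``
under the polymer edge as a function of time.  Times are minutes; lengths
are pixels unless a ``mm_per_px`` calibration is attached, in which case
``s_mm``/``r0_mm`` give physical units.  ``s`` is the inward distance
travelled by the visible (indicator-concentration) front from the initial
protected radius ``r0``: ``s(t) = r(t0) - r(t)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["FrontTrace"]


@dataclass
class FrontTrace:
    """Time series of corrosion-front length with optional pixel calibration.

    Parameters
    ----------
    t : array-like
        Sample times in minutes, strictly increasing.
    s : array-like
        Front length at each time (px, or mm if the producer worked in mm).
    r0 : float, optional
        Initial protected-disk radius, same length unit as ``s``.
    mm_per_px : float, optional
        Pixel pitch. Absent means ``s`` is in pixel units with no
        physical calibration.
    """

    t: np.ndarray
    s: np.ndarray
    r0: Optional[float] = None
    mm_per_px: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.t.ndim != 1 or self.s.ndim != 1:
            raise ValueError("t and s must be one-dimensional")
        if self.t.shape != self.s.shape:
            raise ValueError(
                f"t and s must have equal length, got {self.t.size} and {self.s.size}"
            )
        if self.t.size and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.s)):
            raise ValueError("front lengths must be finite")
        if self.mm_per_px is not None and self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")

    def __len__(self) -> int:
        return self.t.size

    @property
    def s_mm(self) -> np.ndarray:
        if self.mm_per_px is None:
            raise ValueError("trace carries no mm_per_px calibration")
        return self.s * self.mm_per_px

    def window(self, t_min: float = -np.inf, t_max: float = np.inf) -> "FrontTrace":
        """Restrict the trace to samples with ``t_min <= t <= t_max``."""
        keep = (self.t >= t_min) & (self.t <= t_max)
        return FrontTrace(self.t[keep], self.s[keep], r0=self.r0,
                          mm_per_px=self.mm_per_px, meta=dict(self.meta))

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_min": self.t, "s_px": self.s})
        if self.r0 is not None:
            df["r_px"] = self.r0 - self.s
        return df

    def to_csv(self, path: str | Path, provenance: Optional[dict] = None) -> None:
        """Write the trace as CSV; provenance (units, calibration) as a
        JSON sidecar next to it."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        side = {
            "units": {"t": "min", "s": "px"},
            "r0_px": self.r0,
            "mm_per_px": self.mm_per_px,
        }
        side.update(self.meta)
        if provenance:
            side.update(provenance)
        path.with_suffix(".json").write_text(json.dumps(side, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrontTrace":
        path = Path(path)
        df = pd.read_csv(path)
        for col in ("t_min", "s_px"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column '{col}'")
        r0 = None
        mm_per_px = None
        meta: dict = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            r0 = meta.get("r0_px")
            mm_per_px = meta.get("mm_per_px")
        elif "r_px" in df.columns:
            r0 = float(df["r_px"].iloc[0] + df["s_px"].iloc[0])
        return cls(df["t_min"].to_numpy(), df["s_px"].to_numpy(),
                   r0=r0, mm_per_px=mm_per_px, meta=meta)
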