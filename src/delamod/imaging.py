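"""Front tracking from time-lapse images.

The optical method: corroded copper is near-black, protected copper under
the droplet stays bright.  Each RGB frame is converted to grayscale and
thresholded at a fixed contrast margin (default 90 on the 0-255 scale,
"up to and equal" counted as corroded).  Black pixels inside a region of
interest are counted and subtracted from the ROI pixel total; the
remainder is taken as the circular protected area, from which the radius
``r = sqrt(A / pi)`` follows.  The front length is ``s(t) = r(t0) - r(t)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from .trace import FrontTrace

__all__ = [
    "BinarizationRule",
    "CircleROI",
    "rec601_gray",
    "binarize",
    "estimate_radius",
    "extract_front_trace",
    "load_series",
]

#: Rec. 601 luminance weights for R, G, B
_REC601 = np.array([0.299, 0.587, 0.114])


def rec601_gray(rgb: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance, rounded to the nearest integer level.

    Accepts an ``(..., 3)`` array (or a bare RGB triple) of 0-255 values.
    """
    rgb = np.asarray(rgb, dtype=float)
    return np.round(rgb @ _REC601)


_GRAYSCALE = {"rec601": rec601_gray, "mean": lambda rgb: np.round(
    np.asarray(rgb, dtype=float).mean(axis=-1))}


@dataclass(frozen=True)
class BinarizationRule:
    """Threshold rule: grayscale levels <= ``margin`` count as corroded."""

    margin: int = 90
    grayscale_formula: str = "rec601"

    def __post_init__(self) -> None:
        if not (0 <= self.margin <= 255):
            raise ValueError("margin must be in 0..255")
        if self.grayscale_formula not in _GRAYSCALE:
            raise ValueError(
                f"unknown grayscale formula {self.grayscale_formula!r}; "
                f"choose from {sorted(_GRAYSCALE)}")


@dataclass(frozen=True)
class CircleROI:
    """Circular region of interest (pixel coordinates, center + radius)."""

    cy: float
    cx: float
    r: float

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        yy = np.arange(shape[0])[:, None] - self.cy
        xx = np.arange(shape[1])[None, :] - self.cx
        return (yy * yy + xx * xx) <= self.r * self.r


def binarize(frame: np.ndarray, rule: BinarizationRule = BinarizationRule()) -> np.ndarray:
    """Binarize an 8-bit RGB frame: 1 where corroded (grayscale <= margin).

    The boundary level itself is counted as corroded ("up to and equal").
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB frame, got shape {frame.shape}")
    if frame.dtype != np.uint8:
        raise ValueError(
            f"expected 8-bit (uint8) input, got dtype {frame.dtype}; "
            "rescale/convert the image before thresholding")
    gray = _GRAYSCALE[rule.grayscale_formula](frame)
    return (gray <= rule.margin).astype(np.uint8)


def estimate_radius(mask: np.ndarray, roi: Optional[CircleROI] = None) -> float:
    """Protected-disk radius from a corrosion mask by count-and-subtract.

    ``A = (#pixels in ROI) - (#corroded pixels in ROI)``; ``r = sqrt(A/pi)``.
    A fully corroded ROI gives radius 0.  ROI defaults to the full frame.
    """
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("mask is empty")
    if roi is not None:
        sel = roi.mask(mask.shape[:2])
        total = int(sel.sum())
        black = int(np.count_nonzero(mask[sel]))
    else:
        total = mask.size
        black = int(np.count_nonzero(mask))
    area = total - black
    return float(np.sqrt(area / np.pi))


def extract_front_trace(frames: Sequence[np.ndarray], times_min: Sequence[float],
                        rule: BinarizationRule = BinarizationRule(),
                        roi: Optional[CircleROI] = None,
                        mm_per_px: Optional[float] = None,
                        remove_small: int = 0) -> FrontTrace:
    """Track the front through a time-lapse series.

    Per frame: binarize, count, derive the protected radius; then
    ``s(t) = r(t0) - r(t)``.  Values are reported raw (no smoothing); they
    may go slightly negative under noise.  ``remove_small`` optionally
    drops connected corroded specks up to that pixel area before counting
    (off by default — the reference procedure is pure thresholding).
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to track a front")
    if len(frames) != len(times_min):
        raise ValueError("frames and timestamps differ in length")
    shape = np.asarray(frames[0]).shape
    radii = np.empty(len(frames))
    for k, frame in enumerate(frames):
        frame = np.asarray(frame)
        if frame.shape != shape:
            raise ValueError(
                f"frame {k} has shape {frame.shape}, expected {shape}")
        mask = binarize(frame, rule)
        if remove_small > 0:
            from scipy import ndimage

            lab, n = ndimage.label(mask)
            if n:
                sizes = np.bincount(lab.ravel())
                small = np.flatnonzero(sizes <= remove_small)
                mask[np.isin(lab, small[small > 0])] = 0
        radii[k] = estimate_radius(mask, roi)
    s = radii[0] - radii
    tr = FrontTrace(np.asarray(times_min, dtype=float), s,
                    r0=float(radii[0]), mm_per_px=mm_per_px)
    tr.meta["binarization"] = {"margin": rule.margin,
                               "grayscale": rule.grayscale_formula}
    if roi is not None:
        tr.meta["roi"] = {"cy": roi.cy, "cx": roi.cx, "r": roi.r}
    return tr


_TS_RE = re.compile(r"t(\d+(?:\.\d+)?)min")


def load_series(source: str | Path) -> Tuple[list[np.ndarray], list[float]]:
    """Load an image series: a glob pattern / directory of PNG or TIFF
    frames with ``t<minutes>min`` in the filename, or one multi-page TIFF
    (pages assumed equally spaced; timestamps then 0, 1, 2, ... pages)."""
    import imageio.v3 as iio

    source = Path(source)
    if source.is_file() and source.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        frames = [page for page in tifffile.imread(source)]
        return frames, [float(k) for k in range(len(frames))]
    if source.is_dir():
        paths = sorted(source.glob("*.png")) + sorted(source.glob("*.tif*"))
    else:
        paths = sorted(source.parent.glob(source.name))
    if not paths:
        raise FileNotFoundError(f"no frames matched {source}")
    frames, times = [], []
    for p in paths:
        m = _TS_RE.search(p.name)
        if m is None:
            raise ValueError(f"{p.name}: no 't<minutes>min' timestamp in filename")
        frames.append(np.asarray(iio.imread(p)))
        times.append(float(m.group(1)))
    order = np.argsort(times)
    return [frames[i] for i in order], [times[i] for i in order]
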