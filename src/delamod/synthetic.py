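"""Forward simulation of the two bench experiments.

Two set-ups are emulated with known ground truth so that every downstream
stage (imaging, kinetics fitting, diffusivity estimation) can be scored:

1. *Droplet interface diffusion*: a polymer droplet sits on a thin copper
   film immersed in a polysulfide bath.  The exposed copper blackens at
   once; the film under the droplet stays bright and is eaten inward by
   interface diffusion.  Frames show a bright protected disk of radius
   ``r(t) = r0 - s(t)`` inside a dark corroded annulus, with ``s`` following
   a composite three-phase law: ``alpha*sqrt(t)`` (undisturbed interface
   diffusion), then a continuous linear segment (delamination-assisted,
   steady-state membrane transport), then an instantaneous jump (the
   threshold-breakdown artifact when bulk diffusion erases the optical
   contrast).

2. *Tilted-plate cuvette*: a copper platelet slanted inside a cuvette under
   a polymer cast of linearly varying thickness ``h(y)``.  Each position
   blackens once the through-thickness (bulk) diffusion reaches it, at
   ``onset(y) = lag + h(y)^2 / (2 D_bulk)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .bulk import PlateGeometry, layer_thickness
from .imaging import rec601_gray
from .trace import FrontTrace

__all__ = [
    "SceneConfig",
    "CompositeFrontLaw",
    "simulate_front_trace",
    "render_frames",
    "write_frames",
    "simulate_cuvette",
]

#: seconds per minute — minutes are the canonical file unit
MIN = 60.0


@dataclass
class SceneConfig:
    """Rendering parameters for the droplet time-lapse.

    Defaults reproduce the study conditions: a 3 cm diameter droplet
    (radius 15 mm) at 0.05 mm/px (300 px), one frame every 5 minutes.
    Colors are chosen so that a grayscale margin of 90 separates the
    corroded film (dark) from the protected film and background (bright)
    under Rec. 601 luminance; the real specimens provide the same contrast.
    """

    droplet_radius_px: int = 300
    image_size_px: Tuple[int, int] = (672, 672)
    mm_per_px: float = 0.05
    frame_interval_min: float = 5.0
    n_frames: int = 100
    protected_color: Tuple[int, int, int] = (200, 110, 50)
    corroded_color: Tuple[int, int, int] = (35, 25, 20)
    background_color: Tuple[int, int, int] = (120, 120, 120)
    noise_sd: float = 0.0
    illumination_gradient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.droplet_radius_px < 10:
            raise ValueError("droplet_radius_px must be >= 10")
        h, w = self.image_size_px
        if 2 * self.droplet_radius_px >= min(h, w):
            raise ValueError("droplet does not fit inside the image")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.noise_sd < 0 or self.illumination_gradient < 0:
            raise ValueError("noise_sd and illumination_gradient must be >= 0")
        for name in ("protected_color", "corroded_color", "background_color"):
            c = getattr(self, name)
            if len(c) != 3 or any((v < 0 or v > 255) for v in c):
                raise ValueError(f"{name} must be an RGB triple in 0..255")

    def separates(self, margin: int = 90) -> bool:
        """True if protected/background are brighter and corroded darker
        than ``margin`` under the Rec. 601 grayscale used for tracking."""
        bright = min(rec601_gray(np.array(self.protected_color, float)),
                     rec601_gray(np.array(self.background_color, float)))
        dark = rec601_gray(np.array(self.corroded_color, float))
        return bool(dark <= margin < bright)


@dataclass
class CompositeFrontLaw:
    """Piecewise three-phase front law s(t).

    Phase I (0 <= t <= t1): ``s = alpha * sqrt(t)`` — Stefan-type interface
    diffusion.  Phase II (t1 < t <= t2): continuous linear segment with
    slope ``v2`` — delamination front trailing the diffusion front at a
    constant lag turns the not-yet delaminated strip into a fixed-width
    membrane, giving a constant front velocity.  Phase III (t > t2): the
    recorded length jumps by ``jump`` instantly — an artifact of the global
    contrast collapse, not physics.

    Units are carried by the caller (typically px and minutes).
    """

    alpha: float = 1.0
    t1: float = np.inf
    v2: float = 0.0
    t2: float = np.inf
    jump: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.alpha, self.v2, self.jump)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("alpha, v2 and jump must be finite")
        if any(v < 0 for v in vals):
            raise ValueError("alpha, v2 and jump must be >= 0")
        if np.isfinite(self.t2) and not (self.t1 < self.t2):
            raise ValueError(f"need t1 < t2, got t1={self.t1}, t2={self.t2}")
        if self.t1 < 0:
            raise ValueError("t1 must be >= 0")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        s = self.alpha * np.sqrt(t)
        s1 = self.alpha * np.sqrt(self.t1) if np.isfinite(self.t1) else np.inf
        in2 = t > self.t1
        if np.isfinite(self.t1):
            s = np.where(in2, s1 + self.v2 * (t - self.t1), s)
        if np.isfinite(self.t2):
            s2 = s1 + self.v2 * (self.t2 - self.t1)
            s = np.where(t > self.t2, s2 + self.jump, s)
        return s


def simulate_front_trace(law: CompositeFrontLaw, duration: float,
                         step: float) -> FrontTrace:
    """Sample the composite law on a regular grid ``t = 0, step, ..., <= duration``.

    Parameters are in the caller's units (minutes/px by convention).
    """
    if step <= 0 or duration <= 0:
        raise ValueError("duration and step must be positive")
    n = int(np.floor(duration / step)) + 1
    t = np.arange(n) * step
    s = law(t)
    tr = FrontTrace(t, s)
    tr.meta["law"] = {
        "alpha": law.alpha, "t1": law.t1, "v2": law.v2,
        "t2": law.t2, "jump": law.jump,
    }
    return tr


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _dist2_grid(shape: Tuple[int, int]) -> np.ndarray:
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy = np.arange(h)[:, None] - cy
    xx = np.arange(w)[None, :] - cx
    return yy * yy + xx * xx


def render_frames(trace: FrontTrace, scene: SceneConfig,
                  clip: bool = False) -> np.ndarray:
    """Render the droplet time-lapse for a front trace.

    Returns a ``(n_frames, H, W, 3)`` uint8 array.  Each frame shows the
    background, a dark corroded annulus and a bright protected disk of
    radius ``r0 - s(t)`` (in px).  Additive i.i.d. Gaussian pixel noise
    (``noise_sd``, 0–255 scale) and an optional horizontal illumination
    ramp are applied, then values are clipped to 0–255.  Deterministic
    for a given ``scene.seed``.

    ``s > r0`` is rejected (the disk cannot shrink past full corrosion)
    unless ``clip=True``, in which case ``s`` is clamped to ``r0`` — the
    whole-disk darkening used to emulate phase III.
    """
    r0 = float(scene.droplet_radius_px)
    s = np.minimum(trace.s, r0) if clip else trace.s
    if np.any(s > r0 + 1e-9):
        raise ValueError(
            f"front length exceeds droplet radius ({np.max(s):.2f} px > {r0} px); "
            "trim the trace or pass clip=True")
    h, w = scene.image_size_px
    d2 = _dist2_grid((h, w))
    inside = d2 <= r0 * r0
    rng = np.random.default_rng(scene.seed)
    ramp = scene.illumination_gradient * (np.arange(w) / max(w - 1, 1) - 0.5)

    prot = np.array(scene.protected_color, float)
    corr = np.array(scene.corroded_color, float)
    back = np.array(scene.background_color, float)

    out = np.empty((len(trace), h, w, 3), dtype=np.uint8)
    for k in range(len(trace)):
        rp = max(r0 - float(np.maximum(s[k], 0.0)), 0.0)
        frame = np.where(inside[..., None],
                         np.where((d2 <= rp * rp)[..., None], prot, corr),
                         back)
        frame = frame + ramp[None, :, None]
        if scene.noise_sd > 0:
            frame = frame + rng.normal(0.0, scene.noise_sd, size=frame.shape)
        out[k] = np.clip(np.round(frame), 0, 255).astype(np.uint8)
    return out


def write_frames(frames: np.ndarray, times_min: Iterable[float],
                 outdir: str | Path, fmt: str = "png") -> list[Path]:
    """Write frames as PNG/TIFF files named with zero-padded index and
    timestamp in minutes (``frame_0003_t0015.0min.png``)."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, t in enumerate(times_min):
        p = outdir / f"frame_{k:04d}_t{t:07.1f}min.{fmt}"
        iio.imwrite(p, frames[k])
        paths.append(p)
    return paths


# --------------------------------------------------------------------------
# cuvette (bulk diffusion) experiment
# --------------------------------------------------------------------------

def simulate_cuvette(D_bulk: float, geom: PlateGeometry, n_positions: int,
                     lag_min: float = 0.0, rel_noise: float = 0.0,
                     seed: Optional[int] = None) -> pd.DataFrame:
    """Simulate corrosion-onset times along the tilted indicator plate.

    The polymer layer of thickness ``h(y)`` (mm) above plate position
    ``y`` acts as a membrane; the onset of visible corrosion follows the
    Einstein–Smoluchowski traversal time

        ``onset(y) = lag + h(y)^2 / (2 * D_bulk)``

    with ``D_bulk`` in cm²/s.  Output columns: ``y_mm``, ``onset_min``.
    ``rel_noise`` applies multiplicative lognormal-free Gaussian noise of
    that relative s.d. to the diffusive part of each onset.
    """
    if D_bulk <= 0:
        raise ValueError("D_bulk must be positive")
    if n_positions < 2:
        raise ValueError("need at least 2 positions")
    y = np.linspace(0.0, geom.plate_length, n_positions)
    h_cm = layer_thickness(geom, y) / 10.0
    diff_min = h_cm**2 / (2.0 * D_bulk) / MIN
    if rel_noise > 0:
        rng = np.random.default_rng(seed)
        diff_min = diff_min * (1.0 + rel_noise * rng.standard_normal(n_positions))
    onset = lag_min + diff_min
    return pd.DataFrame({"y_mm": y, "onset_min": onset})
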