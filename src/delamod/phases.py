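"""Three-phase kinetics of the corrosion front, and delamination.

Front traces exhibit three segments: phase I follows ``s = alpha sqrt(t)``
(undisturbed Stefan-type interface diffusion); phase II is near-linear
(the delamination front trails the diffusion front at a constant lag
``delta``, so the not-yet delaminated strip acts as a fixed-width membrane
feeding the front at constant rate ``v2 = D C0 / (S delta)``); phase III
is a sharp jump — an artifact of the optical threshold collapsing once
bulk diffusion darkens the whole protected disk, and is therefore
detected and excluded rather than modelled.

The segmentation is an exhaustive changepoint search over observed
timestamps, with continuity enforced at the phase I/II changepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .stefan import StefanParams, goodman_alpha
from .trace import FrontTrace

__all__ = [
    "PhaseSegmentation",
    "DelaminationState",
    "MergePrediction",
    "segment_phases",
    "FrontKineticsModel",
    "delamination_front",
    "steady_state_membrane_rate",
    "predict_merge",
]


@dataclass
class PhaseSegmentation:
    """Fitted piecewise model of a front trace (also the fit results).

    ``t1``/``t2`` are the phase I→II and II→III changepoints in minutes
    (None when the corresponding phase is absent), ``alpha_hat`` the
    phase-I coefficient, ``v2_hat`` the phase-II slope, ``sse`` the total
    squared error of the fitted piecewise model over the modelled (phase
    I+II) points.  The model is continuous at ``t1``; the phase-III jump
    is discontinuous by nature.
    """

    t1: Optional[float]
    t2: Optional[float]
    alpha_hat: float
    v2_hat: Optional[float]
    sse: float
    n_per_phase: tuple[int, int, int]
    alpha_se: float = np.nan
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def predict(self, t) -> np.ndarray:
        """Evaluate the fitted phase I/II model (phase III not modelled)."""
        t = np.asarray(t, dtype=float)
        s = self.alpha_hat * np.sqrt(t)
        if self.t1 is not None and self.v2_hat is not None:
            s1 = self.alpha_hat * np.sqrt(self.t1)
            s = np.where(t > self.t1, s1 + self.v2_hat * (t - self.t1), s)
        return s

    def summary(self) -> str:
        n1, n2, n3 = self.n_per_phase
        lines = [
            "Front-kinetics segmentation",
            "=" * 45,
            f"points per phase:  I: {n1}   II: {n2}   III: {n3}",
            f"alpha (phase I):   {self.alpha_hat:.6g} ± {self.alpha_se:.2g} "
            "[len/sqrt(min)]",
        ]
        if self.t1 is not None:
            lines.append(f"t1 (I → II):       {self.t1:g} min")
            lines.append(f"v2 (phase II):     {self.v2_hat:.6g} [len/min]")
        else:
            lines.append("single-phase fit (no I → II changepoint)")
        if self.t2 is not None:
            lines.append(f"t2 (II → III):     {self.t2:g} min (jump artifact)")
        lines.append(f"SSE (phases I+II): {self.sse:.6g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "t1_min": self.t1, "t2_min": self.t2,
            "alpha_hat": self.alpha_hat, "alpha_se": self.alpha_se,
            "v2_hat": self.v2_hat, "sse": self.sse,
            "n_per_phase": list(self.n_per_phase),
        }


def _fit_single(rt: np.ndarray, s: np.ndarray) -> tuple[float, float, float]:
    """No-intercept sqrt fit; returns (alpha, sse, alpha_se)."""
    denom = float(np.dot(rt, rt))
    alpha = float(np.dot(s, rt) / denom) if denom > 0 else 0.0
    resid = s - alpha * rt
    sse = float(np.dot(resid, resid))
    dof = max(len(s) - 1, 1)
    se = float(np.sqrt(sse / dof / denom)) if denom > 0 else np.nan
    return alpha, sse, se


def _fit_two_phase(t: np.ndarray, s: np.ndarray, rt: np.ndarray,
                   min_seg: int) -> Optional[dict]:
    """Exhaustive changepoint search for the continuous sqrt+linear model.

    For each candidate t1 = t[k] the model is linear in (alpha, v2):
    design columns are sqrt(min(t, t1)) and max(t - t1, 0); solved by
    least squares.  Returns the best candidate or None if no admissible
    split exists.
    """
    n = len(t)
    best = None
    for k in range(min_seg - 1, n - min_seg):
        x1 = np.minimum(rt, rt[k])
        x2 = np.maximum(t - t[k], 0.0)
        X = np.column_stack([x1, x2])
        coef, _, _, _ = np.linalg.lstsq(X, s, rcond=None)
        resid = s - X @ coef
        sse = float(np.dot(resid, resid))
        if best is None or sse < best["sse"]:
            # standard error of alpha from the linear-model covariance
            dof = max(n - 2, 1)
            try:
                cov = np.linalg.inv(X.T @ X) * sse / dof
                se = float(np.sqrt(cov[0, 0]))
            except np.linalg.LinAlgError:
                se = np.nan
            best = {"k": k, "alpha": float(coef[0]), "v2": float(coef[1]),
                    "sse": sse, "alpha_se": se}
    return best


def _detect_jump(resid: np.ndarray, min_seg: int, window: int = 10
                 ) -> Optional[int]:
    """Index of the first point after a residual jump > 5 local (MAD) SDs.

    Returns the start index of phase III, or None.  A small absolute floor
    keeps numerically flat noise-free traces from false-triggering.
    """
    dr = np.diff(resid)
    if dr.size < 4:
        return None
    j = int(np.argmax(dr))
    lo, hi = max(j - window, 0), min(j + window + 1, dr.size)
    local = np.delete(dr[lo:hi], j - lo)
    sd = 1.4826 * float(np.median(np.abs(local - np.median(local))))
    sd = max(sd, 1e-9 * max(float(np.ptp(resid)), 1.0))
    if dr[j] > 5.0 * sd and (j + 1) >= 2 * min_seg:
        return j + 1
    return None


def segment_phases(trace: FrontTrace, min_seg: int = 5) -> PhaseSegmentation:
    """Segment a front trace into the three characteristic phases.

    Phase III (the threshold-breakdown jump) is detected first on residual
    first-differences (> 5 local robust SDs) and excluded; the remaining
    points are fitted by an exhaustive grid search over candidate ``t1``
    among observed timestamps, with the continuous sqrt+linear model.
    A single-phase (pure sqrt) result is returned when the two-phase model
    improves the SSE by less than 5%.  Each retained phase keeps at least
    ``min_seg`` points.
    """
    if len(trace) < 3 * min_seg:
        raise ValueError(f"need at least {3 * min_seg} points, got {len(trace)}")
    t, s = trace.t, trace.s
    if np.any(np.diff(t) <= 0):  # FrontTrace guarantees this, belt and braces
        raise ValueError("timestamps must be strictly increasing")
    rt = np.sqrt(t)
    n = len(t)

    idx3 = n
    for _ in range(4):
        tt, ss, rr = t[:idx3], s[:idx3], rt[:idx3]
        alpha1, sse1, se1 = _fit_single(rr, ss)
        two = _fit_two_phase(tt, ss, rr, min_seg) if idx3 >= 2 * min_seg else None
        pred = (alpha1 * rr if two is None or two["sse"] >= sse1
                else np.minimum(rr, rr[two["k"]]) * two["alpha"]
                + np.maximum(tt - tt[two["k"]], 0.0) * two["v2"])
        start3 = _detect_jump(ss - pred, min_seg)
        if start3 is not None and start3 < idx3 and start3 >= 2 * min_seg:
            idx3 = start3
        else:
            break

    tt, ss, rr = t[:idx3], s[:idx3], rt[:idx3]
    alpha1, sse1, se1 = _fit_single(rr, ss)
    two = _fit_two_phase(tt, ss, rr, min_seg) if idx3 >= 2 * min_seg else None

    scale = max(float(np.ptp(ss)), 1.0)
    tiny = (1e-8 * scale) ** 2 * idx3
    use_two = (two is not None and two["sse"] < sse1
               and sse1 > tiny
               and (sse1 - two["sse"]) / sse1 >= 0.05)

    labels = np.full(n, 3, dtype=int)
    if use_two:
        k = two["k"]
        labels[: k + 1] = 1
        labels[k + 1: idx3] = 2
        seg = PhaseSegmentation(
            t1=float(tt[k]),
            t2=float(tt[-1]) if idx3 < n else None,
            alpha_hat=two["alpha"], v2_hat=two["v2"], sse=two["sse"],
            n_per_phase=(k + 1, idx3 - k - 1, n - idx3),
            alpha_se=two["alpha_se"], labels=labels)
    else:
        labels[:idx3] = 1
        seg = PhaseSegmentation(
            t1=None, t2=float(tt[-1]) if idx3 < n else None,
            alpha_hat=alpha1, v2_hat=None, sse=sse1,
            n_per_phase=(idx3, 0, n - idx3),
            alpha_se=se1, labels=labels)
    return seg


class FrontKineticsModel:
    """Piecewise three-phase kinetics model of a front trace.

    statsmodels-style: build from data, ``fit()`` returns the
    :class:`PhaseSegmentation` results object.

    >>> res = FrontKineticsModel(trace).fit()      # doctest: +SKIP
    >>> print(res.summary())                       # doctest: +SKIP
    """

    def __init__(self, trace: FrontTrace) -> None:
        self.trace = trace

    @classmethod
    def from_csv(cls, path) -> "FrontKineticsModel":
        return cls(FrontTrace.from_csv(path))

    def fit(self, min_seg: int = 5) -> PhaseSegmentation:
        return segment_phases(self.trace, min_seg=min_seg)

    def plot(self, seg: Optional[PhaseSegmentation] = None, path=None):
        """Diagnostic plot: data, fitted piecewise model, phase shading."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if seg is None:
            seg = self.fit()
        fig, ax = plt.subplots(figsize=(6, 4))
        colors = {1: "C0", 2: "C1", 3: "C3"}
        for ph in (1, 2, 3):
            sel = seg.labels == ph
            if sel.any():
                ax.plot(self.trace.t[sel], self.trace.s[sel], ".",
                        color=colors[ph], label=f"phase {ph}")
        tmax = self.trace.t[seg.labels < 3].max() if (seg.labels < 3).any() \
            else self.trace.t.max()
        tg = np.linspace(0, tmax, 300)
        ax.plot(tg, seg.predict(tg), "k-", lw=1, label="fit")
        ax.set_xlabel("t [min]")
        ax.set_ylabel("front length s")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


# --------------------------------------------------------------------------
# delamination
# --------------------------------------------------------------------------

@dataclass
class DelaminationState:
    """Delamination front trailing the diffusion front at constant lag."""

    delta: float
    d: np.ndarray


def delamination_front(X_series, delta: float) -> DelaminationState:
    """Delamination-front positions ``d(t) = max(0, X(t) - delta)``.

    The adhesion front lags the visible diffusion front by the constant
    distance ``delta`` (same units as X).
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    X = np.asarray(X_series, dtype=float)
    return DelaminationState(float(delta), np.maximum(X - delta, 0.0))


def steady_state_membrane_rate(p: StefanParams, delta: float) -> float:
    """Phase-II front velocity from the fixed-width membrane picture.

    Once delamination floods the channel behind ``d(t) = X - delta`` with
    bath concentration C0, the un-delaminated strip of width ``delta``
    carries a steady-state flux ``D C0 / delta``; the Stefan condition
    then gives a constant front velocity

        v2 = D * C0 / (S * delta)        [cm/s for cm inputs].
    """
    if delta <= 0:
        raise ValueError("delta must be positive (delta = 0 gives an "
                         "unbounded membrane rate)")
    return p.D * p.C0 / (p.S * delta)


@dataclass
class MergePrediction:
    """Competition between interface and bulk routes to global delamination."""

    t_interface_s: float
    t_bulk_s: float
    mode: str  # "interface", "bulk" or "none"

    @property
    def t_merge_s(self) -> float:
        return min(self.t_interface_s, self.t_bulk_s)


def predict_merge(p: StefanParams, D_bulk: float, cover_thickness: float,
                  r0: float, delta: float) -> MergePrediction:
    """Which failure route wins: interface front traversal or bulk breakthrough.

    ``t_interface`` is the time for the composite front (phase I
    ``alpha sqrt(t)`` until the delamination lag ``delta`` is established,
    then the linear membrane rate) to traverse the droplet radius ``r0``.
    ``t_bulk`` is the lag-free membrane time ``cover_thickness² / (2 D_bulk)``.
    Lengths in cm, times in s.  Non-finite times on both routes yield mode
    "none" (no failure within horizon).
    """
    if cover_thickness <= 0 or r0 <= 0 or delta <= 0:
        raise ValueError("cover_thickness, r0 and delta must be positive")
    if D_bulk < 0:
        raise ValueError("D_bulk must be >= 0")
    t_bulk = cover_thickness**2 / (2.0 * D_bulk) if D_bulk > 0 else np.inf

    alpha = goodman_alpha(p).alpha
    if alpha == 0:
        t_iface = np.inf
    elif not np.isfinite(r0):
        t_iface = np.inf
    elif r0 <= delta:
        t_iface = (r0 / alpha) ** 2
    else:
        t1 = (delta / alpha) ** 2
        v2 = steady_state_membrane_rate(p, delta)
        t_iface = t1 + (r0 - delta) / v2

    if not np.isfinite(t_iface) and not np.isfinite(t_bulk):
        mode = "none"
    elif t_iface <= t_bulk:
        mode = "interface"
    else:
        mode = "bulk"
    return MergePrediction(float(t_iface), float(t_bulk), mode)
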