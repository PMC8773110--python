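"""Stefan-type moving-boundary model of interface diffusion.

Corroding ions diffuse along the metal-polymer interface from the bath
(boundary concentration ``C0``) into a region initially free of solute.
At the moving front ``X(t)`` every arriving ion is immobilized by reaction
with the metal, consuming ``S`` per unit front advance.  The one
dimensional model is Fick's second law

    dC/dt = D d2C/dx2        on 0 < x < X(t)

with boundary conditions

    C = 0                    for t = 0, x > 0
    C(0, t) = C0             maintained bath at the droplet edge; an
                             optional surface layer of capacity ``l``
                             (l dC/dt = D dC/dx at x = 0) stores l*C0 at
                             startup and leaves the front law unchanged
    S dX/dt = -D dC/dx       at x = X(t)  (Stefan condition)

Two routes to the front position are provided and cross-checked:

* :func:`goodman_alpha` — the heat-balance-integral (Goodman) closed form:
  a quadratic profile ``C = a (x-X) + b (x-X)^2`` is required to satisfy
  the boundary conditions and the spatially integrated diffusion equation,
  which collapses the PDE to a single scalar equation for the front
  coefficient ``alpha`` in ``X = alpha * sqrt(t)``.
* :func:`fd_solve` — an explicit finite-volume scheme with a front-cell
  accumulator, independently auditable through its discrete mass balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .trace import FrontTrace

__all__ = [
    "StefanParams",
    "MovingBoundarySolution",
    "ConcentrationProfile",
    "FDSolution",
    "AlphaFit",
    "goodman_alpha",
    "front_position",
    "goodman_profile",
    "fd_solve",
    "fit_alpha",
]


@dataclass(frozen=True)
class StefanParams:
    """Physical parameters of the interface-diffusion model.

    Parameters
    ----------
    D : float
        Interface diffusivity, cm²/s.
    C0 : float
        Bath boundary concentration (amount/volume), >= 0.
    S : float
        Immobilized amount per unit front advance per unit cross-section
        (same units as C0), > 0.
    l : float
        Surface-layer capacity length, cm (default 0: no reservoir;
        nonzero values only add a startup storage term, see module docs).
    Ci : float, optional
        Indicator concentration at which corrosion becomes visible.
    Climit : float, optional
        Concentration at which adhesion fails (delamination trigger);
        ordering 0 < Ci <= Climit <= C0 is enforced when given.
    """

    D: float
    C0: float
    S: float
    l: float = 0.0
    Ci: Optional[float] = None
    Climit: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("D", "C0", "S", "l"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.C0 < 0:
            raise ValueError("C0 must be >= 0")
        if self.S <= 0:
            raise ValueError("S must be positive")
        if self.l < 0:
            raise ValueError("l must be >= 0")
        if self.Ci is not None or self.Climit is not None:
            ci = self.Ci if self.Ci is not None else self.Climit
            cl = self.Climit if self.Climit is not None else self.Ci
            if not (0 < ci <= cl <= self.C0):
                raise ValueError(
                    f"need 0 < Ci <= Climit <= C0, got Ci={ci}, "
                    f"Climit={cl}, C0={self.C0}")


@dataclass(frozen=True)
class MovingBoundarySolution:
    """Heat-balance-integral solution: front law and profile coefficients.

    ``X(t) = alpha * sqrt(t)``.  The quadratic profile is
    ``C(x, t) = a(t) (x - X) + b(t) (x - X)^2`` with time-dependent
    coefficients ``a(t) = a_scaled / X(t)`` and ``b(t) = b_scaled / X(t)^2``;
    the scaled coefficients (units of concentration) are constants of the
    similarity solution.
    """

    alpha: float
    a_scaled: float
    b_scaled: float

    def profile_coeffs(self, t: float) -> tuple[float, float]:
        """(a, b) at time t > 0, in concentration/cm and concentration/cm²."""
        if t <= 0:
            raise ValueError("profile coefficients require t > 0")
        X = self.alpha * np.sqrt(t)
        if X == 0:
            return 0.0, 0.0
        return self.a_scaled / X, self.b_scaled / X**2


@dataclass
class ConcentrationProfile:
    """Concentration snapshot C(x) at time t (cm, concentration units)."""

    x: np.ndarray
    C: np.ndarray
    t: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.x.shape != self.C.shape:
            raise ValueError("x and C must have equal length")
        if self.x.size > 1 and np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")


def _hbi_residual(alpha: float, p: StefanParams) -> float:
    """Heat-balance residual whose root is the front coefficient.

    Derivation: with ``X = alpha sqrt(t)`` and the quadratic profile, the
    Stefan condition fixes ``a X = -S alpha^2 / (2 D)``, the bath condition
    fixes ``b X^2 = C0 + a X``, and the integrated diffusion equation
    d/dt \\int_0^X C dx = -D dC/dx|_X + D dC/dx|_0 reduces to

        C0 u / 6 + S u^2 / (12 D) + S u - 2 D C0 = 0,   u = alpha^2.
    """
    u = alpha * alpha
    return p.C0 * u / 6.0 + p.S * u * u / (12.0 * p.D) + p.S * u - 2.0 * p.D * p.C0


def goodman_alpha(p: StefanParams) -> MovingBoundarySolution:
    """Front coefficient by Goodman's heat-balance-integral method.

    The scalar heat-balance equation is solved for ``alpha`` by bracketed
    root-finding on ``(0, 10 sqrt(2 D C0 / S)]`` (relative tolerance 1e-10,
    bracket doubled up to 10 times if needed).  ``C0 = 0`` returns the
    trivial solution.
    """
    if p.C0 == 0:
        return MovingBoundarySolution(0.0, 0.0, 0.0)
    hi = 10.0 * np.sqrt(2.0 * p.D * p.C0 / p.S)
    lo = 0.0
    f_lo = _hbi_residual(lo, p)  # = -2 D C0 < 0
    for _ in range(10):
        if _hbi_residual(hi, p) > 0:
            break
        hi *= 2.0
    else:
        raise RuntimeError(
            f"no sign change of the heat-balance residual in (0, {hi:g}]; "
            f"residual({hi:g}) = {_hbi_residual(hi, p):g}, residual(0) = {f_lo:g}")
    alpha = brentq(_hbi_residual, lo, hi, args=(p,), rtol=1e-12, xtol=1e-300)
    a_scaled = -p.S * alpha**2 / (2.0 * p.D)
    b_scaled = p.C0 + a_scaled
    return MovingBoundarySolution(float(alpha), float(a_scaled), float(b_scaled))


def front_position(sol: MovingBoundarySolution, t) -> np.ndarray:
    """Front position X = alpha * sqrt(t); t in seconds, X in cm."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return sol.alpha * np.sqrt(t)


def goodman_profile(sol: MovingBoundarySolution, p: StefanParams, t: float,
                    x: Optional[np.ndarray] = None,
                    n: int = 201) -> ConcentrationProfile:
    """Quadratic concentration profile at time t.

    ``C(x) = a (x - X) + b (x - X)^2`` on [0, X]; zero beyond the front.
    ``C(X) = 0`` exactly and ``C(0) = C0`` by construction.
    """
    if t <= 0:
        raise ValueError("profile requires t > 0")
    X = float(front_position(sol, t))
    if x is None:
        x = np.linspace(0.0, X if X > 0 else 1.0, n)
    else:
        x = np.asarray(x, dtype=float)
    if X == 0:
        return ConcentrationProfile(x, np.zeros_like(x), t)
    a, b = sol.profile_coeffs(t)
    xi = np.minimum(x, X) - X
    C = a * xi + b * xi * xi
    C = np.where(x >= X, 0.0, C)
    return ConcentrationProfile(x, C, t)


# --------------------------------------------------------------------------
# finite-difference (finite-volume) oracle
# --------------------------------------------------------------------------

@dataclass
class FDSolution:
    """Output of :func:`fd_solve`.

    ``t``/``X`` sample the front trajectory; ``snapshots`` hold
    concentration profiles; ``mass_balance_rel`` is the relative gap
    between cumulative influx and (stored + immobilized) mass at t_end.
    """

    t: np.ndarray
    X: np.ndarray
    snapshots: list[ConcentrationProfile] = field(default_factory=list)
    mass_balance_rel: float = np.nan
    dx: float = np.nan
    dt: float = np.nan
    params: Optional[StefanParams] = None

    def alpha_fit(self, t_from: Optional[float] = None) -> float:
        """Front coefficient by no-intercept regression of X on sqrt(t)
        (default window: second half of the horizon)."""
        if t_from is None:
            t_from = self.t[-1] / 2.0
        sel = self.t >= t_from
        rt = np.sqrt(self.t[sel])
        return float(np.dot(self.X[sel], rt) / np.dot(rt, rt))


def fd_solve(p: StefanParams, t_end: float, nx: int = 160, cfl: float = 0.5,
             domain_length: Optional[float] = None, n_record: int = 400,
             n_snapshots: int = 5,
             source_lag: Optional[float] = None) -> FDSolution:
    """Explicit finite-volume solver for the moving-boundary problem.

    The domain [0, L] is split into ``nx`` cells.  Cells behind the front
    diffuse explicitly (time step ``cfl`` times the stability limit
    ``dx^2 / 2D``); the flux across the front face accumulates in a
    front-cell buffer, and each time the buffer reaches ``S dx`` the front
    advances one cell.  The sub-cell front position is
    ``X = j_front dx + buffer / S``.  The bath holds ``C(0) = C0``; the
    gradient at the front uses the true sub-cell front distance.

    ``source_lag`` (cm), if given, emulates delamination-assisted
    transport: every cell whose center lies behind ``X - source_lag`` is
    flooded to ``C0`` each step (the delaminated channel), the injected
    mass being added to the influx tally so the balance audit still holds.

    Returns an :class:`FDSolution`; the discrete mass balance
    (influx = stored + S*X) is reported and must hold to ~1e-3 relative.
    """
    if nx < 50:
        raise ValueError("nx must be >= 50")
    if not (0 < cfl <= 0.5):
        raise ValueError(f"cfl must be in (0, 0.5], got {cfl}")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if p.C0 == 0:
        t_rec = np.linspace(0.0, t_end, n_record)
        return FDSolution(t_rec, np.zeros(n_record), [], 0.0, np.nan, np.nan, p)

    if domain_length is None:
        # size the grid so the expected front ends ~70% across it
        x_expect = goodman_alpha(p).alpha * np.sqrt(t_end)
        if source_lag is not None:
            x_expect = max(x_expect, x_expect + (p.D * p.C0 / (p.S * source_lag)) * t_end)
        domain_length = max(x_expect / 0.7, 1e-12)
    L = float(domain_length)
    dx = L / nx
    dt = cfl * dx * dx / (2.0 * p.D)
    n_steps = max(int(np.ceil(t_end / dt)), 1)
    dt = t_end / n_steps

    C = np.zeros(nx)
    flux = np.empty(nx + 1)
    jf = 0
    acc = 0.0       # immobilized mass buffered at the front, per unit area
    influx = 0.0
    rec_every = max(n_steps // max(n_record - 1, 1), 1)
    t_rec, X_rec = [0.0], [0.0]
    snap_at = set((np.linspace(1, n_steps, n_snapshots)).astype(int)) if n_snapshots else set()
    snapshots: list[ConcentrationProfile] = []
    centers = (np.arange(nx) + 0.5) * dx
    Sdx = p.S * dx

    for step in range(1, n_steps + 1):
        m = jf
        if m == 0:
            f_front = 2.0 * p.D * p.C0 / dx
            acc += f_front * dt
            influx += f_front * dt
        else:
            f = flux[: m + 1]
            f[0] = 2.0 * p.D * (p.C0 - C[0]) / dx
            if m > 1:
                f[1:m] = (p.D / dx) * (C[: m - 1] - C[1:m])
            frac = acc / Sdx
            f[m] = p.D * C[m - 1] / ((0.5 + frac) * dx)
            C[:m] += (dt / dx) * (f[:m] - f[1 : m + 1])
            acc += f[m] * dt
            influx += f[0] * dt
        while acc >= Sdx:
            if jf >= nx:
                raise RuntimeError(
                    "front reached the end of the grid; enlarge domain_length")
            acc -= Sdx
            C[jf] = 0.0
            jf += 1
        if source_lag is not None and jf > 0:
            x_front = jf * dx + acc / p.S
            # flood whole cells; comparing centers + dx/2 (right faces) keeps
            # the effective membrane width unbiased at `source_lag` +- dx/2
            n_flood = int(np.searchsorted(centers[:jf],
                                          x_front - source_lag + 0.5 * dx,
                                          side="right"))
            if n_flood > 0:
                influx += float(np.sum(p.C0 - C[:n_flood])) * dx
                C[:n_flood] = p.C0
        if step % rec_every == 0 or step == n_steps:
            if not np.all(np.isfinite(C[:jf])) or not np.isfinite(acc):
                raise RuntimeError(
                    f"finite-difference solution diverged at step {step} "
                    f"(t = {step * dt:g} s, jf = {jf})")
            t_rec.append(step * dt)
            X_rec.append(jf * dx + acc / p.S)
        if step in snap_at:
            snapshots.append(ConcentrationProfile(centers.copy(), C.copy(), step * dt))

    stored = float(np.sum(C[:jf])) * dx
    immobilized = p.S * jf * dx + acc
    balance = abs(influx - (stored + immobilized)) / max(influx, 1e-300)
    return FDSolution(np.asarray(t_rec), np.asarray(X_rec), snapshots,
                      float(balance), dx, dt, p)


# --------------------------------------------------------------------------
# fitting the front coefficient to data
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AlphaFit:
    """No-intercept least-squares fit of s = alpha * sqrt(t)."""

    alpha: float
    resid_sd: float
    r2: float
    n: int

    def __repr__(self) -> str:  # compact, notebook friendly
        return (f"AlphaFit(alpha={self.alpha:.6g}, resid_sd={self.resid_sd:.3g}, "
                f"r2={self.r2:.4f}, n={self.n})")


def fit_alpha(trace: FrontTrace, window: Optional[tuple[float, float]] = None) -> AlphaFit:
    """Fit the phase-I square-root law to a front trace.

    Least squares of ``s = alpha sqrt(t)`` (no intercept) over the time
    window (min, inclusive).  Units of ``alpha`` follow the trace
    (px/sqrt(min) by default).
    """
    if window is not None:
        trace = trace.window(*window)
    if len(trace) < 3:
        raise ValueError("need at least 3 points in the fitting window")
    rt = np.sqrt(trace.t)
    denom = float(np.dot(rt, rt))
    if denom == 0:
        raise ValueError("window contains only t = 0")
    alpha = float(np.dot(trace.s, rt) / denom)
    resid = trace.s - alpha * rt
    dof = max(len(trace) - 1, 1)
    sstot = float(np.sum((trace.s - trace.s.mean()) ** 2))
    sse = float(np.dot(resid, resid))
    r2 = 1.0 - sse / sstot if sstot > 0 else 1.0
    return AlphaFit(alpha, float(np.sqrt(sse / dof)), r2, len(trace))
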