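"""Moving-boundary model: HBI closed form, FD oracle, alpha fitting."""

import numpy as np
import pytest
from scipy.integrate import quad

from delamod import (CompositeFrontLaw, FrontTrace, StefanParams, fd_solve,
                     fit_alpha, front_position, goodman_alpha,
                     goodman_profile, simulate_front_trace)
from conftest import REF_PARAMS


def hbi_alpha_closed_form(D, C0, S):
    """Independent oracle: the heat-balance equation written as a quadratic.

    C0 u/6 + S u^2/(12 D) + S u = 2 D C0 with u = alpha^2 is
    u^2 + 2 D (g + 6) u - 24 D^2 g = 0, g = C0/S, whose positive root is
    u = D (sqrt((g+6)^2 + 24 g) - (g + 6)).
    """
    g = C0 / S
    u = D * (np.sqrt((g + 6.0) ** 2 + 24.0 * g) - (g + 6.0))
    return np.sqrt(u)


class TestGoodmanAlpha:
    @pytest.mark.parametrize("D", [5e-7, 1e-6, 2e-6])
    @pytest.mark.parametrize("g", [0.05, 0.3, 1.0, 10.0])
    def test_matches_quadratic_closed_form(self, D, g):
        p = StefanParams(D=D, C0=1.0, S=1.0 / g)
        assert goodman_alpha(p).alpha == pytest.approx(
            hbi_alpha_closed_form(D, 1.0, 1.0 / g), rel=1e-10)

    def test_no_driving_concentration(self):
        sol = goodman_alpha(StefanParams(D=1e-6, C0=0.0, S=1.0))
        assert sol.alpha == 0 and sol.a_scaled == 0 and sol.b_scaled == 0

    def test_monotone_in_D_and_S(self):
        alphas_D = [goodman_alpha(StefanParams(D=d, C0=1.0, S=5.0)).alpha
                    for d in np.geomspace(1e-7, 1e-6, 6)]
        assert np.all(np.diff(alphas_D) > 0)
        alphas_S = [goodman_alpha(StefanParams(D=1e-6, C0=1.0, S=s)).alpha
                    for s in np.geomspace(1.0, 10.0, 6)]
        assert np.all(np.diff(alphas_S) < 0)

    def test_scaling_only_through_ratio(self):
        # for l = 0, alpha depends on (C0, S) only through C0/S
        a1 = goodman_alpha(StefanParams(D=1e-6, C0=1.0, S=4.0)).alpha
        a2 = goodman_alpha(StefanParams(D=1e-6, C0=3.0, S=12.0)).alpha
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            StefanParams(D=-1e-6, C0=1.0, S=1.0)
        with pytest.raises(ValueError):
            StefanParams(D=1e-6, C0=1.0, S=0.0)
        with pytest.raises(ValueError):
            StefanParams(D=1e-6, C0=1.0, S=1.0, Ci=2.0)  # Ci > C0


class TestFrontPosition:
    def test_zero_time(self):
        sol = goodman_alpha(REF_PARAMS)
        assert front_position(sol, 0.0) == 0.0

    def test_sqrt_scaling(self):
        sol = goodman_alpha(REF_PARAMS)
        t = 1234.5
        assert front_position(sol, 4 * t) == pytest.approx(
            2 * front_position(sol, t), rel=1e-12)

    def test_closed_form_value(self):
        from delamod import MovingBoundarySolution
        sol = MovingBoundarySolution(alpha=2e-3, a_scaled=0.0, b_scaled=0.0)
        assert front_position(sol, 1e4) == pytest.approx(0.2)

    def test_negative_time_rejected(self):
        sol = goodman_alpha(REF_PARAMS)
        with pytest.raises(ValueError):
            front_position(sol, -1.0)


class TestGoodmanProfile:
    def test_boundary_values(self):
        p = REF_PARAMS
        sol = goodman_alpha(p)
        prof = goodman_profile(sol, p, t=5e4)
        assert prof.C[-1] == pytest.approx(0.0, abs=1e-14)     # C(X) = 0
        assert prof.C[0] == pytest.approx(p.C0, rel=1e-12)     # C(0) = C0

    def test_zero_concentration_everywhere(self):
        p = StefanParams(D=1e-6, C0=0.0, S=1.0)
        prof = goodman_profile(goodman_alpha(p), p, t=100.0)
        assert np.all(prof.C == 0)

    @pytest.mark.parametrize("g", [0.05, 0.5, 2.0])
    def test_nonnegative_profile(self, g):
        p = StefanParams(D=1e-6, C0=1.0, S=1.0 / g)
        prof = goodman_profile(goodman_alpha(p), p, t=1e4, n=501)
        assert np.all(prof.C >= -1e-12)

    def test_quadrature_matches_heat_balance_mass(self):
        # integral of the profile over [0, X] must equal the stored-mass
        # term X (C0/3 + S alpha^2 / 12 D) used in the HBI equation
        p = REF_PARAMS
        sol = goodman_alpha(p)
        t = 3e4
        X = float(front_position(sol, t))
        a, b = sol.profile_coeffs(t)
        integral, _ = quad(lambda x: a * (x - X) + b * (x - X) ** 2, 0.0, X,
                           epsabs=1e-16, epsrel=1e-13)
        expected = X * (p.C0 / 3.0 + p.S * sol.alpha**2 / (12.0 * p.D))
        assert integral == pytest.approx(expected, rel=1e-10)


class TestFDSolve:
    def test_mass_balance(self, fd_reference):
        assert fd_reference.mass_balance_rel <= 1e-3

    def test_sqrt_law_emerges(self, fd_reference):
        sel = fd_reference.t >= fd_reference.t[-1] / 2
        r = np.polyfit(np.log(fd_reference.t[sel]),
                       np.log(fd_reference.X[sel]), 1)
        pred = np.polyval(r, np.log(fd_reference.t[sel]))
        ss_res = np.sum((np.log(fd_reference.X[sel]) - pred) ** 2)
        ss_tot = np.sum((np.log(fd_reference.X[sel])
                         - np.log(fd_reference.X[sel]).mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.999
        assert r[0] == pytest.approx(0.5, abs=0.01)

    def test_agrees_with_goodman(self, fd_reference):
        sol = goodman_alpha(REF_PARAMS)
        sel = fd_reference.t >= fd_reference.t[-1] / 2
        Xg = front_position(sol, fd_reference.t[sel])
        rel = np.abs(Xg - fd_reference.X[sel]) / fd_reference.X[sel]
        assert np.max(rel) <= 0.05

    def test_self_convergence_under_grid_halving(self, fd_reference):
        fine = fd_solve(REF_PARAMS, t_end=2e5, nx=320)
        assert abs(fine.X[-1] - fd_reference.X[-1]) / fine.X[-1] < 0.005

    def test_trivial_when_C0_zero(self):
        sol = fd_solve(StefanParams(D=1e-6, C0=0.0, S=1.0), t_end=100.0)
        assert np.all(sol.X == 0)

    def test_concentration_snapshots_nonnegative(self, fd_reference):
        for snap in fd_reference.snapshots:
            assert np.all(snap.C >= -1e-12)

    def test_validation(self):
        with pytest.raises(ValueError, match="nx"):
            fd_solve(REF_PARAMS, t_end=10.0, nx=10)
        with pytest.raises(ValueError, match="cfl"):
            fd_solve(REF_PARAMS, t_end=10.0, cfl=0.9)
        with pytest.raises(ValueError):
            fd_solve(REF_PARAMS, t_end=-1.0)


class TestFitAlpha:
    def test_exact_sqrt_samples_machine_precision(self):
        t = np.arange(1, 50) * 5.0
        tr = FrontTrace(t, 3.0 * np.sqrt(t))
        fit = fit_alpha(tr)
        assert fit.alpha == pytest.approx(3.0, rel=1e-14)
        assert fit.r2 == pytest.approx(1.0)

    def test_zero_trace(self):
        t = np.arange(1, 20) * 5.0
        assert fit_alpha(FrontTrace(t, np.zeros_like(t))).alpha == 0.0

    def test_empty_window_rejected(self):
        tr = simulate_front_trace(CompositeFrontLaw(alpha=1.0), 100.0, 5.0)
        with pytest.raises(ValueError):
            fit_alpha(tr, window=(1000.0, 2000.0))

    def test_noisy_recovery_rate(self, rng):
        # alpha = 1 px/sqrt(min), sd 0.5 px, 100 points: >= 95/100 within 2%
        t = np.arange(1, 101) * 5.0
        hits = 0
        for _ in range(100):
            s = np.sqrt(t) + rng.normal(0.0, 0.5, t.size)
            if abs(fit_alpha(FrontTrace(t, s)).alpha - 1.0) <= 0.02:
                hits += 1
        assert hits >= 95
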