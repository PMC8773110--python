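"""Phase segmentation, delamination front, membrane rate, merge prediction."""

import numpy as np
import pytest

from delamod import (CompositeFrontLaw, FrontKineticsModel, FrontTrace,
                     StefanParams, delamination_front, fd_solve, predict_merge,
                     segment_phases, simulate_front_trace,
                     steady_state_membrane_rate)

LAW = CompositeFrontLaw(alpha=1.0, t1=420.0, v2=0.05, t2=600.0, jump=30.0)


class TestSegmentPhases:
    def test_pure_sqrt_is_single_phase(self):
        tr = simulate_front_trace(CompositeFrontLaw(alpha=1.3), 500.0, 5.0)
        seg = segment_phases(tr)
        assert seg.t1 is None and seg.t2 is None
        assert seg.alpha_hat == pytest.approx(1.3, rel=1e-10)

    def test_composite_recovery_noise_free(self):
        tr = simulate_front_trace(LAW, 700.0, 5.0)
        seg = segment_phases(tr)
        assert seg.t1 == pytest.approx(420.0, abs=5.0)   # one frame interval
        assert seg.t2 == pytest.approx(600.0, abs=5.0)
        assert seg.alpha_hat == pytest.approx(1.0, rel=1e-6)
        assert seg.v2_hat == pytest.approx(0.05, rel=1e-6)
        assert all(n >= 5 for n in seg.n_per_phase)

    def test_changepoint_recovery_under_noise(self, rng):
        # sd 0.5 px: t1 within +-3 frames in >= 90/100 replicates
        tr = simulate_front_trace(LAW, 700.0, 5.0)
        hits = 0
        for _ in range(100):
            s = LAW(tr.t) + rng.normal(0.0, 0.5, tr.t.size)
            seg = segment_phases(FrontTrace(tr.t, s))
            if seg.t1 is not None and abs(seg.t1 - 420.0) <= 15.0:
                hits += 1
        assert hits >= 90

    def test_piecewise_never_beats_single_phase_sse(self, rng):
        for _ in range(10):
            t = np.arange(1, 61) * 5.0
            s = 0.8 * np.sqrt(t) + rng.normal(0, 1.0, t.size)
            seg = segment_phases(FrontTrace(t, s))
            rt = np.sqrt(t)
            alpha1 = float(s @ rt / (rt @ rt))
            sse1 = float(np.sum((s - alpha1 * rt) ** 2))
            assert seg.sse <= sse1 + 1e-9

    def test_median_t1_error_across_conditions(self, rng):
        # 200 composites spanning alpha, v2 and noise: median error <= 2 frames
        errors = []
        noise_levels = [0.0, 0.5, 1.0]
        for i in range(200):
            law = CompositeFrontLaw(alpha=rng.uniform(0.5, 2.0), t1=420.0,
                                    v2=rng.uniform(0.02, 0.2))
            t = np.arange(0, 141) * 5.0
            s = law(t) + rng.normal(0.0, noise_levels[i % 3], t.size)
            seg = segment_phases(FrontTrace(t, s))
            errors.append(abs(seg.t1 - 420.0) if seg.t1 is not None else np.inf)
        assert np.median(errors) <= 10.0

    def test_too_few_points_rejected(self):
        tr = simulate_front_trace(CompositeFrontLaw(alpha=1.0), 50.0, 5.0)
        with pytest.raises(ValueError, match="at least"):
            segment_phases(tr)

    def test_model_results_summary_and_predict(self):
        tr = simulate_front_trace(LAW, 700.0, 5.0)
        res = FrontKineticsModel(tr).fit()
        assert "alpha" in res.summary() and "t1" in res.summary()
        # continuity at t1
        eps = 1e-9
        assert res.predict(res.t1 - eps) == pytest.approx(
            res.predict(res.t1 + eps), abs=1e-6)
        assert res.labels.size == len(tr)

    def test_diagnostic_plot_written(self, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        tr = simulate_front_trace(LAW, 700.0, 5.0)
        out = tmp_path / "seg.png"
        FrontKineticsModel(tr).plot(path=out)
        assert out.stat().st_size > 0


class TestDelaminationFront:
    def test_zero_lag_is_identity(self):
        X = np.linspace(0, 3, 7)
        assert np.array_equal(delamination_front(X, 0.0).d, X)

    def test_all_below_lag_is_zero(self):
        X = np.linspace(0, 0.5, 5)
        assert np.all(delamination_front(X, 1.0).d == 0)

    def test_constant_distance_identity(self):
        X = np.linspace(0, 5, 50)
        st = delamination_front(X, 1.2)
        active = st.d > 0
        np.testing.assert_allclose(X[active] - st.d[active], 1.2)
        assert np.all(np.diff(st.d) >= 0)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            delamination_front(np.array([1.0]), -0.1)


class TestMembraneRate:
    P = StefanParams(D=1e-6, C0=1.0, S=10.0)

    def test_direct_evaluation_and_scaling(self):
        # D C0 / S = 1e-7 cm^2/s: delta = 1e-2 cm gives 1e-5 cm/s
        assert steady_state_membrane_rate(self.P, 1e-2) == pytest.approx(1e-5)
        assert steady_state_membrane_rate(self.P, 2e-2) == pytest.approx(
            0.5 * steady_state_membrane_rate(self.P, 1e-2))

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError, match="unbounded"):
            steady_state_membrane_rate(self.P, 0.0)

    def test_fd_with_flooded_channel_reproduces_rate(self):
        delta = 0.005
        v2 = steady_state_membrane_rate(self.P, delta)
        fd = fd_solve(self.P, t_end=2000.0, nx=200, source_lag=delta)
        sel = fd.t >= fd.t[-1] / 2
        slope = np.polyfit(fd.t[sel], fd.X[sel], 1)[0]
        assert slope == pytest.approx(v2, rel=0.10)
        assert fd.mass_balance_rel <= 1e-3

    def test_v2_feedback_through_generator_and_segmentation(self):
        # feed the membrane rate into the generator's phase II, re-segment
        delta = 0.005
        v2 = steady_state_membrane_rate(self.P, delta)        # cm/s
        from delamod import goodman_alpha
        alpha = goodman_alpha(self.P).alpha                    # cm/sqrt(s)
        t1 = (delta / alpha) ** 2                              # front at delta
        # work in cm/min for the trace
        law = CompositeFrontLaw(alpha=alpha * np.sqrt(60.0), t1=t1 / 60.0,
                                v2=v2 * 60.0)
        tr = simulate_front_trace(law, duration=3 * t1 / 60.0, step=t1 / 60.0 / 50)
        seg = segment_phases(tr)
        assert seg.v2_hat == pytest.approx(v2 * 60.0, rel=0.05)


class TestPredictMerge:
    P = StefanParams(D=1e-6, C0=1.0, S=10.0)

    def test_interface_wins_as_bulk_vanishes(self):
        pred = predict_merge(self.P, D_bulk=0.0, cover_thickness=0.1,
                             r0=1.5, delta=0.01)
        assert pred.mode == "interface"
        assert np.isfinite(pred.t_merge_s)

    def test_bulk_wins_for_huge_droplet(self):
        pred = predict_merge(self.P, D_bulk=1e-6, cover_thickness=0.1,
                             r0=np.inf, delta=0.01)
        assert pred.mode == "bulk"
        assert pred.t_merge_s == pytest.approx(0.1**2 / (2e-6))

    def test_closed_form_cross_check(self):
        from delamod import goodman_alpha
        delta, r0, cover, Db = 0.01, 1.5, 0.1, 1e-7
        pred = predict_merge(self.P, Db, cover, r0, delta)
        alpha = goodman_alpha(self.P).alpha
        t1 = (delta / alpha) ** 2
        v2 = self.P.D * self.P.C0 / (self.P.S * delta)
        assert pred.t_interface_s == pytest.approx(t1 + (r0 - delta) / v2,
                                                   rel=1e-12)
        assert pred.t_bulk_s == pytest.approx(cover**2 / (2 * Db), rel=1e-12)

    def test_small_droplet_pure_phase_one(self):
        from delamod import goodman_alpha
        alpha = goodman_alpha(self.P).alpha
        pred = predict_merge(self.P, 0.0, 0.1, r0=0.005, delta=0.01)
        assert pred.t_interface_s == pytest.approx((0.005 / alpha) ** 2)

    def test_validation(self):
        with pytest.raises(ValueError):
            predict_merge(self.P, 1e-6, -0.1, 1.0, 0.01)
        with pytest.raises(ValueError):
            predict_merge(self.P, -1e-6, 0.1, 1.0, 0.01)
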