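"""Unit and property tests for the mechanistic kinetic model."""

import numpy as np
import pytest

from fermhybrid.kinetics import (
    BATCH,
    StateVector,
    Trajectory,
    _make_fast_rhs,
    effective_fructose_params,
    reaction_rates,
    rhs,
    simulate,
    smooth_gate,
    specific_rates,
)
from fermhybrid.params import GatingConfig, KineticParameters


class TestSmoothGate:
    def test_zero_exactly_at_threshold(self, gating):
        assert smooth_gate(gating.threshold, "deplete", gating) == 0.0

    def test_saturates_to_one_away_from_threshold(self, gating):
        assert smooth_gate(10.0, "deplete", gating) == pytest.approx(1.0, abs=1e-6)

    def test_leak_below_threshold(self, gating):
        # z = -1e-3, max(gamma z, z) = -1e-5, denominator sqrt(2e-6)
        expected = -1e-5 / np.sqrt(1e-6 + 1e-6)
        assert smooth_gate(0.0, "deplete", gating) == pytest.approx(expected, rel=1e-12)
        assert smooth_gate(0.0, "deplete", gating) == pytest.approx(-7.07e-3, rel=1e-3)

    def test_appear_direction_mirrors_deplete(self, gating):
        for c in (0.0, 0.0005, 0.002, 1.0):
            z = gating.threshold - c
            num = max(gating.gamma * z, z)
            assert smooth_gate(c, "appear", gating) == pytest.approx(
                num / np.sqrt(z * z + gating.epsilon))

    def test_derivative_matches_analytic_away_from_kink(self, gating):
        # d/dz [ m z / sqrt(z^2+eps) ] = m eps / (z^2+eps)^{3/2}, m = 1 or gamma
        eps = gating.epsilon
        for c in (0.02, 0.1, 0.5, -0.05, -0.2):
            z = c - gating.threshold
            m = 1.0 if z > 0 else gating.gamma
            analytic = m * eps / (z * z + eps) ** 1.5
            h = 1e-3 * max(abs(z), 1e-2)

            def central(hh):
                return (smooth_gate(c + hh, "deplete", gating)
                        - smooth_gate(c - hh, "deplete", gating)) / (2 * hh)
            fd = (4 * central(h / 2) - central(h)) / 3  # Richardson, O(h^4)
            assert fd == pytest.approx(analytic, rel=1e-6, abs=1e-18)

    def test_step_function_limit(self):
        sharp = GatingConfig(gamma=1e-8, epsilon=1e-16, threshold=0.001)
        for z in (0.1, 1.0, 25.0):
            assert smooth_gate(z + sharp.threshold, "deplete", sharp) == pytest.approx(1.0, abs=1e-6)
            assert smooth_gate(-z + sharp.threshold, "deplete", sharp) == pytest.approx(0.0, abs=1e-6)

    def test_rejects_non_finite_input(self, gating):
        with pytest.raises(ValueError):
            smooth_gate(float("nan"), "deplete", gating)
        with pytest.raises(ValueError):
            smooth_gate(1.0, "sideways", gating)


class TestEffectiveFructoseParams:
    def test_repression_active_with_glucose_present(self, params, gating):
        mu_eff, _ = effective_fructose_params(20.0, params, gating)
        s = smooth_gate(20.0, "appear", gating)
        assert s == pytest.approx(-gating.gamma, rel=1e-3)  # leak term only
        assert mu_eff == pytest.approx(
            params.mu_max_R + s * (params.mu_max_postG - params.mu_max_R))
        assert mu_eff == pytest.approx(params.mu_max_R, rel=0.05)

    def test_blend_at_zero_glucose(self, params, gating):
        s = smooth_gate(0.0, "appear", gating)
        assert s == pytest.approx(0.707, rel=1e-2)
        mu_eff, K_eff = effective_fructose_params(0.0, params, gating)
        assert mu_eff == pytest.approx(
            params.mu_max_R + s * (params.mu_max_postG - params.mu_max_R))
        assert K_eff == pytest.approx(
            params.K_R + s * (params.K_R_postG - params.K_R))

    def test_identity_when_post_equals_pre(self, params, gating):
        p = params.replace(mu_max_postG=params.mu_max_R)
        for G in (0.0, 0.001, 5.0, 30.0):
            mu_eff, _ = effective_fructose_params(G, p, gating)
            assert mu_eff == pytest.approx(params.mu_max_R, rel=1e-12)


class TestSpecificRates:
    def test_all_zero_without_substrates(self, params, gating):
        st = StateVector(X=1.0, G=0.0, R=0.0, S=0.0, U=0.0, Et=0.0)
        mu_G, mu_R, mu_Et, mu_X = specific_rates(st, params, gating)
        assert mu_X == 0.0

    def test_glucose_rate_saturates_at_mu_max(self, params, gating):
        st = StateVector(X=1.0, G=1000 * params.K_G, R=0.0, S=0.0, U=0.0, Et=0.0)
        mu_G, *_ = specific_rates(st, params, gating)
        assert mu_G == pytest.approx(params.mu_max_G, rel=1e-3)

    def test_half_saturation_with_ethanol_inhibition(self, params, gating):
        st = StateVector(X=1.0, G=params.K_G, R=0.0, S=0.0, U=0.0,
                         Et=params.K_i_Et)
        mu_G, *_ = specific_rates(st, params, gating)
        assert mu_G == pytest.approx(0.149 * 0.5 * 0.5, rel=1e-9)


class TestReactionRates:
    def test_sucrose_uptake_worked_value(self, params, gating):
        st = StateVector(X=1.2, G=0.0, R=0.0, S=39.6, U=0.0, Et=0.0)
        r = reaction_rates(st, params, gating)
        assert r.r_S == pytest.approx(7.645 * (39.6 / (39.6 + 29.935)) * 1.2, rel=1e-12)
        assert r.r_S == pytest.approx(5.22, abs=0.01)
        assert r.r_gG == pytest.approx(r.r_S * 0.520, rel=1e-12)
        assert r.r_gG == pytest.approx(2.72, abs=0.01)

    def test_hydrolysis_feeds_both_monosaccharides_equally(self, params, gating):
        rng = np.random.default_rng(5)
        for _ in range(20):
            st = StateVector(*rng.uniform(
                [0.1, 0, 0, 0, 0, 0, 0.2], [5, 30, 30, 40, 3, 12, 0.5]))
            r = reaction_rates(st, params, gating)
            assert r.r_gG == r.r_gR

    def test_everything_zero_leaves_only_gate_leak(self, params, gating):
        st = StateVector(X=1.0, G=0.0, R=0.0, S=0.0, U=0.0, Et=0.0)
        r = reaction_rates(st, params, gating, clamp_nonpositive=False)
        leak_scale = gating.gamma * gating.threshold / np.sqrt(gating.epsilon)
        for val in (r.r_X, r.r_S, r.r_gG, r.r_Et, r.r_Et_c):
            assert val == pytest.approx(0.0, abs=1e-12)
        # gated consumption terms may show the leak only
        for val in (r.r_G, r.r_R, r.r_Ur):
            assert abs(val) <= leak_scale * 10

    def test_yield_denominator_flag_switches_fructose_term(self, params, gating):
        st = StateVector(X=2.0, G=5.0, R=5.0, S=5.0, U=1.0, Et=2.0)
        rG = reaction_rates(st, params, gating).r_R
        rR = reaction_rates(st, params, gating,
                            fructose_ethanol_yield_denominator="R").r_R
        assert rG != rR


class TestRHS:
    def test_zero_concentrations_give_zero_derivative(self, params, gating):
        st = StateVector(X=0.0, G=0.0, R=0.0, S=0.0, U=0.0, Et=0.0)
        d = rhs(0.0, st, params, cfg=gating)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_sucrose_balance_is_minus_uptake(self, params, gating):
        st = StateVector(X=1.2, G=0.0, R=0.0, S=39.6, U=0.0, Et=0.0)
        d = rhs(0.0, st, params, cfg=gating)
        r = reaction_rates(st, params, gating)
        assert d[3] == pytest.approx(-r.r_S, rel=1e-12)
        assert d[3] == pytest.approx(-5.22, abs=0.01)

    def test_glucose_gains_hydrolysis_flux_when_depleted(self, params, gating):
        # with G below threshold the consumption gate is ~0 and dG ~ r_gG
        st = StateVector(X=1.2, G=0.0005, R=10.0, S=20.0, U=1.0, Et=1.0)
        d = rhs(0.0, st, params, cfg=gating)
        r = reaction_rates(st, params, gating)
        assert d[1] == pytest.approx(r.r_gG, rel=0.05)

    def test_volume_error_aborts(self, params):
        st = StateVector(X=1.0, G=1.0, R=1.0, S=1.0, U=1.0, Et=0.0, V=0.3)
        st.V = -0.1  # corrupt after validation
        from fermhybrid.kinetics import SolverError
        with pytest.raises(SolverError):
            rhs(0.0, st, params)

    def test_fast_path_matches_readable_implementation(self, params, gating):
        fast = _make_fast_rhs(params, BATCH, gating, {})
        rng = np.random.default_rng(0)
        for _ in range(100):
            y = rng.uniform([0, 0, 0, 0, 0, 0, 0.2], [8, 40, 40, 40, 3, 15, 0.5])
            a = np.asarray(fast(0.0, y))
            b = rhs(0.0, StateVector.from_array(y), params, cfg=gating)
            assert np.allclose(a, b, rtol=0, atol=1e-13)

    def test_glucose_only_growth_obeys_yield_stoichiometry(self, gating):
        # m_G = 0 and no ethanol production: consumed glucose = Y_G_X * dX
        p = KineticParameters.defaults().replace(
            m_G=0.0, Y_Et_X=1e-12, mu_max_Et=1e-12)
        ic = StateVector(X=0.5, G=20.0, R=0.0, S=0.0, U=10.0, Et=0.0)
        traj = simulate(ic, p, np.linspace(0, 8, 17), gating)
        X = traj.states[:, 0]
        G = traj.states[:, 1]
        assert G[-1] > 1.0  # still in the exponential phase, gate fully on
        consumed = G[0] - G[-1]
        assert consumed == pytest.approx(p.Y_G_X * (X[-1] - X[0]), rel=1e-3)


class TestSimulate:
    def test_zero_inoculum_stays_constant(self, params, gating):
        ic = StateVector(X=0.0, G=10.0, R=10.0, S=10.0, U=2.0, Et=0.0)
        traj = simulate(ic, params, np.linspace(0, 20, 11), gating)
        assert np.allclose(traj.states, traj.states[0], atol=1e-9)

    def test_first_state_equals_initial_condition_exactly(self, params, gating, test_ic):
        traj = simulate(test_ic, params, np.linspace(0, 10, 6), gating)
        assert np.array_equal(traj.states[0], test_ic.to_array())

    def test_two_phase_batch_dynamics(self, params, gating, test_ic):
        """Sugars deplete and stay depleted; ethanol rises then falls."""
        t = np.linspace(0, 50, 201)
        traj = simulate(test_ic, params, t, gating)
        df = traj.to_frame()
        for sugar in ("glucose", "fructose", "sucrose"):
            depleted = df[sugar] < 0.01
            first = depleted.idxmax()
            assert depleted.loc[first:].all(), f"{sugar} rebounds after depletion"
        et = df["ethanol"].to_numpy()
        peak = et.argmax()
        assert 0 < peak < len(et) - 1
        assert np.all(np.diff(et[:peak + 1]) > -1e-4)
        assert np.all(np.diff(et[peak:]) < 1e-4)
        assert (traj.values() >= 0).all()

    def test_tolerance_refinement_converges_to_reference(self, params, gating, test_ic):
        # convergence is degraded to ~first order in tol by the depletion
        # kinks; assert monotone approach to a tight-tolerance reference
        t = np.linspace(0, 50, 51)
        ref = simulate(test_ic, params, t, gating, atol=1e-11, rtol=1e-11).values()
        errs = [np.abs(simulate(test_ic, params, t, gating,
                                atol=tol, rtol=tol).values() - ref).max()
                for tol in (1e-6, 1e-8, 1e-10)]
        assert errs[0] < 1e-2       # default tolerance: well below noise scale
        assert errs[1] < errs[0]
        assert errs[2] < 1e-4

    def test_agrees_with_fixed_step_rk4(self, params, gating, test_ic):
        t = np.linspace(0, 10, 11)
        traj = simulate(test_ic, params, t, gating)
        f = _make_fast_rhs(params, BATCH, gating, {})
        h = 1e-3
        y = test_ic.to_array()
        out = [y.copy()]
        for k in range(10000):
            tk = k * h
            k1 = np.asarray(f(tk, y))
            k2 = np.asarray(f(tk + h / 2, y + h / 2 * k1))
            k3 = np.asarray(f(tk + h / 2, y + h / 2 * k2))
            k4 = np.asarray(f(tk + h, y + h * k3))
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            if (k + 1) % 1000 == 0:
                out.append(y.copy())
        ref = np.array(out)
        assert np.abs(ref[:, :6] - traj.values()).max() < 1e-4

    def test_grid_validation(self, params, test_ic):
        with pytest.raises(ValueError):
            simulate(test_ic, params, [0.0])
        with pytest.raises(ValueError):
            simulate(test_ic, params, [1.0, 2.0])
        with pytest.raises(ValueError):
            simulate(test_ic, params, [0.0, 2.0, 2.0])

    def test_csv_round_trip(self, params, gating, test_ic, tmp_path):
        traj = simulate(test_ic, params, np.linspace(0, 10, 6), gating)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert np.allclose(back.states, traj.states)
        assert np.allclose(back.times, traj.times)


class TestStateVector:
    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            StateVector(X=-1.0, G=0, R=0, S=0, U=0, Et=0)

    def test_rejects_non_positive_volume(self):
        with pytest.raises(ValueError):
            StateVector(X=1.0, G=0, R=0, S=0, U=0, Et=0, V=0.0)

    def test_clamps_solver_undershoot(self):
        st = StateVector(X=1.0, G=-5e-10, R=0, S=0, U=0, Et=0)
        assert st.G == 0.0

    def test_batch_feed_is_all_zero(self):
        assert BATCH.is_batch
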