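"""Tests for forward sensitivities, PRA metrics, fixing and Monte Carlo."""

import numpy as np
import pandas as pd
import pytest

from fermhybrid.datasets import NoiseModel, generate_experiment
from fermhybrid.identifiability import (
    SensitivityTrajectory,
    _pra_for_free_set,
    confidence_interval,
    forward_sensitivities,
    integrate_sensitivities,
    monte_carlo_bands,
    pra_metrics,
    sequential_fixing,
)
from fermhybrid.kinetics import simulate
from fermhybrid.params import KineticParameters, PARAM_NAMES


class TestIntegrateSensitivities:
    def test_exponential_decay_closed_form(self):
        # dx/dt = -k x, x(0) = 1: dx/dk at t = -t exp(-k t)
        f = lambda y, th: np.array([-th[0] * y[0]])
        jy = lambda y, th: np.array([[-th[0]]])
        jt = lambda y, th: np.array([[-y[0]]])
        t = np.array([0.0, 0.5, 1.0, 2.0])
        states, sens = integrate_sensitivities(f, jy, jt, [1.0], [1.0], t)
        assert np.allclose(states[:, 0], np.exp(-t), atol=1e-7)
        assert np.allclose(sens[:, 0, 0], -t * np.exp(-t), atol=1e-7)

    def test_sensitivities_start_at_zero(self, params, test_ic):
        st = forward_sensitivities(params, test_ic, np.linspace(0, 5, 6))
        assert np.all(st.sens[0] == 0.0)


class TestForwardSensitivities:
    def test_structurally_absent_parameter_has_zero_sensitivity(self, params, test_ic):
        # with the as-printed fructose equation, Y_Et_R appears nowhere
        st = forward_sensitivities(params, test_ic, np.linspace(0, 20, 11),
                                   param_names=("Y_Et_R",))
        assert np.abs(st.sens).max() == 0.0

    def test_states_match_direct_simulation(self, params, test_ic, gating):
        t = np.linspace(0, 20, 11)
        st = forward_sensitivities(params, test_ic, t, gating)
        traj = simulate(test_ic, params, t, gating, atol=1e-9, rtol=1e-9)
        assert np.abs(st.states - traj.values()).max() < 1e-4

    def test_matches_central_finite_differences(self, params, test_ic, gating):
        """Scaled-sensitivity agreement with the FD oracle on [0, 10] h."""
        t = np.linspace(0, 10, 21)
        checkpoints = [4, 8, 12, 16, 20]
        st = forward_sensitivities(params, test_ic, t, gating)
        th0 = params.to_array()
        norms = np.abs(st.states).max(axis=0)
        scaled_fwd = st.sens * th0[None, None, :] / norms[None, :, None]
        global_scale = np.abs(scaled_fwd).max()
        worst = 0.0
        for j in range(len(PARAM_NAMES)):
            h = 1e-5 * max(th0[j], 1e-10)
            tp, tm = th0.copy(), th0.copy()
            tp[j] += h
            tm[j] -= h
            yp = simulate(test_ic, KineticParameters.from_array(tp), t, gating,
                          atol=1e-11, rtol=1e-11).values()
            ym = simulate(test_ic, KineticParameters.from_array(tm), t, gating,
                          atol=1e-11, rtol=1e-11).values()
            fd_scaled = (yp - ym) / (2 * h) * th0[j] / norms[None, :]
            err = np.abs(fd_scaled[checkpoints] - scaled_fwd[checkpoints, :, j]).max()
            worst = max(worst, err / global_scale)
        assert worst < 1e-3


class TestPRAMetrics:
    def _toy_sens(self, columns):
        """A SensitivityTrajectory wrapping given raw sensitivity columns."""
        n_t, n_p = columns.shape
        return SensitivityTrajectory(
            times=np.arange(n_t, dtype=float),
            states=np.ones((n_t, 1)),
            sens=columns[:, None, :],
            param_names=tuple(f"p{i}" for i in range(n_p)),
        )

    def test_t_value_is_inverse_relative_sd(self):
        # theta = 0.149 with 1.83% relative SD -> t = 1/0.0183 ~ 54.6
        sigma_pct = 1.83
        t_val = 1.0 / (sigma_pct / 100.0)
        assert t_val == pytest.approx(54.6, abs=0.1)
        lo, hi = confidence_interval(0.149, sigma_pct)
        assert lo == pytest.approx(0.146, abs=5e-4)
        assert hi == pytest.approx(0.152, abs=5e-4)

    def test_ci_convention_reproduces_half_saturation_row(self):
        lo, hi = confidence_interval(29.935, 19.68)
        assert lo == pytest.approx(24.04, abs=0.01)
        assert hi == pytest.approx(35.83, abs=0.01)

    def test_perfectly_confounded_product_is_non_identifiable(self):
        # model r = theta1 * theta2: scaled sensitivities are identical
        rng = np.random.default_rng(0)
        base = rng.uniform(0.5, 2.0, 12)
        sens = self._toy_sens(np.column_stack([2.0 * base, 3.0 * base]))
        report = pra_metrics(sens, residual_variance=0.01,
                             theta=np.array([3.0, 2.0]))
        assert abs(report.correlation[0, 1]) == pytest.approx(1.0, abs=1e-9)
        assert report.classification["p0"] == "non-identifiable"
        assert report.classification["p1"] == "non-identifiable"

    def test_independent_parameters_are_significant(self):
        rng = np.random.default_rng(1)
        sens = self._toy_sens(rng.normal(size=(40, 3)))
        report = pra_metrics(sens, residual_variance=1e-6,
                             theta=np.array([1.0, 2.0, 3.0]))
        assert all(report.classification[f"p{i}"] == "significant"
                   for i in range(3))
        K = report.correlation
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), 1.0)
        assert (np.abs(K) <= 1.0 + 1e-12).all()

    def test_noiseless_single_parameter_t_diverges(self, params, test_ic):
        ds = generate_experiment(params, test_ic, noise=NoiseModel.noiseless(),
                                 rng_seed=0, role="test",
                                 times=np.linspace(0, 48, 20))
        from fermhybrid.params import GatingConfig
        report = _pra_for_free_set([ds], params, ("mu_max_G",), GatingConfig())
        assert report.t_values[0] > 100.0
        assert report.sigma_pct[0] < 1.0

    def test_report_summary_renders(self):
        rng = np.random.default_rng(2)
        sens = self._toy_sens(rng.normal(size=(20, 2)))
        report = pra_metrics(sens, 1e-4, np.array([1.0, 2.0]))
        text = report.summary()
        assert "t_value" in text and "p0" in text


@pytest.fixture(scope="module")
def densified_sets(params):
    """Two noisy replicate runs, densified to 10 points per parameter."""
    from fermhybrid.datasets import (
        InitialConditionSpec, densify, draw_initial_conditions)
    sets = []
    for seed in (21, 22):
        ic = draw_initial_conditions(InitialConditionSpec(), "train", seed)
        ds = generate_experiment(params, ic, noise=NoiseModel(),
                                 rng_seed=seed, role="train")
        sets.append(densify(ds, len(PARAM_NAMES)))
    return sets


class TestSequentialFixing:
    def test_fixes_nonempty_subset_and_keeps_key_parameters(
            self, densified_sets, params, gating):
        free, fixed, report = sequential_fixing(
            densified_sets, params, PARAM_NAMES, gating)
        assert len(fixed) > 0
        assert set(free) | set(fixed) == set(PARAM_NAMES)
        assert len(set(free) & set(fixed)) == 0
        # structurally absent parameter must be fixed in stage 1
        assert "Y_Et_R" in fixed
        # strongly excited parameters survive the screening
        for name in ("mu_max_G", "alpha_S", "Y_X_Ur"):
            assert name in free
        # stage 2's exit condition: no correlated pair remains
        corr = np.abs(report.correlation.copy())
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.95

    def test_significance_of_well_excited_parameters(
            self, densified_sets, params, gating):
        """With all substrates present, the t-test passes for the key growth,
        hydrolysis and nitrogen parameters."""
        from fermhybrid.params import SIGNIFICANT_PARAMS
        report = _pra_for_free_set(densified_sets, params,
                                   SIGNIFICANT_PARAMS, gating)
        t_by_name = dict(zip(report.param_names, report.t_values))
        for name in ("mu_max_G", "alpha_S", "K_S", "Y_X_Ur"):
            assert t_by_name[name] > 2.0


class TestMonteCarloBands:
    def test_zero_spread_collapses_onto_nominal(self, params, test_ic):
        t = np.linspace(0, 30, 16)
        bands = monte_carlo_bands(params, test_ic, t, rel_sd=0.0, N=5, rng_seed=0)
        assert np.allclose(bands.lower, bands.nominal, atol=1e-9)
        assert np.allclose(bands.upper, bands.nominal, atol=1e-9)

    def test_nominal_contained_in_envelope(self, params, test_ic):
        t = np.linspace(0, 48, 25)
        bands = monte_carlo_bands(params, test_ic, t, rel_sd=0.05, N=40,
                                  rng_seed=3)
        assert (bands.lower <= bands.nominal + 1e-9).all()
        assert (bands.nominal <= bands.upper + 1e-9).all()

    def test_band_width_grows_with_spread(self, params, test_ic):
        t = np.linspace(0, 48, 13)
        widths = []
        for sd in (0.01, 0.05, 0.10):
            b = monte_carlo_bands(params, test_ic, t, rel_sd=sd, N=40, rng_seed=8)
            widths.append((b.upper - b.lower).mean())
        assert widths[0] < widths[1] < widths[2]

    def test_determinism_and_validation(self, params, test_ic):
        t = np.linspace(0, 10, 6)
        a = monte_carlo_bands(params, test_ic, t, N=5, rng_seed=4)
        b = monte_carlo_bands(params, test_ic, t, N=5, rng_seed=4)
        assert np.array_equal(a.lower, b.lower)
        with pytest.raises(ValueError):
            monte_carlo_bands(params, test_ic, t, N=1)
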