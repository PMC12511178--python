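"""Tests for residual computation, scaling, windowing and hybrid blending."""

import numpy as np
import pandas as pd
import pytest

from fermhybrid.datasets import ExperimentDataset, NoiseModel, generate_experiment
from fermhybrid.hybrid import (
    HybridResidualModel,
    HybridWeights,
    ResidualScaler,
    compute_residuals,
    hybrid_predict,
    make_windows,
)
from fermhybrid.kinetics import STATE_NAMES, simulate


class TestResidualScaler:
    def test_round_trip_is_exact(self):
        rng = np.random.default_rng(0)
        R = rng.normal(size=(30, 6)) * np.array([1, 5, 10, 0.1, 2, 7])
        sc = ResidualScaler().fit(R)
        scaled = sc.transform(R)
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0
        assert np.abs(sc.inverse_transform(scaled) - R).max() < 1e-10

    def test_degenerate_channel_maps_to_zero(self):
        R = np.column_stack([np.arange(5.0), np.full(5, 3.3)])
        sc = ResidualScaler().fit(R)
        scaled = sc.transform(R)
        assert np.all(scaled[:, 1] == 0.0)
        back = sc.inverse_transform(scaled)
        assert np.allclose(back[:, 1], 3.3)

    def test_out_of_range_inputs_allowed(self):
        sc = ResidualScaler().fit(np.array([[0.0], [1.0]]))
        assert sc.transform(np.array([[2.0]]))[0, 0] == 2.0

    def test_unfitted_scaler_raises(self):
        with pytest.raises(RuntimeError):
            ResidualScaler().transform(np.zeros((2, 6)))


class TestComputeResiduals:
    def test_perfect_model_gives_zero_residuals(self, params, noiseless_test_ds):
        rs = compute_residuals(noiseless_test_ds, params)
        assert np.abs(rs.matrix).max() == 0.0
        scaled = ResidualScaler().fit(rs.matrix).transform(rs.matrix)
        assert np.all(scaled == 0.0)

    def test_constant_offset_becomes_degenerate_channel(self, params, noiseless_test_ds):
        shifted = ExperimentDataset(
            role="test",
            times=noiseless_test_ds.times,
            values=noiseless_test_ds.values + 1.0,
            volume=noiseless_test_ds.volume)
        # keep the original initial state for the simulation to diverge from
        rs_matrix = (shifted.values.to_numpy()
                     - compute_residuals(noiseless_test_ds, params).trajectory.values())
        assert np.allclose(rs_matrix, 1.0 + compute_residuals(
            noiseless_test_ds, params).matrix)

    def test_recovers_injected_bias(self, params, test_ic, gating):
        """A known sinusoidal bias on ethanol is returned exactly."""
        t = np.linspace(0, 40, 21)
        traj = simulate(test_ic, params, t, gating)
        bias = 0.5 * np.sin(t / 5.0)
        vals = traj.values().copy()
        k = STATE_NAMES.index("ethanol")
        vals[:, k] = np.maximum(vals[:, k] + bias, 0.0)
        ds = ExperimentDataset(role="test", times=t,
                               values=pd.DataFrame(vals, columns=list(STATE_NAMES)),
                               volume=test_ic.V)
        rs = compute_residuals(ds, params, gating)
        clipped = np.maximum(traj.values()[:, k] + bias, 0.0) - traj.values()[:, k]
        assert np.abs(rs.matrix[:, k] - clipped).max() < 1e-9


class TestMakeWindows:
    def test_pair_count(self):
        X, y = make_windows(np.arange(20.0)[:, None], p=5)
        assert X.shape == (15, 5, 1)
        assert y.shape == (15, 1)

    def test_minimum_series_single_pair(self):
        series = np.arange(6.0)[:, None]
        X, y = make_windows(series, p=5)
        assert X.shape == (1, 5, 1)
        assert np.array_equal(X[0, :, 0], np.arange(5.0))
        assert y[0, 0] == 5.0

    def test_consecutive_windows_overlap(self):
        series = np.random.default_rng(0).normal(size=(12, 3))
        X, _ = make_windows(series, p=5)
        for i in range(len(X) - 1):
            assert np.array_equal(X[i, 1:], X[i + 1, :-1])

    def test_targets_reproduce_tail_of_series(self):
        series = np.random.default_rng(1).normal(size=(17, 4))
        _, y = make_windows(series, p=5)
        assert np.array_equal(y, series[5:])

    def test_too_short_series_error_names_minimum(self):
        with pytest.raises(ValueError, match="p \\+ 1 = 6"):
            make_windows(np.zeros((5, 2)), p=5)


class _StubNetwork:
    """Predicts a fixed scaled residual regardless of the window."""

    def __init__(self, scaled_value):
        self.scaled_value = np.asarray(scaled_value, dtype=float)

    def predict(self, X):
        return np.tile(self.scaled_value, (len(X), 1))


class TestHybridPredict:
    @pytest.fixture()
    def setting(self, params, noiseless_test_ds, gating):
        traj = simulate(noiseless_test_ds.initial_state, params,
                        noiseless_test_ds.times, gating)
        scaler = ResidualScaler().fit(
            np.vstack([np.zeros(6), np.ones(6)]))  # identity-ish scaling
        return traj, scaler

    def test_pure_mechanistic_weights(self, setting, noiseless_test_ds):
        traj, scaler = setting
        net = _StubNetwork(np.full(6, 0.7))
        pred = hybrid_predict(traj, net, scaler,
                              HybridWeights(lambda_pheno=1.0, lambda_ml=0.0),
                              observed=noiseless_test_ds)
        assert np.allclose(pred.hybrid.to_numpy(), np.maximum(traj.values(), 0))

    def test_blend_arithmetic(self, setting, noiseless_test_ds):
        traj, scaler = setting
        net = _StubNetwork(np.full(6, 2.0))  # inverse-scales to residual 2.0
        pred = hybrid_predict(traj, net, scaler, HybridWeights(0.3, 0.7),
                              observed=noiseless_test_ds)
        i = 10
        y_ph = traj.values()[i]
        expected = 0.3 * y_ph + 0.7 * (y_ph + 2.0)
        assert np.allclose(pred.hybrid.to_numpy()[i], expected)
        # worked numbers: pheno 10, ml 12 -> 11.4
        assert 0.3 * 10 + 0.7 * 12 == pytest.approx(11.4)

    def test_zero_residual_model_collapses_to_mechanistic(self, setting, noiseless_test_ds):
        traj, scaler = setting
        net = _StubNetwork(np.zeros(6))
        for lam in (HybridWeights(0.3, 0.7), HybridWeights(0.5, 0.5)):
            pred = hybrid_predict(traj, net, scaler, lam,
                                  observed=noiseless_test_ds)
            assert np.allclose(pred.hybrid.to_numpy(),
                               np.maximum(traj.values(), 0.0))

    def test_lookback_head_falls_back_to_mechanistic(self, setting, noiseless_test_ds):
        traj, scaler = setting
        net = _StubNetwork(np.full(6, 5.0))
        pred = hybrid_predict(traj, net, scaler, observed=noiseless_test_ds)
        assert np.allclose(pred.hybrid.to_numpy()[:5],
                           np.maximum(traj.values()[:5], 0.0))
        assert not np.allclose(pred.hybrid.to_numpy()[5], traj.values()[5])

    def test_outputs_clamped_non_negative(self, setting, noiseless_test_ds):
        traj, scaler = setting
        net = _StubNetwork(np.full(6, -50.0))
        pred = hybrid_predict(traj, net, scaler, observed=noiseless_test_ds)
        assert (pred.hybrid.to_numpy() >= 0).all()

    def test_rollout_and_scaler_validation(self, setting, noiseless_test_ds):
        traj, scaler = setting
        net = _StubNetwork(np.zeros(6))
        with pytest.raises(ValueError):
            hybrid_predict(traj, net, ResidualScaler(), observed=noiseless_test_ds)
        with pytest.raises(ValueError):
            hybrid_predict(traj, net, scaler, rollout="free-running",
                           observed=noiseless_test_ds)
        with pytest.raises(ValueError):
            hybrid_predict(traj, net, scaler, rollout="teacher", observed=None)

    def test_recursive_rollout_runs_without_observations(self, setting):
        traj, scaler = setting
        net = _StubNetwork(np.full(6, 0.5))
        pred = hybrid_predict(traj, net, scaler, rollout="recursive")
        assert pred.hybrid.shape == traj.values().shape


class TestHybridResidualModel:
    def test_window_bookkeeping_across_replicates(self, params, gating):
        from fermhybrid.datasets import InitialConditionSpec, draw_initial_conditions
        sets = []
        for seed in (31, 32):
            ic = draw_initial_conditions(InitialConditionSpec(), "train", seed)
            sets.append(generate_experiment(
                params, ic, rng_seed=seed, role="train",
                times=np.linspace(0, 48, 13)))
        model = HybridResidualModel(params, sets, gating)
        scaler, X, y = model._windows()
        # windows never straddle replicate boundaries: (13 - 5) per run
        assert len(X) == 2 * (13 - 5)
        assert X.shape[1:] == (5, 6)

    def test_fit_with_fixed_config_and_end_to_end_predict(
            self, params, gating, noisy_train_ds, noiseless_test_ds):
        from fermhybrid.lstm import LSTMConfig
        model = HybridResidualModel(params, [noisy_train_ds], gating)
        res = model.fit(config=LSTMConfig(units=(32, 32), learning_rate=3e-3,
                                          batch_size=16),
                        seed=0, max_epochs=40)
        pred = res.predict(noiseless_test_ds, rollout="teacher")
        assert pred.hybrid.shape == (len(noiseless_test_ds.times), 6)
        assert (pred.hybrid.to_numpy() >= 0).all()
        assert "LSTM units" in res.summary()

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            HybridWeights(lambda_pheno=-0.1)
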