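"""Residual learning and hybrid blending.

The mechanistic model's pointwise error r(t_i) = y_exp(t_i) - y_pheno(t_i)
is computed per channel, min-max scaled to [0, 1] (scaler fitted on training
residuals only), windowed with a fixed look-back of p = 5, and forecast
one step ahead by the LSTM. The machine-learning trajectory is
y_ml = y_pheno + predicted residual, and the hybrid output is the weighted
sum

    y_hybrid(t) = lambda_pheno * y_pheno(t) + lambda_ml * y_ml(t)

with default weights 0.3 / 0.7. For the first p points no window exists and
the hybrid falls back to the mechanistic prediction; this produces a visible
jump at the window boundary, an accepted artifact of the windowing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ExperimentDataset
from .kinetics import STATE_NAMES, Trajectory, simulate
from .lstm import LSTMConfig, LSTMNetwork, TrainingLog, train_lstm
from .params import GatingConfig, KineticParameters
from .tpe import SearchResult, tpe_search

LOOKBACK = 5


class ResidualScaler:
    """Feature-wise min-max transform to [0, 1].

    A degenerate channel (min = max) maps to all-zeros and inverse-transforms
    back to its constant value; non-degenerate channels round-trip exactly.
    Out-of-range inputs (e.g. test residuals larger than anything seen in
    training) transform outside [0, 1], which is allowed.
    """

    def __init__(self) -> None:
        self.mins: np.ndarray | None = None
        self.maxs: np.ndarray | None = None

    def fit(self, R: np.ndarray) -> "ResidualScaler":
        R = np.asarray(R, dtype=float)
        self.mins = R.min(axis=0)
        self.maxs = R.max(axis=0)
        return self

    @property
    def span(self) -> np.ndarray:
        span = self.maxs - self.mins
        return np.where(span > 0, span, 1.0)

    def transform(self, R: np.ndarray) -> np.ndarray:
        if self.mins is None:
            raise RuntimeError("scaler is not fitted")
        out = (np.asarray(R, dtype=float) - self.mins) / self.span
        return np.where(self.maxs > self.mins, out, 0.0)

    def inverse_transform(self, Rs: np.ndarray) -> np.ndarray:
        if self.mins is None:
            raise RuntimeError("scaler is not fitted")
        Rs = np.asarray(Rs, dtype=float)
        return np.where(self.maxs > self.mins, Rs * self.span + self.mins, self.mins)

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ResidualScaler":
        sc = cls()
        sc.mins = np.asarray(d["mins"], dtype=float)
        sc.maxs = np.asarray(d["maxs"], dtype=float)
        return sc


@dataclass
class ResidualSeries:
    """Mechanistic-model error channels at one run's sample times."""

    times: np.ndarray
    residuals: pd.DataFrame       # g/L, columns = STATE_NAMES
    trajectory: Trajectory | None = None  # the mechanistic prediction

    @property
    def matrix(self) -> np.ndarray:
        return self.residuals.to_numpy()


def compute_residuals(
    ds: ExperimentDataset,
    p: KineticParameters,
    cfg: GatingConfig = GatingConfig(),
) -> ResidualSeries:
    """Simulate the mechanistic model at the dataset's sample times and
    subtract: r(t_i) = y_exp(t_i) - y_pheno(t_i)."""
    traj = simulate(ds.initial_state, p, ds.times, cfg)
    r = ds.values.to_numpy() - traj.values()
    return ResidualSeries(
        times=ds.times,
        residuals=pd.DataFrame(r, columns=list(STATE_NAMES)),
        trajectory=traj,
    )


def make_windows(
    scaled: np.ndarray, p: int = LOOKBACK
) -> tuple[np.ndarray, np.ndarray]:
    """Look-back windows: inputs (N-p, p, m) in chronological order and
    next-step targets (N-p, m). Consecutive windows share p - 1 rows."""
    scaled = np.asarray(scaled, dtype=float)
    N = len(scaled)
    if N <= p:
        raise ValueError(
            f"series has {N} points; need at least p + 1 = {p + 1} for one window")
    inputs = np.stack([scaled[i:i + p] for i in range(N - p)])
    targets = scaled[p:]
    return inputs, targets


@dataclass(frozen=True)
class HybridWeights:
    """Blending weights of the mechanistic and machine-learning predictions."""

    lambda_pheno: float = 0.3
    lambda_ml: float = 0.7

    def __post_init__(self) -> None:
        if self.lambda_pheno < 0 or self.lambda_ml < 0:
            raise ValueError("blending weights must be non-negative")


@dataclass
class HybridPrediction:
    """Mechanistic, ML-corrected and blended trajectories at data times."""

    times: np.ndarray
    pheno: pd.DataFrame
    ml: pd.DataFrame
    hybrid: pd.DataFrame
    weights: HybridWeights
    rollout: str


def hybrid_predict(
    traj: Trajectory,
    network: LSTMNetwork,
    scaler: ResidualScaler,
    weights: HybridWeights = HybridWeights(),
    observed: ExperimentDataset | None = None,
    rollout: str = "teacher",
    p: int = LOOKBACK,
) -> HybridPrediction:
    """Blend the mechanistic trajectory with LSTM residual corrections.

    In ``teacher`` mode the look-back windows are rebuilt from measured
    residuals wherever observations exist; in ``recursive`` mode the first p
    windows use measured residuals and subsequent windows roll the model's
    own predictions forward. The first p points carry no window and fall back
    to the mechanistic prediction. Outputs are clamped at zero.
    """
    if scaler.mins is None:
        raise ValueError("missing scaler: fit it on training residuals first")
    if rollout not in ("teacher", "recursive"):
        raise ValueError("rollout must be 'teacher' or 'recursive'")
    y_pheno = traj.values()
    n = len(traj.times)
    if observed is not None:
        if len(observed.times) != n or not np.allclose(observed.times, traj.times):
            raise ValueError("observation times do not match the trajectory grid")
        meas_scaled = scaler.transform(observed.values.to_numpy() - y_pheno)
    elif rollout == "teacher":
        raise ValueError("teacher rollout requires observations")
    else:
        meas_scaled = None

    y_ml = y_pheno.copy()
    window_src = np.zeros((n, y_pheno.shape[1]))
    if meas_scaled is not None:
        window_src[:min(p, n)] = meas_scaled[:min(p, n)]
        if rollout == "teacher":
            window_src[:] = meas_scaled
    for i in range(p, n):
        pred_scaled = network.predict(window_src[i - p:i][None])[0]
        if rollout == "recursive":
            window_src[i] = pred_scaled
        resid = scaler.inverse_transform(pred_scaled[None])[0]
        y_ml[i] = y_pheno[i] + resid

    lam_p, lam_m = weights.lambda_pheno, weights.lambda_ml
    y_hybrid = lam_p * y_pheno + lam_m * y_ml
    y_hybrid[:p] = y_pheno[:p]
    y_hybrid = np.maximum(y_hybrid, 0.0)
    cols = list(STATE_NAMES)
    return HybridPrediction(
        times=traj.times,
        pheno=pd.DataFrame(y_pheno, columns=cols),
        ml=pd.DataFrame(np.maximum(y_ml, 0.0), columns=cols),
        hybrid=pd.DataFrame(y_hybrid, columns=cols),
        weights=weights,
        rollout=rollout,
    )


@dataclass
class HybridResults:
    """Fitted residual learner plus everything needed to predict."""

    network: LSTMNetwork
    scaler: ResidualScaler
    config: LSTMConfig
    mse_val: float
    weights: HybridWeights
    params: KineticParameters
    gating: GatingConfig
    search: SearchResult | None = None
    training_log: TrainingLog | None = None
    seed: int | None = None

    def predict(self, ds: ExperimentDataset, rollout: str = "teacher",
                t_grid: np.ndarray | None = None) -> HybridPrediction:
        times = ds.times if t_grid is None else t_grid
        traj = simulate(ds.initial_state, self.params, times, self.gating)
        observed = ds if rollout == "teacher" or t_grid is None else None
        return hybrid_predict(traj, self.network, self.scaler, self.weights,
                              observed=observed, rollout=rollout)

    def summary(self) -> str:
        c = self.config
        lines = [
            "Hybrid residual model",
            "=" * 40,
            f"LSTM units:            {c.units}",
            f"activation:            {c.activation}",
            f"dropout / recurrent:   {c.dropout:.3f} / {c.recurrent_dropout:.3f}",
            f"learning rate:         {c.learning_rate:.2e}",
            f"batch size:            {c.batch_size}",
            f"optimizer:             {c.optimizer}",
            f"validation MSE:        {self.mse_val:.5g}",
            f"blend weights:         pheno {self.weights.lambda_pheno}, "
            f"ml {self.weights.lambda_ml}",
        ]
        if self.search is not None:
            lines.append(f"TPE trials:            {len(self.search.trials)}")
        return "\n".join(lines)


def save_hybrid_checkpoint(path, results: "HybridResults") -> None:
    """Serialize network weights, scaler bounds, config and seed as JSON."""
    import json

    payload = {
        "config": {**results.config.__dict__,
                   "units": list(results.config.units)},
        "input_dim": results.network.input_dim,
        "weights": [w.tolist() for w in results.network.get_weights()],
        "scaler": results.scaler.to_dict(),
        "mse_val": results.mse_val,
        "weights_lambda": [results.weights.lambda_pheno,
                           results.weights.lambda_ml],
        "seed": results.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_hybrid_checkpoint(
    path,
    params: KineticParameters,
    gating: GatingConfig = GatingConfig(),
) -> HybridResults:
    """Rebuild a :class:`HybridResults` from a JSON checkpoint."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    cfg = LSTMConfig(**{**payload["config"],
                        "units": tuple(payload["config"]["units"])})
    net = LSTMNetwork(cfg, input_dim=int(payload["input_dim"]))
    net.set_weights([np.asarray(w) for w in payload["weights"]])
    lam = payload.get("weights_lambda", [0.3, 0.7])
    return HybridResults(
        network=net,
        scaler=ResidualScaler.from_dict(payload["scaler"]),
        config=cfg,
        mse_val=float(payload.get("mse_val", float("nan"))),
        weights=HybridWeights(*lam),
        params=params,
        gating=gating,
        seed=payload.get("seed"),
    )


class HybridResidualModel:
    """LSTM residual learner over a calibrated mechanistic model.

    Built from the calibrated kinetic parameters and the training datasets;
    ``fit`` runs the hyper-parameter search (or trains a fixed configuration)
    on the pooled scaled residual windows of the training runs.
    """

    def __init__(
        self,
        params: KineticParameters,
        train_datasets: list[ExperimentDataset],
        gating: GatingConfig = GatingConfig(),
        weights: HybridWeights = HybridWeights(),
        lookback: int = LOOKBACK,
    ):
        self.params = params
        self.train_datasets = list(train_datasets)
        self.gating = gating
        self.weights = weights
        self.lookback = lookback

    def _windows(self) -> tuple[ResidualScaler, np.ndarray, np.ndarray]:
        series = [compute_residuals(ds, self.params, self.gating)
                  for ds in self.train_datasets]
        scaler = ResidualScaler().fit(np.vstack([s.matrix for s in series]))
        ins, outs = [], []
        for s in series:  # windows never straddle run boundaries
            X, y = make_windows(scaler.transform(s.matrix), self.lookback)
            ins.append(X)
            outs.append(y)
        return scaler, np.concatenate(ins), np.concatenate(outs)

    def fit(
        self,
        trials: int = 100,
        seed: int = 0,
        config: LSTMConfig | None = None,
        patience: int = 15,
        max_epochs: int = 500,
    ) -> HybridResults:
        scaler, X, y = self._windows()
        train_kwargs = {"patience": patience, "max_epochs": max_epochs}
        search = None
        if config is None:
            search = tpe_search(X, y, trials=trials, rng_seed=seed,
                                train_kwargs=train_kwargs)
            config = search.best_config
        net, mse_val, log = train_lstm(X, y, config, rng_seed=seed, **train_kwargs)
        return HybridResults(
            network=net, scaler=scaler, config=config, mse_val=mse_val,
            weights=self.weights, params=self.params, gating=self.gating,
            search=search, training_log=log, seed=seed,
        )
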