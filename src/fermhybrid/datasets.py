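"""Synthetic batch-experiment generation and densification preprocessing.

The study design this module emulates: two biological replicate training runs
drawn around common nominal initial conditions, plus one independent test run
with deliberately shifted starting concentrations; offline sampling every
1.5-3 h up to ~30 h and sparser afterwards; multiplicative measurement noise
on every channel. Sparse noisy series are densified by per-variable
polynomial regression (degree chosen by adjusted R^2) onto an even grid of
10 observations per free model parameter before being handed to calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.preprocessing import PolynomialFeatures

from .kinetics import STATE_NAMES, StateVector, simulate
from .params import GatingConfig, KineticParameters

#: Nominal train-run initial conditions, mean (g/L).
TRAIN_IC_MEAN = {"biomass": 0.5, "glucose": 27.3, "fructose": 27.1,
                 "sucrose": 32.7, "urea": 2.6, "ethanol": 0.0}
#: Replicate-to-replicate SD of the train initial conditions (g/L).
TRAIN_IC_SD = {"biomass": 0.1, "glucose": 3.8, "fructose": 4.1,
               "sucrose": 3.9, "urea": 0.7, "ethanol": 0.0}
#: Shifted initial conditions of the independent test run (g/L).
TEST_IC = {"biomass": 1.2, "glucose": 27.5, "fructose": 25.8,
           "sucrose": 39.6, "urea": 2.3, "ethanol": 0.0}


@dataclass(frozen=True)
class InitialConditionSpec:
    """Means/SDs for train-like runs and fixed values for the test run."""

    train_mean: dict = field(default_factory=lambda: dict(TRAIN_IC_MEAN))
    train_sd: dict = field(default_factory=lambda: dict(TRAIN_IC_SD))
    test: dict = field(default_factory=lambda: dict(TEST_IC))
    volume: float = 0.3  # working volume, L (0.3 or 0.4 in the study design)


@dataclass(frozen=True)
class SamplingSchedule:
    """Offline sampling cadence: dense early phase, sparse after sugar depletion."""

    dense_min: float = 1.5    # h, shortest dense-phase interval
    dense_max: float = 3.0    # h, longest dense-phase interval
    dense_end: float = 30.0   # h, end of dense phase
    sparse_interval: float = 6.0  # h
    horizon: float = 48.0     # h

    def generate_times(self, rng: np.random.Generator) -> np.ndarray:
        times = [0.0]
        t = 0.0
        while True:
            t += rng.uniform(self.dense_min, self.dense_max)
            if t > min(self.dense_end, self.horizon):
                break
            times.append(t)
        t = times[-1]
        while t + self.sparse_interval <= self.horizon:
            t += self.sparse_interval
            times.append(t)
        if times[-1] < self.horizon:
            times.append(self.horizon)
        return np.asarray(times)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise, truncated at zero.

    Per-point SD is ``max(rel_sd * value, abs_floor)``; setting both to zero
    reproduces the model output exactly.
    """

    rel_sd: float = 0.05
    abs_floor: float = 0.02  # g/L

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.rel_sd == 0.0 and self.abs_floor == 0.0:
            return values.copy()
        sd = np.maximum(self.rel_sd * np.abs(values), self.abs_floor)
        noisy = values + rng.normal(0.0, 1.0, size=values.shape) * sd
        return np.maximum(noisy, 0.0)

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(rel_sd=0.0, abs_floor=0.0)


@dataclass
class ExperimentDataset:
    """Sampled (noisy) time series of one batch run.

    ``values`` is a DataFrame with the six concentration columns in canonical
    order; ``true_params`` records the generating parameter set so recovery
    tests can compare against the known truth.
    """

    role: str                      # "train" or "test"
    times: np.ndarray              # h
    values: pd.DataFrame           # g/L, columns = STATE_NAMES
    volume: float = 0.3            # L
    true_params: KineticParameters | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ("train", "test"):
            raise ValueError("role must be 'train' or 'test'")
        if list(self.values.columns) != list(STATE_NAMES):
            raise ValueError(f"value columns must be {STATE_NAMES}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("measured values must be non-negative")

    @property
    def initial_state(self) -> StateVector:
        row = self.values.iloc[0]
        return StateVector(
            X=row["biomass"], G=row["glucose"], R=row["fructose"],
            S=row["sucrose"], U=row["urea"], Et=row["ethanol"], V=self.volume,
        )

    def to_csv(self, path) -> None:
        path = Path(path)
        df = self.values.copy()
        df.insert(0, "time_h", self.times)
        df["volume"] = self.volume
        df.to_csv(path, index=False)
        meta = {"role": self.role, "seed": self.seed, "volume": self.volume}
        if self.true_params is not None:
            meta["true_params"] = self.true_params.to_dict()
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path, role: str | None = None) -> "ExperimentDataset":
        path = Path(path)
        df = pd.read_csv(path)
        meta = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        true_params = (
            KineticParameters.from_dict(meta["true_params"])
            if "true_params" in meta else None
        )
        volume = meta.get("volume", df["volume"].iloc[0] if "volume" in df else 0.3)
        return cls(
            role=role or meta.get("role", "train"),
            times=df["time_h"].to_numpy(),
            values=df[list(STATE_NAMES)].reset_index(drop=True),
            volume=float(volume),
            true_params=true_params,
            seed=meta.get("seed"),
        )


@dataclass
class DensifiedDataset:
    """Polynomial-regression densification of a sparse dataset.

    Grid length is 10 x (number of free parameters); negative fitted values
    are clamped to zero.
    """

    role: str
    times: np.ndarray
    values: pd.DataFrame
    degrees: dict
    r_squared: dict
    volume: float = 0.3
    source: ExperimentDataset | None = None

    @property
    def initial_state(self) -> StateVector:
        row = self.values.iloc[0]
        return StateVector(
            X=row["biomass"], G=row["glucose"], R=row["fructose"],
            S=row["sucrose"], U=row["urea"], Et=row["ethanol"], V=self.volume,
        )

    def to_csv(self, path) -> None:
        df = self.values.copy()
        df.insert(0, "time_h", self.times)
        df.to_csv(path, index=False)


def draw_initial_conditions(
    spec: InitialConditionSpec, role: str, rng_seed: int | np.random.Generator
) -> StateVector:
    """Sample a run's initial state: Normal(mean, SD) truncated at 0 for
    train-like runs, the fixed shifted values for the test run; ethanol 0."""
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    if role == "test":
        v = spec.test
        return StateVector(X=v["biomass"], G=v["glucose"], R=v["fructose"],
                           S=v["sucrose"], U=v["urea"], Et=0.0, V=spec.volume)
    draws = {}
    for name in STATE_NAMES:
        mean, sd = spec.train_mean[name], spec.train_sd[name]
        draws[name] = max(0.0, rng.normal(mean, sd)) if sd > 0 else mean
    return StateVector(X=draws["biomass"], G=draws["glucose"], R=draws["fructose"],
                       S=draws["sucrose"], U=draws["urea"], Et=0.0, V=spec.volume)


def generate_experiment(
    p: KineticParameters,
    ic: StateVector,
    sched: SamplingSchedule = SamplingSchedule(),
    noise: NoiseModel = NoiseModel(),
    rng_seed: int = 0,
    role: str = "train",
    cfg: GatingConfig = GatingConfig(),
    times: np.ndarray | None = None,
    **rate_options,
) -> ExperimentDataset:
    """Simulate the kinetic model at schedule times and apply measurement noise.

    Deterministic given ``rng_seed``. An explicit ``times`` grid overrides
    the randomized schedule.
    """
    rng = np.random.default_rng(rng_seed)
    t = np.asarray(times, dtype=float) if times is not None else sched.generate_times(rng)
    traj = simulate(ic, p, t, cfg, **rate_options)
    clean = traj.values()
    noisy = noise.apply(clean, rng)
    noisy[0] = clean[0]  # the initial condition is prepared, not measured
    return ExperimentDataset(
        role=role,
        times=t,
        values=pd.DataFrame(noisy, columns=list(STATE_NAMES)),
        volume=ic.V,
        true_params=p,
        seed=rng_seed,
    )


def _fit_best_polynomial(t_std, y, max_degree):
    """Degree-selection by adjusted R^2 over degrees 2..max_degree."""
    n = len(y)
    if np.ptp(y) < 1e-12:
        return None, 0, 1.0  # constant channel: degree-0 fit, R^2 := 1
    best = None
    for deg in range(2, max_degree + 1):
        if n < deg + 2:  # need at least one residual dof
            break
        feats = PolynomialFeatures(degree=deg, include_bias=False)
        Xd = feats.fit_transform(t_std[:, None])
        reg = LinearRegression().fit(Xd, y)
        r2 = reg.score(Xd, y)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - deg - 1)
        if best is None or adj > best[3] + 1e-12:
            best = (reg, deg, r2, adj, feats)
    reg, deg, r2, _, feats = best
    return (reg, feats), deg, r2


def densify(
    ds: ExperimentDataset, n_free_params: int, max_degree: int = 6
) -> DensifiedDataset:
    """Fit per-variable polynomials and evaluate on an even grid.

    Grid has ``10 * n_free_params`` points over [0, max sample time]. Degree
    is selected among 2..max_degree by adjusted R^2 (capped when there are
    fewer points than degree + 1); negative fits are clamped to 0.
    """
    if len(ds.times) < 6:
        raise ValueError("densification needs at least 6 sample points")
    if n_free_params < 1:
        raise ValueError("n_free_params must be >= 1")
    t = ds.times
    mu, sd = t.mean(), t.std()
    t_std = (t - mu) / sd
    grid = np.linspace(0.0, t.max(), 10 * n_free_params)
    grid_std = (grid - mu) / sd

    fitted = {}
    degrees = {}
    r2s = {}
    for name in STATE_NAMES:
        y = ds.values[name].to_numpy()
        model, deg, r2 = _fit_best_polynomial(t_std, y, max_degree)
        if model is None:  # constant channel
            fitted[name] = np.full_like(grid, y[0])
        else:
            reg, feats = model
            fitted[name] = reg.predict(feats.transform(grid_std[:, None]))
        degrees[name] = deg
        r2s[name] = float(r2)
    values = pd.DataFrame(fitted, columns=list(STATE_NAMES)).clip(lower=0.0)
    return DensifiedDataset(
        role=ds.role, times=grid, values=values, degrees=degrees,
        r_squared=r2s, volume=ds.volume, source=ds,
    )
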