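"""Model/Results front end for the mechanistic fermentation model.

``BatchFermentationModel`` wraps one or more batch datasets and the fitting
machinery; ``fit`` runs the global calibration and returns a
``FermentationResults`` carrying the estimates, the identifiability report,
Monte Carlo uncertainty, simulation and a text ``summary`` in the style of
statistical modeling packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationResult,
    ObjectiveConfig,
    ParameterBounds,
    iterative_bound_refinement,
    make_objective,
    objective,
)
from .datasets import DensifiedDataset, ExperimentDataset, densify
from .evaluation import RMSETable
from .identifiability import (
    PRAReport,
    UncertaintyBands,
    monte_carlo_bands,
    sequential_fixing,
)
from .kinetics import StateVector, Trajectory, simulate
from .params import (
    GatingConfig,
    KineticParameters,
    LITERATURE_BOUNDS,
    PARAM_NAMES,
)


class BatchFermentationModel:
    """Mechanistic six-state fermentation model bound to batch datasets.

    Parameters
    ----------
    datasets
        Training datasets (sparse experiments or densified regressions).
    params0
        Starting parameter vector; defaults to the literature initial
        guesses.
    free_names
        Subset of parameters to estimate (all 22 by default).
    densify_data
        When True, sparse experiment datasets are densified to
        10 x n_free points before fitting.
    """

    def __init__(
        self,
        datasets: list[ExperimentDataset | DensifiedDataset],
        params0: KineticParameters | None = None,
        free_names=PARAM_NAMES,
        gating: GatingConfig = GatingConfig(),
        objective_config: ObjectiveConfig = ObjectiveConfig(),
        densify_data: bool = False,
        **rate_options,
    ):
        self.raw_datasets = list(datasets)
        self.free_names = tuple(free_names)
        if densify_data:
            self.datasets = [
                densify(ds, len(self.free_names))
                if isinstance(ds, ExperimentDataset) else ds
                for ds in self.raw_datasets
            ]
        else:
            self.datasets = list(self.raw_datasets)
        self.params0 = params0 or KineticParameters.initial_guesses()
        self.gating = gating
        self.objective_config = objective_config
        self.rate_options = rate_options

    @classmethod
    def from_csv(cls, paths, **kwargs) -> "BatchFermentationModel":
        return cls([ExperimentDataset.from_csv(p) for p in paths], **kwargs)

    def objective(self, params: KineticParameters) -> float:
        return objective(params, self.datasets, self.objective_config,
                         self.gating, **self.rate_options)

    def fit(
        self,
        pop: int = 30,
        total_epochs: int = 160,
        round_epochs: int = 20,
        seed: int = 0,
        initial_rel_bounds: float = 0.30,
        bounds: ParameterBounds | None = None,
        literature_bounds: ParameterBounds | None = None,
    ) -> "FermentationResults":
        """Grey-wolf calibration with iterative bound recalibration."""
        f = make_objective(self.datasets, self.free_names, self.params0,
                           self.objective_config, self.gating,
                           **self.rate_options)
        init = bounds or ParameterBounds.around(
            self.params0, initial_rel_bounds, self.free_names)
        lit = literature_bounds or ParameterBounds(
            {n: LITERATURE_BOUNDS[n] for n in self.free_names})
        theta0 = np.array([getattr(self.params0, n) for n in self.free_names])
        calib = iterative_bound_refinement(
            f, init, lit, self.free_names,
            round_epochs=round_epochs, total_epochs=total_epochs,
            pop=pop, rng_seed=seed, theta0=theta0,
        )
        return FermentationResults(self, calib)

    def simulate(self, ic: StateVector, t_grid,
                 params: KineticParameters | None = None) -> Trajectory:
        return simulate(ic, params or self.params0, t_grid, self.gating,
                        **self.rate_options)


@dataclass
class FermentationResults:
    """Calibrated parameter estimates with diagnostics."""

    model: BatchFermentationModel
    calibration: CalibrationResult
    _pra: PRAReport | None = None

    @property
    def params(self) -> KineticParameters:
        return self.calibration.params

    @property
    def objective_value(self) -> float:
        return self.calibration.objective_value

    def pra(self, recompute: bool = False) -> PRAReport:
        """Identifiability report (sequential fixing not applied)."""
        if self._pra is None or recompute:
            from .identifiability import _pra_for_free_set
            self._pra = _pra_for_free_set(
                self.model.datasets, self.params,
                self.calibration.free_names, self.model.gating)
        return self._pra

    def fix_and_refit(self, pop: int = 30, total_epochs: int = 160,
                      seed: int = 0):
        """Sequential PRA fixing followed by re-calibration of the free set."""
        free, fixed, report = sequential_fixing(
            self.model.datasets, self.params,
            self.calibration.free_names, self.model.gating)
        refit_model = BatchFermentationModel(
            self.model.datasets, params0=self.params, free_names=free,
            gating=self.model.gating,
            objective_config=self.model.objective_config,
            **self.model.rate_options)
        res = refit_model.fit(pop=pop, total_epochs=total_epochs, seed=seed)
        return res, fixed, report

    def monte_carlo(self, ic: StateVector, t_grid, rel_sd: float = 0.05,
                    N: int = 100, seed: int = 0) -> UncertaintyBands:
        return monte_carlo_bands(self.params, ic, t_grid, rel_sd=rel_sd,
                                 N=N, rng_seed=seed, cfg=self.model.gating)

    def predict(self, ic: StateVector, t_grid) -> Trajectory:
        return self.model.simulate(ic, t_grid, self.params)

    def rmse_table(self, datasets_by_role: dict[str, list[ExperimentDataset]]
                   ) -> RMSETable:
        table = RMSETable()
        for role, dss in datasets_by_role.items():
            preds = [self.predict(ds.initial_state, ds.times).values()
                     for ds in dss]
            table.add("mechanistic", role, preds, dss)
        return table

    def summary(self) -> str:
        lines = [
            "Batch fermentation model — grey wolf calibration",
            "=" * 56,
            f"datasets:        {len(self.model.datasets)}",
            f"free parameters: {len(self.calibration.free_names)} of {len(PARAM_NAMES)}",
            f"epochs run:      {self.calibration.epochs_run}"
            f"  (evaluations: {self.calibration.n_evaluations})",
            f"objective J:     {self.objective_value:.6g}",
            f"bound recalibrations: {len(self.calibration.bound_history)}",
            "",
        ]
        rows = []
        for name in self.calibration.free_names:
            rows.append({"parameter": name,
                         "start": getattr(self.model.params0, name),
                         "estimate": getattr(self.params, name)})
        df = pd.DataFrame(rows).set_index("parameter")
        lines.append(df.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)
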