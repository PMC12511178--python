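"""Prediction-error metrics: per-variable RMSE, totals and fold reductions.

The "Total" of a six-variable RMSE row is the arithmetic mean of the
per-variable values (a pooled-RMSE alternative is available behind a flag).
RMSEs are conventionally reported at two decimals and fold ratios at one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExperimentDataset
from .kinetics import STATE_NAMES


def rmse(pred: np.ndarray, obs: ExperimentDataset, variable: str,
         times: np.ndarray | None = None) -> float:
    """Root-mean-square error of one variable at the observation times."""
    if variable not in STATE_NAMES:
        raise ValueError(f"unknown variable {variable!r}")
    pred = np.asarray(pred, dtype=float)
    if times is None:
        if len(pred) != len(obs.times):
            raise ValueError("prediction and observation times do not overlap")
    else:
        mask = np.isin(np.round(times, 9), np.round(obs.times, 9))
        if not mask.any():
            raise ValueError("prediction and observation times do not overlap")
        pred = pred[mask]
    k = STATE_NAMES.index(variable)
    col = pred[:, k] if pred.ndim == 2 else pred
    diff = col - obs.values[variable].to_numpy()
    return float(np.sqrt(np.mean(diff**2)))


def total_rmse(per_variable, pooled: bool = False) -> float:
    """Aggregate six per-variable RMSEs; arithmetic mean by default."""
    vals = np.asarray(list(per_variable), dtype=float)
    if vals.shape != (6,):
        raise ValueError("total_rmse needs exactly the six per-variable RMSEs")
    if pooled:
        return float(np.sqrt(np.mean(vals**2)))
    return float(np.mean(vals))


def fold_reduction(total_mech: float, total_hybrid: float) -> float:
    """Error-reduction ratio mechanistic / hybrid, reported at one decimal."""
    if total_hybrid <= 0:
        raise ValueError("hybrid total RMSE must be positive")
    return round(total_mech / total_hybrid, 1)


@dataclass
class RMSETable:
    """Per-variable and total RMSEs for each model x role combination."""

    rows: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def add(self, model: str, role: str, pred: np.ndarray,
            obs_list: list[ExperimentDataset]) -> None:
        """Pool one or more runs of the same role (squared errors pooled
        across runs per variable before the root)."""
        preds = pred if isinstance(pred, list) else [pred]
        per_var = {}
        for name in STATE_NAMES:
            k = STATE_NAMES.index(name)
            sq = []
            for pr, obs in zip(preds, obs_list):
                diff = np.asarray(pr)[:, k] - obs.values[name].to_numpy()
                sq.append(diff**2)
            per_var[name] = float(np.sqrt(np.mean(np.concatenate(sq))))
        per_var["Total"] = total_rmse([per_var[n] for n in STATE_NAMES])
        self.rows[(model, role)] = per_var

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.rows.keys(), names=["model", "role"])
        return pd.DataFrame(list(self.rows.values()), index=idx)

    def fold_reductions(self) -> dict[str, float]:
        out = {}
        for role in {r for _, r in self.rows}:
            mech = self.rows.get(("mechanistic", role))
            hyb = self.rows.get(("hybrid", role))
            if mech and hyb:
                out[role] = fold_reduction(mech["Total"], hyb["Total"])
        return out

    def summary(self) -> str:
        df = self.to_frame().round(2)
        lines = [df.to_string()]
        folds = self.fold_reductions()
        for role, f in sorted(folds.items()):
            lines.append(f"fold reduction ({role}): {f:.1f}x")
        return "\n".join(lines)
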