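"""Tree-structured Parzen estimator search over the LSTM hyper-parameter space.

Observed trials are split into a "good" fraction (lowest validation losses)
and the rest; each dimension is modeled independently with a kernel density
(continuous) or smoothed counts (categorical). New candidates are drawn from
the good-density model and scored by the density ratio l(x)/g(x); the best
candidate is evaluated. The first few trials sample the prior at random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import gaussian_kde

from .lstm import (
    ACTIVATION_CHOICES,
    BATCH_CHOICES,
    LSTMConfig,
    OPTIMIZER_CHOICES,
    UNIT_CHOICES,
    train_lstm,
)

logger = logging.getLogger(__name__)

#: Search-space descriptors: (kind, domain). "log-uniform" is sampled in
#: log10 space.
SEARCH_SPACE: dict[str, tuple[str, tuple]] = {
    "units_1": ("categorical", UNIT_CHOICES),
    "units_2": ("categorical", UNIT_CHOICES),
    "activation": ("categorical", ACTIVATION_CHOICES),
    "leaky_alpha": ("uniform", (0.01, 0.3)),
    "dropout": ("uniform", (0.0, 0.5)),
    "recurrent_dropout": ("uniform", (0.0, 0.5)),
    "learning_rate": ("log-uniform", (1e-5, 1e-2)),
    "batch_size": ("categorical", BATCH_CHOICES),
    "optimizer": ("categorical", OPTIMIZER_CHOICES),
}


@dataclass
class Trial:
    number: int
    config: LSTMConfig
    raw: dict
    loss: float
    error: str | None = None


@dataclass
class SearchResult:
    best_config: LSTMConfig
    best_loss: float
    trials: list[Trial] = field(default_factory=list)


def _sample_prior(rng: np.random.Generator) -> dict:
    raw = {}
    for name, (kind, domain) in SEARCH_SPACE.items():
        if kind == "categorical":
            raw[name] = domain[rng.integers(len(domain))]
        elif kind == "uniform":
            raw[name] = float(rng.uniform(*domain))
        else:  # log-uniform
            lo, hi = np.log10(domain[0]), np.log10(domain[1])
            raw[name] = float(10 ** rng.uniform(lo, hi))
    return raw


def _tpe_propose(history: list[Trial], rng: np.random.Generator,
                 gamma: float = 0.25, n_candidates: int = 24) -> dict:
    ok = [t for t in history if t.error is None]
    losses = np.array([t.loss for t in ok])
    n_good = max(1, int(np.ceil(gamma * len(ok))))
    order = np.argsort(losses)
    good = [ok[i] for i in order[:n_good]]
    bad = [ok[i] for i in order[n_good:]]

    raw = {}
    for name, (kind, domain) in SEARCH_SPACE.items():
        g_vals = [t.raw[name] for t in good]
        b_vals = [t.raw[name] for t in bad]
        if kind == "categorical":
            def probs(vals):
                counts = np.array([sum(v == d for v in vals) for d in domain],
                                  dtype=float) + 1.0
                return counts / counts.sum()
            pg, pb = probs(g_vals), probs(b_vals)
            cand = rng.choice(len(domain), size=n_candidates, p=pg)
            scores = pg[cand] / pb[cand]
            raw[name] = domain[int(cand[int(np.argmax(scores))])]
        else:
            lo, hi = domain
            to_x = (lambda v: np.log10(v)) if kind == "log-uniform" else (lambda v: v)
            to_v = (lambda x: float(10 ** x)) if kind == "log-uniform" else float
            xlo, xhi = to_x(lo), to_x(hi)

            def density(vals):
                xs = np.array([to_x(v) for v in vals])
                if len(np.unique(xs)) < 2:
                    return None
                try:
                    return gaussian_kde(xs)
                except np.linalg.LinAlgError:
                    return None
            kg, kb = density(g_vals), density(b_vals)
            if kg is None:
                raw[name] = to_v(float(rng.uniform(xlo, xhi)))
                continue
            cand = np.clip(kg.resample(n_candidates, seed=rng)[0], xlo, xhi)
            lg = kg(cand)
            lb = kb(cand) if kb is not None else np.full_like(lg, 1.0 / (xhi - xlo))
            lb = np.maximum(lb, 1e-12)
            raw[name] = to_v(float(cand[int(np.argmax(lg / lb))]))
    return raw


def _raw_to_config(raw: dict, output_dim: int) -> LSTMConfig:
    return LSTMConfig(
        units=(int(raw["units_1"]), int(raw["units_2"])),
        activation=str(raw["activation"]),
        leaky_alpha=float(raw["leaky_alpha"]),
        dropout=float(raw["dropout"]),
        recurrent_dropout=float(raw["recurrent_dropout"]),
        learning_rate=float(raw["learning_rate"]),
        batch_size=int(raw["batch_size"]),
        optimizer=str(raw["optimizer"]),
        output_dim=output_dim,
    )


def tpe_search(
    inputs: np.ndarray,
    targets: np.ndarray,
    trials: int = 100,
    rng_seed: int = 0,
    n_startup: int = 10,
    objective: Callable[[LSTMConfig, int], float] | None = None,
    train_kwargs: dict | None = None,
) -> SearchResult:
    """Minimize the LSTM validation MSE over the hyper-parameter space.

    Each trial trains a network on the windowed residuals with its sampled
    configuration and records the validation loss; the returned result holds
    the best configuration and the full trial log. Reproducible per seed.
    ``objective`` may replace the default training call (used in tests).
    """
    if trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(rng_seed)
    train_kwargs = train_kwargs or {}
    out_dim = targets.shape[1]

    def default_objective(cfg: LSTMConfig, seed: int) -> float:
        _, val, _ = train_lstm(inputs, targets, cfg, rng_seed=seed, **train_kwargs)
        return val

    evaluate = objective or default_objective
    history: list[Trial] = []
    for k in range(trials):
        usable = [t for t in history if t.error is None]
        if k < n_startup or len(usable) < 4:
            raw = _sample_prior(rng)
        else:
            raw = _tpe_propose(history, rng)
        cfg = _raw_to_config(raw, out_dim)
        try:
            loss = float(evaluate(cfg, int(rng.integers(2**31 - 1))))
            history.append(Trial(k, cfg, raw, loss))
            logger.info("trial %d: loss %.5g (%s)", k, loss, raw)
        except Exception as exc:  # noqa: BLE001 - trial-level isolation
            history.append(Trial(k, cfg, raw, np.inf, error=str(exc)))
            logger.warning("trial %d failed: %s", k, exc)
    ok = [t for t in history if t.error is None]
    if not ok:
        diag = "; ".join(f"trial {t.number}: {t.error}" for t in history)
        raise RuntimeError(f"all hyper-parameter trials failed ({diag})")
    best = min(ok, key=lambda t: t.loss)
    return SearchResult(best_config=best.config, best_loss=best.loss,
                        trials=history)
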