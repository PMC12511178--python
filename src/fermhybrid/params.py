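"""Kinetic parameter set, gating configuration, and shipped default values.

The mechanistic model carries 22 kinetic parameters: maximum specific growth
rates on glucose, fructose (pre- and post-repression) and ethanol; maintenance
coefficients; the sucrose hydrolysis capacity; Monod half-saturation and
inhibition constants; and yield coefficients. Defaults below are the
calibrated estimates of the source study's batch runs, together with the
literature-derived bounds and the literature initial guesses used to seed
calibration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import yaml

#: Canonical parameter ordering used by every array-facing routine.
PARAM_NAMES: tuple[str, ...] = (
    "mu_max_Et",    # max specific growth rate on ethanol, g/(g h)
    "mu_max_G",     # max specific growth rate on glucose, g/(g h)
    "mu_max_R",     # max specific growth rate on fructose (glucose present), g/(g h)
    "mu_max_postG", # max specific growth rate on fructose after glucose depletion, g/(g h)
    "m_G",          # glucose maintenance coefficient, g/(g h)
    "m_R",          # fructose maintenance coefficient, g/(g h)
    "alpha_S",      # max specific sucrose uptake (invertase hydrolysis), g/(g h)
    "K_inh_AF",     # fermentable-sugar inhibition constant on ethanol uptake, g/L
    "K_Et",         # ethanol half-saturation for ethanol growth, g/L
    "K_i_Et",       # ethanol inhibition constant on sugar growth, g/L
    "K_G",          # glucose half-saturation, g/L
    "K_R",          # fructose half-saturation (glucose present), g/L
    "K_R_postG",    # fructose half-saturation after glucose depletion, g/L
    "K_S",          # sucrose half-saturation, g/L
    "Y_AF_S",       # g monosaccharide produced per g sucrose hydrolyzed
    "Y_Et_G",       # g ethanol per g glucose, g/g
    "Y_Et_R",       # g ethanol per g fructose, g/g
    "Y_Et_X",       # g ethanol per g biomass (production), g/g
    "Y_cEt_X",      # g ethanol per g biomass (consumption), g/g
    "Y_G_X",        # g glucose per g biomass, g/g
    "Y_R_X",        # g fructose per g biomass, g/g
    "Y_X_Ur",       # g biomass per g urea, g/g
)

#: Calibrated estimates shipped as the model default.
DEFAULT_ESTIMATES: dict[str, float] = {
    "mu_max_Et": 0.007,
    "mu_max_G": 0.149,
    "mu_max_R": 0.011,
    "mu_max_postG": 0.047,
    "m_G": 0.037,
    "m_R": 0.128,
    "alpha_S": 7.645,
    "K_inh_AF": 0.203,
    "K_Et": 0.092,
    "K_i_Et": 7.920,
    "K_G": 0.035,
    "K_R": 1.666,
    "K_R_postG": 6.768e-09,
    "K_S": 29.935,
    "Y_AF_S": 0.520,
    "Y_Et_G": 0.451,
    "Y_Et_R": 0.740,
    "Y_Et_X": 3.126,
    "Y_cEt_X": 10.907,
    "Y_G_X": 5.417,
    "Y_R_X": 7.488,
    "Y_X_Ur": 2.794,
}

#: Literature initial guesses used to seed calibration.
INITIAL_GUESSES: dict[str, float] = {
    "mu_max_Et": 0.090,
    "mu_max_G": 0.098,
    "mu_max_R": 0.096,
    "mu_max_postG": 0.265,
    "m_G": 0.047,
    "m_R": 0.057,
    "alpha_S": 11.815,
    "K_inh_AF": 0.186,
    "K_Et": 0.108,
    "K_i_Et": 12.836,
    "K_G": 0.057,
    "K_R": 10.548,
    "K_R_postG": 0.001,
    "K_S": 38.983,
    "Y_AF_S": 0.563,
    "Y_Et_G": 0.891,
    "Y_Et_R": 0.900,
    "Y_Et_X": 5.409,
    "Y_cEt_X": 5.603,
    "Y_G_X": 5.000,
    "Y_R_X": 3.000,
    "Y_X_Ur": 3.590,
}

#: Literature-based (lower, upper) bounds per parameter.
LITERATURE_BOUNDS: dict[str, tuple[float, float]] = {
    "mu_max_Et": (0.1, 0.3),
    "mu_max_G": (0.1, 0.5),
    "mu_max_R": (0.05, 0.5),
    "mu_max_postG": (0.04, 1.5),
    "m_G": (0.01, 0.09),
    "m_R": (0.01, 0.09),
    "alpha_S": (4.0, 30.0),
    "K_inh_AF": (0.01, 0.2),
    "K_Et": (0.01, 0.15),
    "K_i_Et": (15.0, 30.0),
    "K_G": (0.001, 0.5),
    "K_R": (0.001, 0.5),
    "K_R_postG": (0.0, 0.5),
    "K_S": (0.1, 20.0),
    "Y_AF_S": (0.4, 0.6),
    "Y_Et_G": (0.3, 0.8),
    "Y_Et_R": (0.3, 0.8),
    "Y_Et_X": (10.0, 20.0),
    "Y_cEt_X": (5.0, 50.0),
    "Y_G_X": (10.0, 50.0),
    "Y_R_X": (10.0, 50.0),
    "Y_X_Ur": (3.0, 5.0),
}

#: Parameters classified significant (t > 2) in the reference calibration;
#: the complement was fixed by the identifiability screening.
SIGNIFICANT_PARAMS: tuple[str, ...] = (
    "mu_max_Et",
    "mu_max_G",
    "m_R",
    "alpha_S",
    "K_inh_AF",
    "K_i_Et",
    "K_G",
    "K_S",
    "Y_AF_S",
    "Y_Et_G",
    "Y_Et_R",
    "Y_Et_X",
    "Y_cEt_X",
    "Y_X_Ur",
)


@dataclass(frozen=True)
class GatingConfig:
    """Settings of the normalized leaky-ReLU depletion/appearance gates.

    ``gamma`` is the leak slope of the leaky ReLU, ``epsilon`` the smoothing
    constant (units (g/L)^2) of the normalizing square root, and ``threshold``
    the concentration (g/L) at which a rate is considered switched off.
    epsilon must be far below threshold^2 so the gate saturates to ~1 away
    from the threshold.
    """

    gamma: float = 0.01
    epsilon: float = 1e-6
    threshold: float = 0.001

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")
        if self.epsilon <= 0.0:
            raise ValueError("epsilon must be positive")
        if self.threshold < 0.0:
            raise ValueError("threshold must be non-negative")


@dataclass
class KineticParameters:
    """The 22 kinetic parameters of the batch fermentation model.

    Field order matches :data:`PARAM_NAMES`. All values must be positive
    (``K_R_postG`` may be arbitrarily small but not negative).
    """

    mu_max_Et: float
    mu_max_G: float
    mu_max_R: float
    mu_max_postG: float
    m_G: float
    m_R: float
    alpha_S: float
    K_inh_AF: float
    K_Et: float
    K_i_Et: float
    K_G: float
    K_R: float
    K_R_postG: float
    K_S: float
    Y_AF_S: float
    Y_Et_G: float
    Y_Et_R: float
    Y_Et_X: float
    Y_cEt_X: float
    Y_G_X: float
    Y_R_X: float
    Y_X_Ur: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0.0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {v}")

    @classmethod
    def defaults(cls) -> "KineticParameters":
        return cls(**DEFAULT_ESTIMATES)

    @classmethod
    def initial_guesses(cls) -> "KineticParameters":
        return cls(**INITIAL_GUESSES)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "KineticParameters":
        values = list(values)
        if len(values) != len(PARAM_NAMES):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {len(values)}")
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "KineticParameters":
        return cls(**{k: float(mapping[k]) for k in PARAM_NAMES})

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    def replace(self, **updates: float) -> "KineticParameters":
        return dataclasses.replace(self, **updates)


def load_params_yaml(path) -> tuple[KineticParameters, GatingConfig]:
    """Read a YAML file holding ``parameters:`` and optional ``gating:`` blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    params = KineticParameters.from_dict(raw["parameters"])
    gating = GatingConfig(**raw.get("gating", {}))
    return params, gating


def save_params_yaml(path, params: KineticParameters, gating: GatingConfig = GatingConfig()) -> None:
    payload = {
        "parameters": params.to_dict(),
        "gating": {
            "gamma": gating.gamma,
            "epsilon": gating.epsilon,
            "threshold": gating.threshold,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
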