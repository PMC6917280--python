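"""Parametric transition hazards of the illness-death model.

The model has three states — Healthy, Ill, Dead — and three transitions:

* ``incidence_rate``  λ(a, Z): Healthy → Ill,
* ``mortality_free``  μ0(a, Z): Healthy → Dead,
* ``mortality_ill``   μ1(a, Z) = HR · μ0(a, Z): Ill → Dead,

all depending on age ``a`` (years) and a scalar risk factor ``Z`` (here BMI,
kg/m²).  The incidence is exponential-parabolic in age and log-linear in the
risk factor; disease-free mortality follows a Gompertz–Makeham law with a
j-shaped risk-factor term ``exp(ξ·|Z − z0|)`` that is minimal at the reference
value ``z0`` and penalises both under- and overweight.  Excess mortality of
the diseased is a constant hazard ratio ``hr``.

Hazards are pure functions of continuous age and an unrestricted real ``Z``;
the support restriction of the risk factor lives in
:mod:`idmrisk.risk_distribution`, not here.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields, replace

import numpy as np
from numpy.typing import ArrayLike

__all__ = [
    "RateParameters",
    "incidence_rate",
    "mortality_free",
    "mortality_ill",
]


@dataclass(frozen=True)
class RateParameters:
    """The nine hazard coefficients plus reference BMI and hazard ratio.

    Defaults parameterise age-specific type-2-diabetes incidence and German
    all-cause mortality for a male birth cohort.

    Parameters
    ----------
    epsilon : float
        Incidence scale (1/year); must be positive.
    alpha, beta, gamma : float
        Quadratic (1/year²), linear (1/year) and intercept coefficients of
        the exponential-parabolic age dependence of incidence.
    delta : float
        Log-linear incidence effect per BMI unit.
    xi : float
        Mortality effect per BMI unit of distance from ``z0`` (j-shape).
    theta, nu : float
        Gompertz–Makeham intercept and age slope (1/year) of disease-free
        mortality.
    z0 : float
        Reference BMI (kg/m²) at which disease-free mortality is minimal.
    hr : float
        Hazard ratio of diseased vs disease-free mortality; ``hr >= 1``.
    """

    epsilon: float = 0.014
    alpha: float = -0.001
    beta: float = 0.209
    gamma: float = -11.112
    delta: float = 0.1
    xi: float = 0.02
    theta: float = -10.948
    nu: float = 0.095
    z0: float = 23.75
    hr: float = 2.0

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if not self.hr >= 1:
            raise ValueError(f"hr must be >= 1, got {self.hr}")
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v}")

    def to_dict(self) -> dict[str, float]:
        """Flat mapping keyed by the conventional symbol names."""
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "RateParameters":
        """Build from a flat mapping; unknown keys are an error."""
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown rate parameter key(s): {sorted(unknown)}")
        return cls(**mapping)

    def replace(self, **changes: float) -> "RateParameters":
        return replace(self, **changes)


def _validated_age(age: ArrayLike) -> np.ndarray:
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be non-negative")
    return a


def incidence_rate(params: RateParameters, age: ArrayLike, z: ArrayLike) -> np.ndarray:
    """Hazard of disease onset λ(a, Z) = ε·exp(α·a² + β·a + γ + δ·Z), 1/year.

    Vectorised over ``age`` and ``z`` (numpy broadcasting).  Strictly
    positive; raises ``ValueError`` for negative ages.
    """
    a = _validated_age(age)
    z = np.asarray(z, dtype=float)
    return params.epsilon * np.exp(
        params.alpha * a**2 + params.beta * a + params.gamma + params.delta * z
    )


def mortality_free(params: RateParameters, age: ArrayLike, z: ArrayLike) -> np.ndarray:
    """Disease-free mortality μ0(a, Z) = exp(ξ·|Z − z0| + ϑ + ν·a), 1/year.

    Gompertz–Makeham in age; for fixed age, minimal at ``Z = z0`` and
    increasing in ``|Z − z0|`` (j-shaped BMI dependence).
    """
    a = _validated_age(age)
    z = np.asarray(z, dtype=float)
    return np.exp(params.xi * np.abs(z - params.z0) + params.theta + params.nu * a)


def mortality_ill(params: RateParameters, age: ArrayLike, z: ArrayLike) -> np.ndarray:
    """Mortality of the diseased μ1(a, Z) = hr · μ0(a, Z), 1/year."""
    return params.hr * mortality_free(params, age, z)
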