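"""Population-level statistical structure shared by the simulator and the fitter.

Individual parameters are log-normally distributed around population typical
values: phi_i = exp(mu + lambda_i) with lambda_i ~ N(0, Omega).  Residual
error is a combined additive + proportional normal model,
y = f + (a + b*f) * e with e ~ N(0, sigma^2); sigma is fixed to 1 by default
so its scale is absorbed into (a, b), removing the a*sigma / b*sigma
indeterminacy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .structural import StructuralModel, get_model

__all__ = ["ErrorParams", "PopulationSpec"]


@dataclass(frozen=True)
class ErrorParams:
    """Residual-error model y = f + (a + b*f) e, e ~ N(0, sigma^2)."""

    a: float = 20.0  # additive scale, mm^3
    b: float = 0.1  # proportional scale, dimensionless
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ConfigurationError("error scales a, b must be >= 0")
        if self.a == 0 and self.b == 0:
            raise ConfigurationError("a and b cannot both be 0")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")

    def sd(self, f):
        """Residual standard deviation at predicted volume(s) ``f``."""
        return (self.a + self.b * np.clip(np.asarray(f, dtype=float), 0.0, None)) * self.sigma


@dataclass
class PopulationSpec:
    """Fixed effects, random-effect covariance and error model for one structural model.

    ``mu`` and ``omega`` are keyed by the model's parameter names; ``mu`` is on
    the log (transformed) scale and ``omega`` holds the random-effect standard
    deviations (square roots of the diagonal of Omega).  An omitted omega entry
    means no inter-individual variability for that parameter.
    """

    model_id: str
    mu: dict[str, float]
    omega: dict[str, float] = field(default_factory=dict)
    error: ErrorParams = field(default_factory=ErrorParams)
    psi: float = 20.0

    def __post_init__(self) -> None:
        model = self.model
        missing = [p for p in model.param_names if p not in self.mu]
        if missing:
            raise ConfigurationError(f"mu missing entries for {missing}")
        extra = [p for p in self.omega if p not in model.param_names]
        if extra:
            raise ConfigurationError(f"omega has unknown parameters {extra}")
        if any(not math.isfinite(v) for v in self.mu.values()):
            raise ConfigurationError("non-finite mu")
        if any(v < 0 or not math.isfinite(v) for v in self.omega.values()):
            raise ConfigurationError("omega entries must be finite and >= 0")

    @property
    def model(self) -> StructuralModel:
        return get_model(self.model_id, psi=self.psi)

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.model.param_names

    @property
    def mu_vector(self) -> np.ndarray:
        return np.array([self.mu[p] for p in self.param_names])

    @property
    def omega_vector(self) -> np.ndarray:
        return np.array([self.omega.get(p, 0.0) for p in self.param_names])

    @property
    def typical(self) -> dict[str, float]:
        """Population typical values exp(mu) on the natural scale."""
        return {p: math.exp(v) for p, v in self.mu.items()}

    @classmethod
    def from_typical(cls, model_id: str, typical: dict[str, float],
                     omega: dict[str, float] | None = None,
                     error: ErrorParams | None = None, psi: float = 20.0) -> "PopulationSpec":
        if any(v <= 0 for v in typical.values()):
            raise ConfigurationError("typical values must be > 0 (log-normal model)")
        return cls(model_id=model_id,
                   mu={p: math.log(v) for p, v in typical.items()},
                   omega=dict(omega or {}),
                   error=error or ErrorParams(), psi=psi)
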