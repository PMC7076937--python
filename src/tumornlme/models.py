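"""Structural models of perturbed and unperturbed tumor growth.

The central object is a biphasic tumor growth function (TGF) that switches
smoothly from exponential growth at rate ``lambda0`` to linear growth at slope
``lambda1``, the sharpness of the switch set by ``psi``.  Chemotherapy is
modelled by a first-order-eliminated drug concentration ``c(t)`` that moves
proliferating cells (compartment Z1) into a chain of "damaged" transit
compartments at rate ``k1*c(t)``, through which they pass at rate ``k2``
before elimination.  A variant replaces the transit chain with a single
damaged compartment whose elimination is explicitly delayed by ``t2`` days.
Three classic saturating growth laws (generalized logistic, Gompertz,
von Bertalanffy) are provided with their closed-form solutions for use as
competing candidates on untreated cohorts.

Units: time in days, volumes in mm^3, drug amount in arbitrary concentration
units (the potency ``k1`` absorbs the concentration scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "DoseRegimen",
    "SimeoniParams",
    "ClassicParams",
    "CLASSIC_MODEL_NAMES",
    "concentration",
    "tgf",
    "simeoni_rhs",
    "delay_rhs",
    "classic_volume",
    "classic_rhs",
]

CLASSIC_MODEL_NAMES = ("generalized_logistic", "gompertz", "von_bertalanffy")


@dataclass(frozen=True)
class DoseRegimen:
    """A single intravenous bolus followed by first-order drug elimination.

    ``dose_amount = 0`` encodes an untreated (control) subject.
    """

    dose_time: float = 0.0
    dose_amount: float = 1.0
    ke: float = 1.0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.dose_time, self.dose_amount, self.ke))):
            raise DomainError("dose regimen fields must be finite")
        if self.dose_amount < 0:
            raise ConfigurationError("dose_amount must be >= 0")
        if self.ke <= 0:
            raise ConfigurationError("elimination rate ke must be > 0")

    @classmethod
    def control(cls) -> "DoseRegimen":
        return cls(dose_time=0.0, dose_amount=0.0, ke=1.0)


@dataclass(frozen=True)
class SimeoniParams:
    """Parameters of the transit-chain model and its explicit-delay variant.

    ``n_transit`` is the number of damaged-cell compartments in the chain
    (arbitrary by construction; 3 is the classic depiction).  ``t2`` is the
    elimination delay in days and is read only by the delay variant.
    """

    lambda0: float  # exponential growth rate, 1/day
    lambda1: float  # linear growth slope, mm^3/day
    V0: float  # initial tumor volume, mm^3
    psi: float = 20.0  # switching sharpness, dimensionless
    k1: float = 0.0  # drug potency, 1/(conc * day)
    k2: float = 0.0  # transit / elimination rate, 1/day
    n_transit: int = 3
    t2: float = 0.0  # elimination delay, days (delay variant only)

    def __post_init__(self) -> None:
        vals = (self.lambda0, self.lambda1, self.V0, self.psi, self.k1, self.k2, self.t2)
        if not all(map(math.isfinite, vals)):
            raise DomainError("model parameters must be finite")
        if self.lambda0 <= 0 or self.lambda1 <= 0 or self.V0 <= 0:
            raise ConfigurationError("lambda0, lambda1 and V0 must be > 0")
        if self.psi < 1:
            raise ConfigurationError("psi must be >= 1")
        if self.k1 < 0 or self.k2 < 0:
            raise ConfigurationError("k1 and k2 must be >= 0")
        if self.t2 < 0:
            raise ConfigurationError("delay t2 must be >= 0")
        if int(self.n_transit) != self.n_transit or self.n_transit < 1:
            raise ConfigurationError("n_transit must be an integer >= 1")

    def with_(self, **kw) -> "SimeoniParams":
        return replace(self, **kw)


def concentration(t, regimen: DoseRegimen):
    """Drug concentration at time(s) ``t``: 0 before the bolus, then
    ``dose_amount * exp(-ke * (t - dose_time))``."""
    t = np.asarray(t, dtype=float)
    dt = t - regimen.dose_time
    c = np.where(dt >= 0.0, regimen.dose_amount * np.exp(-regimen.ke * np.minimum(dt, 700 / regimen.ke)), 0.0)
    if c.ndim == 0:
        return float(c)
    return c


def _tgf_denominator(v: float, lambda0: float, lambda1: float, psi: float) -> float:
    # [1 + ((l0/l1) V)^psi]^(1/psi), evaluated stably for large arguments
    x = (lambda0 / lambda1) * v
    if x <= 0.0:
        return 1.0
    logx = math.log(x)
    if psi * logx > 700.0:  # x^psi would overflow; limit is x itself
        return x
    return math.pow(1.0 + math.pow(x, psi), 1.0 / psi)


def tgf(z1: float, v: float, lambda0: float, lambda1: float, psi: float) -> float:
    """Biphasic tumor growth function: ``lambda0*Z1 / [1 + ((lambda0/lambda1) V)^psi]^(1/psi)``.

    Exponential at small volume (rate lambda0), linear at large volume
    (slope lambda1).  ``v`` is the total volume entering the saturation term;
    a transiently negative total (possible in the delay variant) is clamped
    to 0 there.
    """
    if not (math.isfinite(z1) and math.isfinite(v)):
        raise DomainError("tgf: non-finite inputs")
    if z1 < 0:
        raise DomainError("tgf: Z1 must be >= 0")
    return lambda0 * z1 / _tgf_denominator(max(v, 0.0), lambda0, lambda1, psi)


def simeoni_rhs(t: float, state, params: SimeoniParams, regimen: DoseRegimen) -> np.ndarray:
    """Right-hand side of the transit-chain system.

    ``state`` = (Z1, Z2, ..., Z_{n+1}) with Z1 proliferating and n damaged
    compartments.  Mass balance: the component sum of the derivative equals
    TGF - k2 * Z_last.
    """
    z = np.asarray(state, dtype=float)
    if z.shape != (1 + params.n_transit,):
        raise ConfigurationError(
            f"state length {z.size} != 1 + n_transit = {1 + params.n_transit}"
        )
    c = concentration(t, regimen)
    kill = params.k1 * c * z[0]
    growth = tgf(max(z[0], 0.0), float(z.sum()), params.lambda0, params.lambda1, params.psi)
    dz = np.empty_like(z)
    dz[0] = growth - kill
    dz[1] = kill - params.k2 * z[1]
    for j in range(2, z.size):
        dz[j] = params.k2 * (z[j - 1] - z[j])
    return dz


def delay_rhs(t: float, state_now, z2_lagged: float, params: SimeoniParams,
              regimen: DoseRegimen) -> np.ndarray:
    """Right-hand side of the explicit-delay variant.

    ``state_now`` = (Z1(t), Z2(t)); ``z2_lagged`` = Z2(t - t2) supplied by the
    integrator's history (identically 0 before time 0).  Total volume is
    Z1 + Z2.
    """
    if params.t2 < 0:
        raise ConfigurationError("negative lag")
    z1, z2 = float(state_now[0]), float(state_now[1])
    c = concentration(t, regimen)
    kill = params.k1 * c * z1
    growth = tgf(max(z1, 0.0), z1 + z2, params.lambda0, params.lambda1, params.psi)
    return np.array([growth - kill, kill - params.k2 * z2_lagged])


@dataclass(frozen=True)
class ClassicParams:
    """Parameters of one of the classic saturating growth laws.

    Only the fields used by ``model_name`` may be set:

    - ``generalized_logistic``: dV/dt = a V (1 - (V/K)^nu)
    - ``gompertz``:             dV/dt = a V ln(beta V)
    - ``von_bertalanffy``:      dV/dt = a V^gamma - b V
    """

    model_name: str
    V0: float
    a: float
    K: float | None = None
    nu: float | None = None
    beta: float | None = None
    b: float | None = None
    gamma: float | None = None

    _REQUIRED = {
        "generalized_logistic": ("K", "nu"),
        "gompertz": ("beta",),
        "von_bertalanffy": ("b", "gamma"),
    }

    def __post_init__(self) -> None:
        if self.model_name not in CLASSIC_MODEL_NAMES:
            raise ConfigurationError(f"unknown classic model {self.model_name!r}")
        if self.V0 <= 0 or self.a <= 0:
            raise ConfigurationError("V0 and a must be > 0")
        required = self._REQUIRED[self.model_name]
        for name in ("K", "nu", "beta", "b", "gamma"):
            val = getattr(self, name)
            if name in required:
                if val is None or val <= 0:
                    raise ConfigurationError(f"{self.model_name} requires {name} > 0")
            elif val is not None:
                raise ConfigurationError(f"{name} is not a parameter of {self.model_name}")
        if self.model_name == "von_bertalanffy" and not self.gamma < 1:
            raise ConfigurationError("von Bertalanffy exponent gamma must be < 1")


def classic_volume(t, params: ClassicParams):
    """Closed-form solution of the named classic growth law with V(0) = V0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("classic_volume: t must be >= 0")
    name, v0, a = params.model_name, params.V0, params.a
    if name == "generalized_logistic":
        K, nu = params.K, params.nu
        out = K / (1.0 + ((K / v0) ** nu - 1.0) * np.exp(-a * nu * t)) ** (1.0 / nu)
    elif name == "gompertz":
        beta = params.beta
        out = (1.0 / beta) * np.exp(np.log(beta * v0) * np.exp(a * t))
    else:  # von_bertalanffy
        b, g = params.b, params.gamma
        p = 1.0 - g
        out = (a / b + (v0 ** p - a / b) * np.exp(-b * p * t)) ** (1.0 / p)
    if out.ndim == 0:
        return float(out)
    return out


def classic_rhs(t, v, params: ClassicParams):
    """The differential form of the named classic law (for numeric cross-checks).

    Accepts scalar or array states so it can be handed to adaptive integrators
    directly.
    """
    v = np.asarray(v, dtype=float)
    name, a = params.model_name, params.a
    if name == "generalized_logistic":
        return a * v * (1.0 - (v / params.K) ** params.nu)
    if name == "gompertz":
        return a * v * np.log(params.beta * v)
    return a * v ** params.gamma - params.b * v
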