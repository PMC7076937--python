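"""Registry of structural models usable by the simulator and the mixed-effects fitter.

A :class:`StructuralModel` maps an individual parameter vector (natural scale,
ordered as ``param_names``), a dosing regimen and observation times to
predicted tumor volumes.  Models are selected by string id:

========================  =============================================  =======================
id                        dynamics                                       individual parameters
========================  =============================================  =======================
``tgf``                   unperturbed biphasic growth (control cohorts)  lambda0, lambda1, V0
``simeoni-<n>``           transit chain with n damaged compartments      lambda0, lambda1, V0, k1, k2
``delay``                 single damaged compartment, delayed clearance  lambda0, lambda1, V0, k1, k2, t2
``generalized_logistic``  closed form                                    a, K, nu, V0
``gompertz``              closed form                                    a, beta, V0
``von_bertalanffy``       closed form                                    a, b, gamma, V0
========================  =============================================  =======================

The switching sharpness ``psi`` is a model-level constant (default 20), not an
individual parameter: it is weakly identifiable from volume data and is fixed
during estimation unless the caller builds a model with a different value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .dynamics import DDE_STEP, Trajectory, solve_dde, solve_ode, solve_ode_rk4
from .errors import ConfigurationError
from .models import ClassicParams, DoseRegimen, SimeoniParams, classic_volume

__all__ = ["StructuralModel", "get_model", "MODEL_IDS"]

MODEL_IDS = (
    "tgf",
    "simeoni-1",
    "simeoni-2",
    "simeoni-3",
    "delay",
    "generalized_logistic",
    "gompertz",
    "von_bertalanffy",
)

_CLASSIC_PARAM_NAMES = {
    "generalized_logistic": ("a", "K", "nu", "V0"),
    "gompertz": ("a", "beta", "V0"),
    "von_bertalanffy": ("a", "b", "gamma", "V0"),
}


@dataclass(frozen=True)
class StructuralModel:
    """A named mechanistic model with a uniform prediction interface."""

    id: str
    param_names: tuple[str, ...]
    psi: float = 20.0
    n_transit: int = 0  # transit-chain variants only
    dde_step: float = DDE_STEP
    rtol: float = 1e-8
    atol: float = 1e-8
    ode_mode: str = "adaptive"  # "adaptive" | "rk4" (fast fitting profile)

    @property
    def kind(self) -> str:
        if self.id == "delay":
            return "delay"
        if self.id == "tgf" or self.id.startswith("simeoni"):
            return "transit"
        return "classic"

    def _phi_dict(self, phi) -> dict:
        phi = np.asarray(phi, dtype=float)
        if phi.shape != (len(self.param_names),):
            raise ConfigurationError(
                f"{self.id}: expected {len(self.param_names)} parameters "
                f"{self.param_names}, got shape {phi.shape}"
            )
        return dict(zip(self.param_names, phi))

    def trajectory(self, times, phi, regimen: DoseRegimen | None = None) -> Trajectory:
        """Full solution object (volumes plus compartments where applicable)."""
        p = self._phi_dict(phi)
        regimen = regimen or DoseRegimen.control()
        if self.kind == "classic":
            cp = ClassicParams(model_name=self.id, **p)
            t = np.asarray(times, dtype=float)
            return Trajectory(times=t, volumes=np.clip(classic_volume(t, cp), 0.0, None))
        untreated = regimen.dose_amount == 0.0
        if self.kind == "transit" or untreated:
            # with no dose the damaged compartments stay empty and every
            # perturbed variant reduces exactly to the 1-D growth chain
            sp = SimeoniParams(
                lambda0=p["lambda0"], lambda1=p["lambda1"], V0=p["V0"], psi=self.psi,
                k1=0.0 if untreated else p.get("k1", 0.0),
                k2=p.get("k2", 0.0),
                n_transit=1 if untreated else max(self.n_transit, 1),
            )
            if self.ode_mode == "rk4":
                return solve_ode_rk4(sp, regimen, times, step=self.dde_step)
            return solve_ode(sp, regimen, times, rtol=self.rtol, atol=self.atol)
        sp = SimeoniParams(
            lambda0=p["lambda0"], lambda1=p["lambda1"], V0=p["V0"], psi=self.psi,
            k1=p["k1"], k2=p["k2"], n_transit=1, t2=p["t2"],
        )
        return solve_dde(sp, regimen, times, step=self.dde_step)

    def predict(self, times, phi, regimen: DoseRegimen | None = None) -> np.ndarray:
        """Predicted volumes (mm^3) at ``times`` for individual parameters ``phi``."""
        return self.trajectory(times, phi, regimen).volumes


def get_model(model_id: str, psi: float = 20.0, dde_step: float = DDE_STEP,
              rtol: float = 1e-8, atol: float = 1e-8,
              ode_mode: str = "adaptive") -> StructuralModel:
    """Look up a structural model by id (see module docstring for the table)."""
    if model_id in _CLASSIC_PARAM_NAMES:
        return StructuralModel(id=model_id, param_names=_CLASSIC_PARAM_NAMES[model_id])
    if model_id == "tgf":
        return StructuralModel(id="tgf", param_names=("lambda0", "lambda1", "V0"),
                               psi=psi, n_transit=1, rtol=rtol, atol=atol,
                               dde_step=dde_step, ode_mode=ode_mode)
    if model_id == "delay":
        return StructuralModel(id="delay",
                               param_names=("lambda0", "lambda1", "V0", "k1", "k2", "t2"),
                               psi=psi, dde_step=dde_step, ode_mode=ode_mode)
    m = re.fullmatch(r"simeoni-(\d+)", model_id)
    if m:
        n = int(m.group(1))
        if n < 1:
            raise ConfigurationError("simeoni-n requires n >= 1")
        return StructuralModel(id=model_id,
                               param_names=("lambda0", "lambda1", "V0", "k1", "k2"),
                               psi=psi, n_transit=n, rtol=rtol, atol=atol,
                               dde_step=dde_step, ode_mode=ode_mode)
    raise ConfigurationError(f"unknown model id {model_id!r}; known ids: {MODEL_IDS}")
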