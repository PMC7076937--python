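"""Synthetic preclinical cohorts with the statistical structure the analysis assumes.

The generator emulates a single-site mammary-tumor chemotherapy experiment:
two arms (untreated controls and a single cisplatin-like bolus at day 0),
near-daily caliper measurement with weekend gaps, enrolment restricted to
tumors below 700 mm^3, and welfare censoring at the first observation reaching
~2500 mm^3.  Individual parameters are log-normal around population typical
values; observations carry combined additive + proportional noise.

True individual parameters are stored on each synthetic subject
(``phi_true``) so parameter-recovery tests can compare directly; the fitting
module never reads them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .models import DoseRegimen
from .population import ErrorParams, PopulationSpec

__all__ = [
    "Subject",
    "Cohort",
    "StudyDesign",
    "default_population",
    "control_population",
    "sample_individual_params",
    "observe",
    "caliper_volume",
    "generate_cohort",
    "read_cohort_csv",
]


def default_population() -> PopulationSpec:
    """Generator defaults for a treated-arm delay-model population.

    Typical values are stand-ins chosen to produce realistic kinetics for the
    emulated study: ~4-day initial doubling, ~120 mm^3/day linear phase,
    visible-but-heterogeneous regression after a unit bolus with 1/day
    elimination.
    """
    return PopulationSpec.from_typical(
        "delay",
        typical={"lambda0": 0.25, "lambda1": 120.0, "V0": 200.0,
                 "k1": 0.8, "k2": 0.5, "t2": 2.0},
        omega={"lambda0": 0.3, "lambda1": 0.3, "V0": 0.4,
               "k1": 0.4, "k2": 0.3, "t2": 0.2},
        error=ErrorParams(a=20.0, b=0.1),
    )


def control_population() -> PopulationSpec:
    """Generator defaults for an untreated cohort under pure biphasic growth."""
    return PopulationSpec.from_typical(
        "tgf",
        typical={"lambda0": 0.25, "lambda1": 120.0, "V0": 200.0},
        omega={"lambda0": 0.3, "lambda1": 0.3, "V0": 0.4},
        error=ErrorParams(a=20.0, b=0.1),
    )


@dataclass
class Subject:
    """One animal's longitudinal record."""

    id: str
    group: str  # "control" | "treated"
    regimen: DoseRegimen
    times: np.ndarray  # observation days, increasing
    volumes: np.ndarray  # observed volumes, mm^3, > 0
    phi_true: dict[str, float] | None = None  # synthetic cohorts only

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.group not in ("control", "treated"):
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.times.shape != self.volumes.shape or self.times.ndim != 1:
            raise ConfigurationError("times/volumes shape mismatch")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("subject times must be increasing")
        if np.any(self.volumes <= 0):
            raise ConfigurationError("observed volumes must be > 0")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


@dataclass
class Cohort:
    """A set of subjects plus the provenance needed to regenerate it."""

    subjects: list[Subject]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ConfigurationError("cohort must contain at least one subject")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)

    def subset(self, group: str) -> "Cohort":
        subs = [s for s in self.subjects if s.group == group]
        if not subs:
            raise ConfigurationError(f"no subjects in group {group!r}")
        return Cohort(subjects=subs, provenance={**self.provenance, "subset": group})

    def data_hash(self) -> str:
        """Cheap fingerprint used to verify that fits share a cohort."""
        import hashlib

        h = hashlib.sha1()
        for s in self.subjects:
            h.update(s.id.encode())
            h.update(np.round(s.times, 6).tobytes())
            h.update(np.round(s.volumes, 6).tobytes())
        return h.hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for t, v in zip(s.times, s.volumes):
                rows.append((s.id, s.group, t, v))
        return pd.DataFrame(rows, columns=["subject_id", "group", "time_day", "volume_mm3"])

    def dosing_frame(self) -> pd.DataFrame:
        rows = [(s.id, s.regimen.dose_time, s.regimen.dose_amount, s.regimen.ke)
                for s in self.subjects]
        return pd.DataFrame(rows, columns=["subject_id", "dose_time_day", "dose_amount", "ke"])

    def to_csv(self, obs_path, dosing_path=None) -> None:
        self.to_frame().to_csv(obs_path, index=False, float_format="%.6f")
        if dosing_path is not None:
            self.dosing_frame().to_csv(dosing_path, index=False, float_format="%.6f")


def read_cohort_csv(obs_path, dosing_path=None) -> Cohort:
    """Load a tidy cohort CSV (and optional dosing sidecar) written by :meth:`Cohort.to_csv`."""
    df = pd.read_csv(obs_path)
    dosing = {}
    if dosing_path is not None and Path(dosing_path).exists():
        ddf = pd.read_csv(dosing_path)
        for _, r in ddf.iterrows():
            dosing[str(r.subject_id)] = DoseRegimen(
                dose_time=float(r.dose_time_day), dose_amount=float(r.dose_amount),
                ke=float(r.get("ke", 1.0)))
    subjects = []
    for sid, g in df.groupby("subject_id", sort=False):
        group = str(g["group"].iloc[0])
        reg = dosing.get(str(sid))
        if reg is None:
            reg = DoseRegimen.control() if group == "control" else DoseRegimen()
        subjects.append(Subject(id=str(sid), group=group, regimen=reg,
                                times=g["time_day"].to_numpy(),
                                volumes=g["volume_mm3"].to_numpy()))
    return Cohort(subjects=subjects, provenance={"source": str(obs_path)})


@dataclass(frozen=True)
class StudyDesign:
    """Arm sizes, schedule and stopping rules of the emulated experiment."""

    n_control: int = 21
    n_treated: int = 19
    horizon_days: int = 42
    dose_time: float = 0.0
    dose_amount: float = 1.0
    ke: float = 1.0  # drug elimination rate, 1/day
    censor_volume: float = 2500.0  # welfare threshold, mm^3
    v0_cap: float = 700.0  # enrolment cap on initial volume, mm^3
    weekend_gaps: bool = True  # repeating 5-on / 2-off sampling pattern
    positivity: str = "resample"  # "resample" | "truncate" handling of y <= 0

    def __post_init__(self) -> None:
        if self.horizon_days <= 0:
            raise ConfigurationError("design horizon must be > 0")
        if self.n_control < 0 or self.n_treated < 0 or self.n_control + self.n_treated < 1:
            raise ConfigurationError("need at least one subject")
        if self.positivity not in ("resample", "truncate"):
            raise ConfigurationError("positivity must be 'resample' or 'truncate'")

    def observation_days(self) -> np.ndarray:
        days = np.arange(0, self.horizon_days + 1)
        if self.weekend_gaps:
            days = days[days % 7 < 5]
        return days.astype(float)

    def regimen(self, group: str) -> DoseRegimen:
        if group == "control":
            return DoseRegimen(dose_time=self.dose_time, dose_amount=0.0, ke=self.ke)
        return DoseRegimen(dose_time=self.dose_time, dose_amount=self.dose_amount, ke=self.ke)


def sample_individual_params(spec: PopulationSpec, n_subjects: int, seed) -> np.ndarray:
    """Draw phi_i = exp(mu + lambda_i), lambda_i ~ N(0, Omega), Omega diagonal.

    Returns an (n_subjects, p) array on the natural scale, columns ordered as
    ``spec.param_names``.  Reproducible: ``seed`` may be an int or an already
    constructed :class:`numpy.random.Generator`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = spec.mu_vector
    om = spec.omega_vector
    lam = rng.standard_normal((n_subjects, mu.size)) * om
    return np.exp(mu + lam)


def observe(f_pred: float, error: ErrorParams, rng: np.random.Generator,
            positivity: str = "resample") -> float:
    """One noisy measurement y = f + (a + b*f) e, constrained positive.

    ``resample`` redraws e until y > 0 (up to 1000 draws); ``truncate`` clips
    at a small positive floor instead.
    """
    if f_pred < 0:
        raise DomainError("predicted volume must be >= 0")
    s = float(error.sd(f_pred))
    for _ in range(1000):
        y = f_pred + s * rng.standard_normal()
        if y > 0:
            return float(y)
        if positivity == "truncate":
            return 1e-3
    raise DomainError("could not draw a positive observation")


def caliper_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid caliper approximation V = L * W^2 / 2 (mm^3), requiring L >= W > 0."""
    if not (math.isfinite(length_mm) and math.isfinite(width_mm)):
        raise DomainError("caliper dimensions must be finite")
    if width_mm <= 0 or length_mm < width_mm:
        raise DomainError("require length >= width > 0")
    return length_mm * width_mm ** 2 / 2.0


def _simulate_subject(spec: PopulationSpec, design: StudyDesign, group: str,
                      sid: str, rng: np.random.Generator) -> Subject:
    model = spec.model
    names = list(spec.param_names)
    v0_idx = names.index("V0")
    regimen = design.regimen(group)
    days = design.observation_days()

    for _ in range(1000):  # enrolment: redraw until V0 below the cap
        phi = sample_individual_params(spec, 1, rng)[0]
        if phi[v0_idx] < design.v0_cap:
            break
    else:
        raise ConfigurationError("could not draw V0 below the enrolment cap")

    f = np.clip(model.predict(days, phi, regimen), 0.0, None)
    y = np.array([observe(fi, spec.error, rng, design.positivity) for fi in f])
    over = np.nonzero(y >= design.censor_volume)[0]
    if over.size:  # keep the triggering observation, drop later ones
        days, y = days[: over[0] + 1], y[: over[0] + 1]
    return Subject(id=sid, group=group, regimen=regimen, times=days, volumes=y,
                   phi_true=dict(zip(names, map(float, phi))))


def generate_cohort(spec: PopulationSpec, design: StudyDesign, seed: int,
                    control_spec: PopulationSpec | None = None) -> Cohort:
    """Simulate a full two-arm cohort.

    Controls are generated from ``control_spec`` when given (e.g. a pure-growth
    population), otherwise from ``spec`` with a zero-dose regimen — the
    structural models coincide on controls either way.  Control and treated
    draws use independent child streams of ``seed`` so arm sizes can change
    without perturbing the other arm.
    """
    ss = np.random.SeedSequence(seed)
    rng_c, rng_t = (np.random.default_rng(s) for s in ss.spawn(2))
    cspec = control_spec or spec
    subjects = []
    for i in range(design.n_control):
        subjects.append(_simulate_subject(cspec, design, "control", f"C{i + 1:02d}", rng_c))
    for i in range(design.n_treated):
        subjects.append(_simulate_subject(spec, design, "treated", f"T{i + 1:02d}", rng_t))
    prov = {"seed": int(seed), "model_id": spec.model_id,
            "design": {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                       for k, v in asdict(design).items()}}
    prov = json.loads(json.dumps(prov))  # force plain JSON-able types
    return Cohort(subjects=subjects, provenance=prov)
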