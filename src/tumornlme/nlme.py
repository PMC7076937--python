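"""Nonlinear mixed-effects estimation by stochastic-approximation EM (SAEM).

The hierarchical model: observations y_ij = f(t_ij, phi_i) + (a + b f) e_ij
with e_ij ~ N(0, 1); individual parameters phi_i = exp(eta_i) with
eta_i ~ N(mu, Omega), Omega diagonal.  The E-step runs a few random-walk
Metropolis transitions per subject on eta_i; sufficient statistics are
updated by stochastic approximation (step 1 in the exploratory phase, then
1/iter^0.7); the M-step is closed-form for mu and the Omega diagonal and a
small Nelder--Mead solve for the residual scales (a, b).

A fit's table-grade marginal -2 log-likelihood is computed separately by
importance sampling with a conditional-mode-centered Gaussian proposal
(:func:`estimate_minus2LL`); :func:`fit_population` itself records a cheaper
Laplace approximation evaluated at the smoothed individual modes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigurationError, SolverError
from .population import ErrorParams
from .simulate import Cohort, Subject
from .structural import StructuralModel, get_model

__all__ = [
    "SaemSettings",
    "FitResult",
    "individual_loglik",
    "fit_population",
    "estimate_minus2LL",
    "individual_fits",
]

_LOG2PI = math.log(2.0 * math.pi)
_SD_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# settings / results
# ---------------------------------------------------------------------------


@dataclass
class SaemSettings:
    """Tuning knobs of the SAEM fit; the defaults are the 'full' profile."""

    n_burn: int = 300  # exploratory iterations (step size 1)
    n_smooth: int = 200  # smoothing iterations (step size 1/k^0.7)
    n_mcmc: int = 2  # random-walk block sweeps per subject per iteration
    step_power: float = 0.7
    error_model: str = "combined"  # "additive" | "proportional" | "combined"
    init_error: tuple[float, float] = (20.0, 0.1)
    init_omega: float = 0.3  # initial random-effect sd (all parameters)
    init_typical: dict[str, float] | None = None  # natural-scale starting values
    random_effects: dict[str, bool] | None = None  # default: all True
    omega_pinned: float = 0.05  # sd used for parameters with toggled-off REs
    omega_floor: float = 1e-3
    proposal_scale: float = 0.6
    adapt_proposal: bool = True
    omega_zero: bool = False  # degenerate path: plain shared-parameter ML
    compute_laplace: bool = True  # Laplace -2LL at the end of the fit
    init_strategy: str = "individual"  # "individual" | "typical" starting etas

    @classmethod
    def profile(cls, name: str, **overrides) -> "SaemSettings":
        """Named iteration budgets: 'full' (300+200) or 'fast' (200+100)."""
        if name == "full":
            base = cls()
        elif name == "fast":
            base = cls(n_burn=200, n_smooth=100, compute_laplace=False)
        else:
            raise ConfigurationError(f"unknown profile {name!r}")
        return replace(base, **overrides)


@dataclass
class FitResult:
    """Population estimates, individual modes and fit diagnostics."""

    model_id: str
    param_names: tuple[str, ...]
    mu: np.ndarray  # fixed effects, log scale
    omega: np.ndarray  # random-effect sds (sqrt of the Omega diagonal)
    error: ErrorParams
    minus2LL: float
    minus2LL_method: str
    minus2LL_se: float
    individual_eta: np.ndarray  # (N, p) smoothed conditional modes, log scale
    n_obs: int
    n_subjects: int
    k: int  # parameter count for information criteria
    converged: bool
    data_hash: str
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def typical(self) -> dict[str, float]:
        """exp(mu): population typical values on the natural scale."""
        return {p: float(np.exp(m)) for p, m in zip(self.param_names, self.mu)}

    @property
    def omega_dict(self) -> dict[str, float]:
        return {p: float(o) for p, o in zip(self.param_names, self.omega)}

    @property
    def individual_phi(self) -> np.ndarray:
        return np.exp(self.individual_eta)

    def to_json(self, path) -> None:
        payload = {
            "model_id": self.model_id,
            "param_names": list(self.param_names),
            "mu": self.mu.tolist(),
            "omega": self.omega.tolist(),
            "error": {"a": self.error.a, "b": self.error.b, "sigma": self.error.sigma},
            "minus2LL": self.minus2LL,
            "minus2LL_method": self.minus2LL_method,
            "minus2LL_se": self.minus2LL_se,
            "individual_eta": self.individual_eta.tolist(),
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "k": self.k,
            "converged": self.converged,
            "data_hash": self.data_hash,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "FitResult":
        d = json.loads(Path(path).read_text())
        return cls(
            model_id=d["model_id"], param_names=tuple(d["param_names"]),
            mu=np.asarray(d["mu"]), omega=np.asarray(d["omega"]),
            error=ErrorParams(**d["error"]),
            minus2LL=d["minus2LL"], minus2LL_method=d["minus2LL_method"],
            minus2LL_se=d["minus2LL_se"],
            individual_eta=np.asarray(d["individual_eta"]),
            n_obs=d["n_obs"], n_subjects=d["n_subjects"], k=d["k"],
            converged=d["converged"], data_hash=d["data_hash"], seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------


def _gaussian_loglik(y: np.ndarray, f: np.ndarray, error: ErrorParams) -> float:
    g = np.maximum(error.sd(f), _SD_FLOOR)
    r = (y - f) / g
    return float(-0.5 * np.sum(r * r) - np.sum(np.log(g)) - 0.5 * y.size * _LOG2PI)


def individual_loglik(subject: Subject, phi, model: StructuralModel,
                      error: ErrorParams) -> float:
    """Log-density of one subject's observations given individual parameters.

    Solver failures propagate as :class:`SolverError` tagged with the subject
    id; structurally invalid parameter vectors raise ConfigurationError.
    """
    try:
        f = model.predict(subject.times, phi, subject.regimen)
    except SolverError as exc:
        raise SolverError(f"subject {subject.id}: {exc}") from exc
    return _gaussian_loglik(subject.volumes, f, error)


class _SubjectLik:
    """Per-subject likelihood evaluator that swallows solver failures into -inf."""

    def __init__(self, subject: Subject, model: StructuralModel):
        self.subject = subject
        self.model = model
        self.n_failures = 0

    def __call__(self, phi, error: ErrorParams):
        try:
            f = self.model.predict(self.subject.times, phi, self.subject.regimen)
        except (SolverError, ConfigurationError, FloatingPointError, OverflowError):
            self.n_failures += 1
            return -np.inf, None
        if not np.all(np.isfinite(f)):
            self.n_failures += 1
            return -np.inf, None
        return _gaussian_loglik(self.subject.volumes, f, error), f


def _prior_loglik(eta: np.ndarray, mu: np.ndarray, omega: np.ndarray) -> float:
    om = np.maximum(omega, _SD_FLOOR)
    z = (eta - mu) / om
    return float(-0.5 * np.sum(z * z) - np.sum(np.log(om)) - 0.5 * eta.size * _LOG2PI)


def _fit_error_scales(fbar: np.ndarray, r2bar: np.ndarray, a: float, b: float,
                      error_model: str) -> tuple[float, float]:
    """M-step for the residual scales given SA-smoothed predictions and
    squared residuals (one entry per observation)."""
    f = np.clip(fbar, 0.0, None)
    if error_model == "additive":
        return math.sqrt(max(float(np.mean(r2bar)), 1e-12)), 0.0
    if error_model == "proportional":
        fs = np.maximum(f, 1.0)
        return 0.0, math.sqrt(max(float(np.mean(r2bar / fs ** 2)), 1e-12))

    def obj(x):
        g = np.maximum(math.exp(x[0]) + math.exp(x[1]) * f, _SD_FLOOR)
        return float(np.sum(np.log(g) + 0.5 * r2bar / (g * g)))

    x0 = [math.log(max(a, 1e-3)), math.log(max(b, 1e-4))]
    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"maxiter": 120, "xatol": 1e-4, "fatol": 1e-6})
    return math.exp(res.x[0]), math.exp(res.x[1])


# ---------------------------------------------------------------------------
# SAEM
# ---------------------------------------------------------------------------


def fit_population(cohort: Cohort, model: StructuralModel | str,
                   settings: SaemSettings | None = None,
                   seed: int = 0) -> FitResult:
    """Maximum-likelihood fit of the population model to a cohort.

    Deterministic given (cohort, settings, seed).  Non-convergence is flagged
    on the result, never raised; proposals for which the model cannot be
    solved are rejected and counted in ``diagnostics['n_solver_failures']``.
    """
    if isinstance(model, str):
        model = get_model(model)
    settings = settings or SaemSettings()
    if not cohort.subjects:
        raise ConfigurationError("empty cohort")
    if settings.init_typical is None:
        raise ConfigurationError("settings.init_typical (starting values) is required")
    missing = [p for p in model.param_names if p not in settings.init_typical]
    if missing:
        raise ConfigurationError(f"init_typical missing {missing}")

    if settings.omega_zero:
        return _fit_shared_ml(cohort, model, settings, seed)

    rng = np.random.default_rng(seed)
    names = model.param_names
    p = len(names)
    N = len(cohort)
    subjects = cohort.subjects
    liks = [_SubjectLik(s, model) for s in subjects]

    re_mask = np.array([(settings.random_effects or {}).get(nm, True) for nm in names])
    mu = np.log([settings.init_typical[nm] for nm in names])
    omega = np.where(re_mask, settings.init_omega, settings.omega_pinned).astype(float)
    a, b = settings.init_error
    if settings.error_model == "additive":
        b = 0.0
    elif settings.error_model == "proportional":
        a = 0.0
    error = ErrorParams(a=max(a, 1e-9), b=b, sigma=1.0)

    # Metropolis blocks (also used to restrict the initial individual fits):
    # growth parameters and drug-effect parameters mix on very different
    # posterior geometries, so they are proposed separately.  For untreated
    # subjects the drug block has no likelihood contribution and its
    # conditional posterior is the prior: sample it exactly (free Gibbs).
    drug_idx = [j for j, nm in enumerate(names) if nm in ("k1", "k2", "t2")]
    growth_idx = [j for j, nm in enumerate(names) if nm not in ("k1", "k2", "t2")]
    blocks = [np.array(ix) for ix in (growth_idx, drug_idx) if ix]
    sub_blocks: list[list[np.ndarray]] = []
    sub_inert: list[np.ndarray] = []
    for s in subjects:
        if drug_idx and s.regimen.dose_amount == 0:
            sub_blocks.append([np.array(growth_idx)])
            sub_inert.append(np.array(drug_idx))
        else:
            sub_blocks.append(blocks)
            sub_inert.append(np.array([], dtype=int))

    eta = np.tile(mu, (N, 1))
    if settings.init_strategy == "individual":
        # rough per-subject ML fits (informative components only) give the
        # starting individual etas; their spread initializes mu and omega,
        # sidestepping the slow-drift regime of SAEM under poor starts
        for i, lik in enumerate(liks):
            free = np.concatenate(sub_blocks[i])
            def nls(x, i=i, free=free):
                e = eta[i].copy()
                e[free] = x
                ll, _ = lik(np.exp(e), error)
                return -ll if np.isfinite(ll) else 1e12
            # deliberately short: these starts should be rough — chasing each
            # subject's noise inflates the initial spread and destabilizes
            # the variance components
            res = minimize(nls, eta[i][free], method="Nelder-Mead",
                           options={"maxiter": 150, "xatol": 1e-3, "fatol": 1e-2})
            if np.isfinite(res.fun) and res.fun < 1e11 and nls(res.x) < 1e11:
                eta[i][free] = res.x  # else keep the typical-value start
        informative = np.array([[j in np.concatenate(sub_blocks[i]) for j in range(p)]
                                for i in range(N)])
        counts = informative.sum(axis=0)
        mu = np.where(counts > 0,
                      (eta * informative).sum(axis=0) / np.maximum(counts, 1), mu)
        dev = (eta - mu) * informative
        sd = np.sqrt((dev ** 2).sum(axis=0) / np.maximum(counts - 1, 1))
        omega = np.where(re_mask, np.clip(sd, 0.1, 0.6), settings.omega_pinned)
        eta[:, :] = np.where(informative, eta, mu)

    mu0 = np.log([settings.init_typical[nm] for nm in names])
    cur_ll = np.empty(N)
    cur_f = [None] * N
    for i, lik in enumerate(liks):
        cur_ll[i], cur_f[i] = lik(np.exp(eta[i]), error)
        if not np.isfinite(cur_ll[i]):  # fall back to the typical-value start
            eta[i] = mu0
            cur_ll[i], cur_f[i] = lik(np.exp(eta[i]), error)
        if not np.isfinite(cur_ll[i]):
            raise SolverError(f"model unsolvable at starting values for subject {subjects[i].id}")

    s1, s2 = eta.copy(), eta ** 2
    sF = [f.copy() for f in cur_f]
    sR = [(s.volumes - f) ** 2 for s, f in zip(subjects, cur_f)]

    n_iter = settings.n_burn + settings.n_smooth
    scales = np.full(len(blocks), settings.proposal_scale)
    acc = np.zeros(len(blocks))
    tot = np.zeros(len(blocks))
    mu_trace = np.empty((n_iter, p))
    omega_trace = np.empty((n_iter, p))
    error_trace = np.empty((n_iter, 2))
    obj_trace = np.empty(n_iter)

    for it in range(1, n_iter + 1):
        gamma = 1.0 if it <= settings.n_burn else (it - settings.n_burn) ** -settings.step_power
        base_sd = np.maximum(omega, 0.1 if it <= settings.n_burn else 0.05)
        for i, lik in enumerate(liks):
            pr_cur = _prior_loglik(eta[i], mu, omega)
            # local random-walk Metropolis sweeps over the parameter blocks
            for _ in range(settings.n_mcmc):
                for bi, idx in enumerate(sub_blocks[i]):
                    prop = eta[i].copy()
                    prop[idx] += scales[bi] * base_sd[idx] * rng.standard_normal(idx.size)
                    ll_p, f_p = lik(np.exp(prop), error)
                    tot[bi] += 1
                    if np.isfinite(ll_p):
                        pr_p = _prior_loglik(prop, mu, omega)
                        if math.log(rng.random()) < (ll_p + pr_p) - (cur_ll[i] + pr_cur):
                            eta[i], cur_ll[i], cur_f[i], pr_cur = prop, ll_p, f_p, pr_p
                            acc[bi] += 1
            inert = sub_inert[i]
            if inert.size:  # exact conditional draw, no model solve needed
                eta[i, inert] = mu[inert] + omega[inert] * rng.standard_normal(inert.size)

        if settings.adapt_proposal and it <= settings.n_burn and it % 20 == 0:
            rate = acc / np.maximum(tot, 1)
            scales[rate < 0.20] *= 0.8
            scales[rate > 0.45] *= 1.25
            acc[:] = 0
            tot[:] = 0

        # stochastic-approximation update of sufficient statistics
        s1 += gamma * (eta - s1)
        s2 += gamma * (eta ** 2 - s2)
        for i in range(N):
            sF[i] += gamma * (cur_f[i] - sF[i])
            sR[i] += gamma * ((subjects[i].volumes - cur_f[i]) ** 2 - sR[i])

        # M-step: closed form for mu and the Omega diagonal
        mu = s1.mean(axis=0)
        var = np.maximum((s2 - 2 * mu * s1 + mu ** 2).mean(axis=0), settings.omega_floor ** 2)
        a_new, b_new = _fit_error_scales(np.concatenate(sF), np.concatenate(sR), a, b,
                                         settings.error_model)
        if it <= settings.n_burn:
            # simulated-annealing constraint: variances may shrink at most a
            # few percent per exploratory iteration, keeping the MCMC hot
            # enough to escape the early-collapse pathology
            var = np.maximum(var, 0.95 * np.where(re_mask, omega, 0.0) ** 2)
            a_new = max(a_new, 0.975 * a)
            b_new = max(b_new, 0.975 * b)
        a, b = a_new, b_new
        omega = np.where(re_mask, np.sqrt(var), settings.omega_pinned)
        error = ErrorParams(a=max(a, 1e-9), b=b, sigma=1.0)
        # cached subject log-densities were computed under the previous error
        # scales; refresh them from the cached predictions
        for i in range(N):
            cur_ll[i] = _gaussian_loglik(subjects[i].volumes, cur_f[i], error)

        mu_trace[it - 1] = mu
        omega_trace[it - 1] = omega
        error_trace[it - 1] = (a, b)
        obj_trace[it - 1] = float(-2.0 * np.sum(cur_ll + np.array(
            [_prior_loglik(eta[i], mu, omega) for i in range(N)])))

    tail = min(20, settings.n_smooth)
    converged = bool(np.all(np.ptp(mu_trace[-tail:], axis=0) < 0.05)) if tail > 1 else False

    n_error = 1 if settings.error_model in ("additive", "proportional") else 2
    k = p + int(re_mask.sum()) + n_error
    if settings.compute_laplace:
        m2ll, _ = _laplace_minus2ll(s1, liks, mu, omega, error)
        m2ll_method = "laplace"
    else:
        # cheap conditional placeholder; estimate_minus2LL refines it
        m2ll = float(-2.0 * sum(liks[i](np.exp(s1[i]), error)[0] for i in range(N)))
        m2ll_method = "conditional"
    return FitResult(
        model_id=model.id, param_names=names, mu=mu, omega=omega, error=error,
        minus2LL=m2ll, minus2LL_method=m2ll_method, minus2LL_se=float("nan"),
        individual_eta=s1, n_obs=cohort.n_obs, n_subjects=N, k=k,
        converged=converged, data_hash=cohort.data_hash(), seed=int(seed),
        diagnostics={
            "mu_trace": mu_trace, "omega_trace": omega_trace,
            "error_trace": error_trace, "obj_trace": obj_trace,
            "proposal_scales": scales,
            "n_solver_failures": int(sum(l.n_failures for l in liks)),
        },
    )


def _fit_shared_ml(cohort: Cohort, model: StructuralModel,
                   settings: SaemSettings, seed: int) -> FitResult:
    """Degenerate Omega = 0 path: every subject shares exp(mu); plain ML fit of
    (mu, error scales) by direct optimization."""
    names = model.param_names
    liks = [_SubjectLik(s, model) for s in cohort.subjects]
    combined = settings.error_model == "combined"

    def objective(x):
        phi = np.exp(x[: len(names)])
        if combined:
            err = ErrorParams(a=max(math.exp(x[-2]), 1e-9), b=math.exp(x[-1]))
        elif settings.error_model == "additive":
            err = ErrorParams(a=math.exp(x[-1]), b=0.0)
        else:
            err = ErrorParams(a=1e-9, b=math.exp(x[-1]))
        total = 0.0
        for lik in liks:
            ll, _ = lik(phi, err)
            if not np.isfinite(ll):
                return 1e12
            total += ll
        return -2.0 * total

    a0, b0 = settings.init_error
    x0 = [math.log(settings.init_typical[nm]) for nm in names]
    x0 += [math.log(max(a0, 1e-3)), math.log(max(b0, 1e-4))] if combined else \
        [math.log(max(a0 if settings.error_model == "additive" else b0, 1e-4))]
    res = minimize(objective, np.asarray(x0), method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9})
    x = res.x
    mu = x[: len(names)]
    if combined:
        error = ErrorParams(a=max(math.exp(x[-2]), 1e-9), b=math.exp(x[-1]))
        n_error = 2
    elif settings.error_model == "additive":
        error, n_error = ErrorParams(a=math.exp(x[-1]), b=0.0), 1
    else:
        error, n_error = ErrorParams(a=1e-9, b=math.exp(x[-1])), 1
    N = len(cohort)
    return FitResult(
        model_id=model.id, param_names=names, mu=mu, omega=np.zeros(len(names)),
        error=error, minus2LL=float(res.fun), minus2LL_method="exact",
        minus2LL_se=0.0, individual_eta=np.tile(mu, (N, 1)),
        n_obs=cohort.n_obs, n_subjects=N, k=len(names) + n_error,
        converged=bool(res.success), data_hash=cohort.data_hash(), seed=int(seed),
        diagnostics={"optimizer": {"nfev": res.nfev, "message": res.message},
                     "n_solver_failures": int(sum(l.n_failures for l in liks))},
    )


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------


def _neg_logpost(eta, lik: _SubjectLik, mu, omega, error):
    ll, _ = lik(np.exp(eta), error)
    if not np.isfinite(ll):
        return 1e12
    return -(ll + _prior_loglik(eta, mu, omega))


def _conditional_mode(lik, eta0, mu, omega, error, maxiter: int = 200) -> np.ndarray:
    res = minimize(_neg_logpost, eta0, args=(lik, mu, omega, error),
                   method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6})
    return res.x


def _numeric_hessian(fun, x0, h=1e-3) -> np.ndarray:
    p = x0.size
    H = np.empty((p, p))
    f0 = fun(x0)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h
            ej = np.zeros(p); ej[j] = h
            if i == j:
                H[i, i] = (fun(x0 + ei) - 2 * f0 + fun(x0 - ei)) / h ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(x0 + ei + ej) - fun(x0 + ei - ej)
                    - fun(x0 - ei + ej) + fun(x0 - ei - ej)
                ) / (4 * h ** 2)
    return H


def _laplace_minus2ll(eta_modes, liks, mu, omega, error) -> tuple[float, int]:
    """Laplace approximation of -2 log marginal likelihood at given modes."""
    p = mu.size
    total = 0.0
    n_fallback = 0
    for i, lik in enumerate(liks):
        eta0 = eta_modes[i]
        f = lambda e: _neg_logpost(e, lik, mu, omega, error)
        H = _numeric_hessian(f, eta0)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0 or not np.isfinite(logdet):
            # fall back to the prior curvature for ill-conditioned Hessians
            logdet = float(np.sum(-2.0 * np.log(np.maximum(omega, _SD_FLOOR))))
            n_fallback += 1
        total += -f(eta0) + 0.5 * p * _LOG2PI - 0.5 * logdet
    return -2.0 * total, n_fallback


def estimate_minus2LL(fit: FitResult, cohort: Cohort, model: StructuralModel | str,
                      n_is_samples: int = 1000, seed: int = 0) -> float:
    """Importance-sampling estimate of the marginal -2 log-likelihood.

    Per subject, the proposal is a Gaussian centered at the conditional mode
    with covariance from the inverse curvature there (falling back to a
    prior-scaled diagonal when the numeric Hessian is not positive definite;
    the fallback count lands in ``fit.diagnostics``).  The estimate and its
    Monte-Carlo standard error are written back onto ``fit`` and the value is
    returned.  With Omega = 0 the integral collapses and the exact value
    -2 sum_i loglik(exp(mu)) is returned.
    """
    if isinstance(model, str):
        model = get_model(model)
    if fit.data_hash != cohort.data_hash():
        raise ConfigurationError("fit and cohort do not match")
    liks = [_SubjectLik(s, model) for s in cohort.subjects]
    mu, omega, error = fit.mu, fit.omega, fit.error

    if np.all(omega < 1e-8):
        total = sum(individual_loglik(s, np.exp(mu), model, error) for s in cohort.subjects)
        fit.minus2LL, fit.minus2LL_method, fit.minus2LL_se = -2.0 * total, "exact", 0.0
        return fit.minus2LL

    rng = np.random.default_rng(seed)
    p = mu.size
    total = 0.0
    var_total = 0.0
    n_fallback = 0
    for i, lik in enumerate(liks):
        mode = _conditional_mode(lik, fit.individual_eta[i], mu, omega, error)
        f = lambda e: _neg_logpost(e, lik, mu, omega, error)
        H = _numeric_hessian(f, mode)
        try:
            L = np.linalg.cholesky(np.linalg.inv(H))
            cov_logdet = -float(np.linalg.slogdet(H)[1])
        except np.linalg.LinAlgError:
            n_fallback += 1
            sd = np.maximum(omega, 0.05) / math.sqrt(2.0)
            L = np.diag(sd)
            cov_logdet = float(2.0 * np.sum(np.log(sd)))
        z = rng.standard_normal((n_is_samples, p))
        etas = mode + z @ L.T
        logq = -0.5 * np.sum(z * z, axis=1) - 0.5 * p * _LOG2PI - 0.5 * cov_logdet
        logw = np.empty(n_is_samples)
        for s_idx in range(n_is_samples):
            ll, _ = lik(np.exp(etas[s_idx]), error)
            logw[s_idx] = (ll + _prior_loglik(etas[s_idx], mu, omega) - logq[s_idx]
                           if np.isfinite(ll) else -np.inf)
        m = logw.max()
        w = np.exp(logw - m)
        wbar = w.mean()
        total += m + math.log(wbar)
        var_total += float(w.var() / (n_is_samples * wbar ** 2))

    value = -2.0 * total
    fit.minus2LL = value
    fit.minus2LL_method = "importance_sampling"
    fit.minus2LL_se = 2.0 * math.sqrt(var_total)
    fit.diagnostics["is_proposal_fallbacks"] = n_fallback
    fit.diagnostics["is_n_samples"] = n_is_samples
    return value


# ---------------------------------------------------------------------------
# empirical-Bayes individual fits
# ---------------------------------------------------------------------------


def individual_fits(fit: FitResult, cohort: Cohort, model: StructuralModel | str,
                    dense: int = 0):
    """Conditional-mode individual parameters and predicted trajectories.

    Returns ``(frame, eta_modes)``: a tidy DataFrame with one row per
    observation (plus ``dense`` extra prediction-only rows per subject when
    requested) and the (N, p) array of conditional modes on the log scale.
    """
    import pandas as pd

    if isinstance(model, str):
        model = get_model(model)
    if fit.data_hash != cohort.data_hash():
        raise ConfigurationError("fit and cohort do not match")
    rows = []
    modes = np.empty_like(fit.individual_eta)
    for i, subject in enumerate(cohort.subjects):
        lik = _SubjectLik(subject, model)
        mode = _conditional_mode(lik, fit.individual_eta[i], fit.mu, fit.omega, fit.error)
        modes[i] = mode
        phi = np.exp(mode)
        pred = model.predict(subject.times, phi, subject.regimen)
        for t, y, fhat in zip(subject.times, subject.volumes, pred):
            rows.append((subject.id, subject.group, float(t), float(y), float(fhat)))
        if dense > 1:
            tgrid = np.linspace(subject.times[0], subject.times[-1], dense)
            for t, fhat in zip(tgrid, model.predict(tgrid, phi, subject.regimen)):
                rows.append((subject.id, subject.group, float(t), np.nan, float(fhat)))
    frame = pd.DataFrame(rows, columns=["subject_id", "group", "time_day",
                                        "observed_mm3", "predicted_mm3"])
    return frame, modes
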