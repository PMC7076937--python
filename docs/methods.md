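# Methods

## Scientific setting

`tumornlme` models longitudinal tumor-volume series from two-arm preclinical
chemotherapy experiments: untreated controls and animals receiving a single
intravenous bolus (cisplatin-like) at day 0.  The package provides the
structural models, a nonlinear mixed-effects (NLME) estimator, information-
criterion model comparison, and a synthetic-cohort generator that stands in
for animal data, so the entire analysis is reproducible end to end from a
seed.

## Structural models

**Biphasic tumor growth function (TGF).**  Unperturbed growth follows

    dZ1/dt = lambda0 * Z1 / [1 + ((lambda0/lambda1) * V)^psi]^(1/psi)

which is exponential at rate `lambda0` (1/day) for small volumes and linear
with slope `lambda1` (mm^3/day) for large ones; `psi` (dimensionless, >= 1)
sets the sharpness of the switch, which happens around V* = lambda1/lambda0.
There is no plateau: the model suits experiments that stop at a welfare
threshold long before any saturation.  `psi` is held fixed at 20 by default —
it is weakly identifiable from volume data — and is a model-level constant
rather than an individual parameter.

**Transit-chain (perturbed) model.**  Drug at concentration
`c(t) = D exp(-ke (t - t_dose))` (zero before the bolus) moves proliferating
cells into a chain of n "damaged" compartments at rate `k1 c(t) Z1`; damaged
cells advance through the chain at rate `k2` and are eliminated from its end.
Observed volume is the sum of all compartments.  The chain length n is
arbitrary (`simeoni-1/2/3` in the model registry); the chain encodes the lag
between exposure and cell loss.  Dose units are arbitrary: `k1` absorbs the
concentration scale, and the default regimen for treated synthetic subjects
is a unit dose at day 0 with `ke` = 1/day.

**Explicit-delay variant.**  The chain is replaced by a single damaged
compartment whose clearance is lagged:

    dZ2/dt = k1 c(t) Z1 - k2 * Z2(t - t2),      Z2(t) = 0 for t < 0.

Note the clearance term is *linear delayed feedback*: for `k2 * t2 > 1/e` the
decay of Z2 is oscillatory, and Z2 transiently undershoots zero.  This is a
property of the published model equations, not a solver artifact; with the
default generator values (`k2` = 0.5/day, `t2` = 2 days, so `k2 t2` = 1) the
undershoot is a few percent of the peak damaged mass and total volume stays
positive in any realistic regime.  Predicted volumes are floored at zero
before the observation layer.  The non-negativity guard on compartments
applies to the transit-chain ODE only, where negativity genuinely indicates
solver failure.

**Classic growth laws.**  Generalized logistic `aV(1-(V/K)^nu)`, Gompertz
`aV ln(beta V)` and von Bertalanffy `aV^gamma - bV` are implemented through
their closed-form solutions (each is verified against adaptive integration of
its own differential form in the test suite).  As written, the Gompertz form
grows only on the branch `beta V0 > 1`; starting values supplied by the
pipeline respect this.

## Numerical integration

The transit-chain system is integrated with adaptive RK45 (default
rtol = atol = 1e-8), restarting at the dose time so step-size control never
straddles the concentration kink.  Zero-dose subjects take an exact shortcut:
with no kill flux every perturbed variant reduces to the 1-D growth chain.

The delay system is integrated by the method of steps: the horizon is cut at
every lag multiple (plus dose-time images under the lag), and each window is
advanced with breakpoint-aligned classical RK4 (default target step 0.05 day)
using a cubic-Hermite interpolant of the already-computed solution as
history; the step never exceeds the lag, so history lookups always land in
the computed past, and history before time 0 is identically zero.  A fixed-
order method was chosen over per-window adaptive restarts deliberately: the
system is smooth and non-stiff within windows, the cost of adaptive solving
here is dominated by per-restart overhead, and step-halving plus an
independent fixed-step Heun oracle bound the solver's relative error near
1e-7 at the default step — three orders of magnitude inside the 1e-3
acceptance tolerance.  Lags below 1e-6 day fall back to the exactly nested
one-compartment ODE.

## Statistical model

Observations follow `y_ij = f(t_ij, phi_i) + (a + b f) e_ij`, `e_ij ~ N(0,
sigma^2)`, with `sigma` fixed to 1 so its scale is absorbed into the additive
(`a`, mm^3) and proportional (`b`) residual scales — the parameterization is
otherwise not identifiable.  Individual parameters are log-normal:
`phi_i = exp(mu + lambda_i)`, `lambda_i ~ N(0, Omega)` with diagonal Omega by
default (the data carry little information about correlations at these
sample sizes; a full-Omega extension was deliberately left out of scope).

### SAEM estimator

The likelihood is maximized by stochastic-approximation EM:

- **E-step:** per subject, random-walk Metropolis on `eta_i = log phi_i`,
  proposing the growth parameters (lambda0, lambda1, V0 or the classic-law
  parameters) and the drug parameters (k1, k2, t2) as separate blocks — they
  live on very different posterior geometries.  For untreated subjects the
  drug block has no likelihood term, so it is drawn exactly from its
  conditional (the population prior) at zero cost.  Proposal scales adapt
  toward a 20–45% acceptance band during the exploratory phase.
- **Stochastic approximation:** step size 1 for the exploratory phase, then
  `1/k^0.7` during smoothing.
- **M-step:** closed form for `mu` and the Omega diagonal; the residual
  scales solve a 2-D Nelder–Mead problem on smoothed per-observation
  predictions and squared residuals each iteration (closed form in the pure
  additive / proportional cases).  Cached subject log-densities are refreshed
  after every error-scale update so Metropolis ratios never mix error models.
- **Annealing:** during the exploratory phase, variance components and error
  scales may shrink by at most ~5% per iteration.  Without this constraint
  the estimator exhibits the classic early-collapse pathology (Omega -> 0
  freezes the sampler at its starting point).
- **Initialization:** rough per-subject Nelder–Mead ML fits (restricted to
  each subject's informative blocks) seed the individual etas; their medians
  and MAD-based spreads (clipped to [0.1, 0.5]) seed `mu` and `omega`.
  Robust statistics matter here: individual fits of short noisy series
  scatter heavily.

Profiles: `full` = 300 exploratory + 200 smoothing iterations, 2 sweeps per
subject per iteration, 1e4 importance-sampling draws; `fast` = 200 + 100
iterations with 300–400 draws and coarser solvers (fixed-step RK4 kernels,
delay step 0.1 day).  The fast profile is the package's desk-scale default
for the simulation experiments and the acceptance script; all problem sizes
there (N = 40 cohorts, 5-seed replications) are the package's own choices
for a reproducible desk-scale analogue of the emulated study.

A finite-sample identifiability caveat, found while validating the
estimator and worth stating plainly: with 19 treated subjects, the drug
parameters (k1, k2, t2) of the delay model are only weakly jointly
identified.  On some simulated cohorts the exact maximum-likelihood point
sits 20–30% away from the generating k1 with a compressed omega_k1 — and has
a *better* marginal likelihood than the generating values (verified by
importance sampling; differences of ~20 units of -2LL, far beyond Monte-
Carlo error).  Very long SAEM runs dutifully find those points.  Parameter-
recovery checks in this package therefore describe estimates at the
moderate default iteration budget, and recovery of drug parameters should be
interpreted with this caveat at realistic arm sizes.

Parameters with random effects toggled off keep their omega pinned at a
small constant (0.05) and still update `mu` through the same machinery; this
is a deliberate simplification over a separate fixed-effect-only estimator.

### Marginal likelihood

`estimate_minus2LL` integrates the random effects per subject by importance
sampling (default 1e4 draws) from a Gaussian proposal centered at the
conditional mode with covariance from the inverse numeric Hessian (falling
back to a prior-scaled diagonal if the Hessian is not positive definite) and
reports a Monte-Carlo standard error.  With Omega = 0 the integral collapses
and the exact value is returned.  `fit_population` itself records a Laplace
approximation at the smoothed individual modes (or, in the fast profile, a
conditional placeholder that the importance-sampling pass overwrites).
A Gauss–Hermite quadrature oracle on an analytic toy model pins the
estimator's accuracy in the test suite.

### Empirical-Bayes individual fits

Conditional modes are found per subject by Nelder–Mead started from the
SAEM-smoothed etas; predicted trajectories are exported in tidy CSV.

## Information criteria

AIC = -2LL + 2k; AICc adds `2k(k+1)/(n-k-1)` with n = number of
observations; BIC penalizes `k ln(m)` with m = number of *subjects* by
default — the sample size at the level the random effects enter, and the
convention whose arithmetic matches the published tables this package
mirrors (a flag switches to observations).  k counts fixed effects +
estimated random-effect variances + residual-error parameters.  Evidence
weights `exp(-Delta_j/2)` are normalized shift-stably.  The bundled published
tables are reproduced from their *printed* IC values because the printed
parameter counts are not fully internally consistent (the AIC, AICc and BIC
gaps imply different k for some rows); the package computes its own criteria
from explicit (k, n, N) definitions and records them in every table's
metadata.

## Synthetic-cohort generator

The generator emulates the design of the mirrored study: 21 controls + 19
treated, measurement on a repeating 5-on/2-off daily schedule (weekend gaps;
holidays ignored), enrolment only below 700 mm^3, and censoring at the first
*observed* volume >= 2500 mm^3 (that observation retained).  Default
population values are stand-ins — the study's fitted parameters were never
published — chosen once to give kinetics of the right shape: typical
lambda0 = 0.25/day (about a 4-day initial doubling), lambda1 = 120 mm^3/day,
V0 = 200 mm^3, k1 = 0.8 per unit concentration per day (visible but
heterogeneous regression), k2 = 0.5/day, t2 = 2 days, ke = 1/day; log-normal
inter-individual sds 0.2–0.4; residual scales a = 20 mm^3, b = 0.1.  With a
42-day horizon these produce roughly 18 observations per control (the study
reports 386/21) and 20 per treated animal before censoring.  Negative
observation draws are resampled by default (truncation available behind a
flag).  True individual parameters are stored on synthetic subjects for
direct recovery tests; the fitter never reads them.

What the generator does *not* emulate: holiday gaps, measurement rounding,
multiple tumors per animal, dropout for causes other than the volume
threshold, and any drift in measurement technique.  Passing recovery tests
therefore demonstrate correctness of the estimator under the stated model,
not robustness to real-data artifacts.

## Known limitations

- Standard errors of population estimates (Fisher information) are not
  computed.
- Omega is diagonal; no covariate or between-occasion variability models.
- The SAEM fast profile can misestimate weakly-identified components on
  unlucky cohorts (e.g., the linear slope lambda1 when many subjects are
  censored while still near-exponential); the acceptance experiments
  therefore assert majority behaviour across seed replicates rather than
  per-seed success.
- Repeated dosing and richer PK models are out of scope.
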