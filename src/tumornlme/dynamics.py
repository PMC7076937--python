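"""Numerical integration of the tumor-growth systems.

Two solvers are provided:

- :func:`solve_ode` integrates the transit-chain system with scipy's adaptive
  RK45 (restarting at the dose time so step-size control never straddles the
  concentration kink).
- :func:`solve_dde` integrates the constant-lag delay variant by the method of
  steps: the horizon is cut at every lag multiple (and every dose-time image
  under the lag), and each window is integrated with breakpoint-aligned
  classical RK4 using a cubic-Hermite interpolant of the already-computed
  solution as the history.  Step size never exceeds the lag, so every history
  lookup lands in the computed past.  The systems are smooth and non-stiff
  within windows, which a fixed-order method handles accurately and cheaply;
  accuracy is verified in the test suite against a brute-force fixed-step
  method-of-steps oracle and against the t2 -> 0 nesting with the adaptive
  ODE path.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .errors import SolverError
from .models import DoseRegimen, SimeoniParams

__all__ = ["Trajectory", "solve_ode", "solve_ode_rk4", "solve_dde"]

#: default absolute/relative tolerances (mm^3 / relative) for the adaptive path
RTOL = 1e-8
ATOL = 1e-8

#: default RK4 target step (days) for the delay solver
DDE_STEP = 0.05


@dataclass
class Trajectory:
    """A solution sampled at requested observation times."""

    times: np.ndarray  # strictly increasing, days
    volumes: np.ndarray  # total volume V(t), mm^3, >= 0
    compartments: np.ndarray | None = None  # (n_times, n_states)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise SolverError("trajectory times must be strictly increasing")
        if not np.all(np.isfinite(self.volumes)):
            raise SolverError("non-finite volumes in trajectory")


def _clip_states(z: np.ndarray, atol: float) -> np.ndarray:
    """Zero sub-tolerance negative excursions; large negatives are a failure."""
    if np.any(z < -10.0 * atol):
        raise SolverError(f"negative compartment beyond tolerance: min={z.min():.3e}")
    return np.clip(z, 0.0, None)


def _make_transit_rhs(params: SimeoniParams, regimen: DoseRegimen):
    """Scalar-math closure equivalent to :func:`~tumornlme.models.simeoni_rhs`
    (the public operation carries validation and array overhead the inner
    solver loop cannot afford)."""
    l0, l1, psi = params.lambda0, params.lambda1, params.psi
    k1, k2 = params.k1, params.k2
    amount, ke, td = regimen.dose_amount, regimen.ke, regimen.dose_time
    inv_ratio = l0 / l1

    def rhs(t, z):
        z1 = z[0] if z[0] > 0.0 else 0.0
        v = float(z.sum())
        x = inv_ratio * (v if v > 0.0 else 0.0)
        if x <= 0.0:
            den = 1.0
        else:
            lx = psi * math.log(x)
            den = x if lx > 700.0 else (1.0 + math.exp(lx)) ** (1.0 / psi)
        c = amount * math.exp(-ke * (t - td)) if (amount > 0.0 and t >= td) else 0.0
        kill = k1 * c * z1
        dz = np.empty_like(z)
        dz[0] = l0 * z1 / den - kill
        dz[1] = kill - k2 * z[1]
        for j in range(2, z.size):
            dz[j] = k2 * (z[j - 1] - z[j])
        return dz

    return rhs


def solve_ode(params: SimeoniParams, regimen: DoseRegimen, times,
              rtol: float = RTOL, atol: float = ATOL) -> Trajectory:
    """Integrate the transit-chain system from Z = (V0, 0, ..., 0) at t = 0
    and sample total volume at ``times``."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(times < 0):
        raise SolverError("times must be a non-empty 1-D array of days >= 0")
    t_end = float(times[-1])
    y0 = np.zeros(1 + params.n_transit)
    y0[0] = params.V0
    rhs = _make_transit_rhs(params, regimen)

    # integration restarts at the dose time to protect step-size control
    breaks = [0.0]
    if 0.0 < regimen.dose_time < t_end and regimen.dose_amount > 0:
        breaks.append(regimen.dose_time)
    breaks.append(max(t_end, 1e-12))

    segments = []
    y = y0
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        t_eval = times[(times >= lo) & (times <= hi)]
        # always carry the state to `hi`; t_eval may be empty inside a segment
        sol = solve_ivp(
            rhs, (lo, hi), y,
            method="RK45", rtol=rtol, atol=atol, dense_output=True,
        )
        if not sol.success:
            raise SolverError(f"ODE integration failed on [{lo}, {hi}]: {sol.message}")
        if t_eval.size:
            segments.append((t_eval, sol.sol(t_eval).T))
        y = sol.y[:, -1]

    if times[0] == 0.0 and (not segments or segments[0][0][0] != 0.0):
        segments.insert(0, (np.array([0.0]), y0[None, :]))
    zs = np.vstack([s for _, s in segments])
    ts = np.concatenate([t for t, _ in segments])
    # times may repeat across segment boundaries; deduplicate preserving order
    keep = np.concatenate([[True], np.diff(ts) > 0])
    ts, zs = ts[keep], zs[keep]
    zs = _clip_states(zs, atol)
    return Trajectory(times=ts, volumes=zs.sum(axis=1), compartments=zs)


def solve_ode_rk4(params: SimeoniParams, regimen: DoseRegimen, times,
                  step: float = 0.05) -> Trajectory:
    """Fixed-step RK4 alternative to :func:`solve_ode` for the transit chain.

    Used by the fast fitting profile, where the per-call overhead of the
    adaptive integrator dominates; agreement with the adaptive path is
    cross-checked in the test suite (relative error ~1e-7 at the default
    step for realistic parameters).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(times < 0):
        raise SolverError("times must be a non-empty 1-D array of days >= 0")
    if not _kernels.HAVE_NUMBA:
        return solve_ode(params, regimen, times)
    zs = _kernels.transit_rk4(
        params.lambda0, params.lambda1, params.psi, params.k1, params.k2,
        params.V0, params.n_transit, regimen.dose_amount, regimen.ke,
        regimen.dose_time, times, step)
    if not np.all(np.isfinite(zs)):
        raise SolverError("RK4 integration diverged")
    zs = _clip_states(zs, 1e-6)
    return Trajectory(times=times, volumes=zs.sum(axis=1), compartments=zs)


# ---------------------------------------------------------------------------
# delay solver: method of steps with breakpoint-aligned RK4
# ---------------------------------------------------------------------------


class _History:
    """Cubic-Hermite interpolant of the accumulated (t, Z2, dZ2) grid."""

    def __init__(self) -> None:
        self.t: list[float] = []
        self.z2: list[float] = []
        self.f2: list[float] = []

    def append(self, t: float, z2: float, f2: float) -> None:
        self.t.append(t)
        self.z2.append(z2)
        self.f2.append(f2)

    def __call__(self, s: float) -> float:
        if s < 0.0:
            return 0.0  # stated pre-treatment history
        t = self.t
        i = bisect_right(t, s) - 1
        if i >= len(t) - 1:
            return self.z2[-1]
        if i < 0:
            return self.z2[0]
        h = t[i + 1] - t[i]
        x = (s - t[i]) / h
        y0, y1, f0, f1 = self.z2[i], self.z2[i + 1], self.f2[i], self.f2[i + 1]
        h00 = (1 + 2 * x) * (1 - x) ** 2
        h10 = x * (1 - x) ** 2
        h01 = x * x * (3 - 2 * x)
        h11 = x * x * (x - 1)
        return h00 * y0 + h10 * h * f0 + h01 * y1 + h11 * h * f1


def solve_dde(params: SimeoniParams, regimen: DoseRegimen, times,
              step: float = DDE_STEP) -> Trajectory:
    """Integrate the explicit-delay system by the method of steps.

    State is (Z1, Z2) with Z2(0) = 0 and Z2 identically 0 before time 0.
    For lags below 1e-6 day the system nests exactly into the one-transit
    chain and the adaptive ODE path is used instead.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(times < 0):
        raise SolverError("times must be a non-empty 1-D array of days >= 0")
    t2 = params.t2
    if t2 < 1e-6:
        ode = solve_ode(params.with_(n_transit=1, t2=0.0), regimen, times)
        return ode

    t_end = float(times[-1])
    if t_end == 0.0:
        z0 = np.tile([params.V0, 0.0], (times.size, 1))
        return Trajectory(times=times, volumes=z0.sum(axis=1), compartments=z0)
    # window boundaries: lag multiples and dose-time images under the lag
    bounds = {0.0, t_end}
    m = 1
    while m * t2 < t_end:
        bounds.add(m * t2)
        m += 1
    if regimen.dose_amount > 0 and regimen.dose_time > 0:
        s = regimen.dose_time
        while s < t_end:
            bounds.add(s)
            s += t2
    bounds = sorted(bounds)

    if _kernels.HAVE_NUMBA:
        zs = _kernels.dde_rk4(
            params.lambda0, params.lambda1, params.psi, params.k1, params.k2,
            t2, params.V0, regimen.dose_amount, regimen.ke, regimen.dose_time,
            np.asarray(bounds, dtype=float), step, times)
        if not np.all(np.isfinite(zs)):
            raise SolverError("delay integration diverged")
        vols = np.clip(zs.sum(axis=1), 0.0, None)
        return Trajectory(times=times, volumes=vols, compartments=zs)

    hist = _History()
    l0, l1, psi = params.lambda0, params.lambda1, params.psi
    k1, k2 = params.k1, params.k2
    amount, ke, td = regimen.dose_amount, regimen.ke, regimen.dose_time
    inv_ratio = l0 / l1
    exp, logf = math.exp, math.log

    def rhs(t: float, z1: float, z2: float) -> tuple[float, float]:
        z1p = z1 if z1 > 0.0 else 0.0
        v = z1 + z2
        x = inv_ratio * (v if v > 0.0 else 0.0)
        if x <= 0.0:
            den = 1.0
        else:
            lx = psi * logf(x)
            den = x if lx > 700.0 else (1.0 + exp(lx)) ** (1.0 / psi)
        c = amount * exp(-ke * (t - td)) if (amount > 0.0 and t >= td) else 0.0
        kill = k1 * c * z1p
        return l0 * z1p / den - kill, kill - k2 * hist(t - t2)

    z1, z2 = params.V0, 0.0
    f1, f2 = rhs(0.0, z1, z2)
    hist.append(0.0, z2, f2)
    grid_t = [0.0]
    grid_z1 = [z1]
    grid_f1 = [f1]

    for lo, hi in zip(bounds[:-1], bounds[1:]):
        n = max(1, math.ceil((hi - lo) / step))
        h = (hi - lo) / n
        for i in range(n):
            t = lo + i * h
            a1, a2 = f1, f2  # FSAL: derivative at the current point
            b1, b2 = rhs(t + h / 2, z1 + h / 2 * a1, z2 + h / 2 * a2)
            c1, c2 = rhs(t + h / 2, z1 + h / 2 * b1, z2 + h / 2 * b2)
            d1, d2 = rhs(t + h, z1 + h * c1, z2 + h * c2)
            z1 += h / 6 * (a1 + 2 * b1 + 2 * c1 + d1)
            z2 += h / 6 * (a2 + 2 * b2 + 2 * c2 + d2)
            tn = t + h
            f1, f2 = rhs(tn, z1, z2)
            hist.append(tn, z2, f2)
            grid_t.append(tn)
            grid_z1.append(z1)
            grid_f1.append(f1)
            if not (math.isfinite(z1) and math.isfinite(z2)):
                raise SolverError(f"delay integration diverged at t={tn:.3f}")

    # sample requested times by cubic Hermite interpolation on the dense grid
    def hermite(ts, ys, fs, s):
        i = min(max(bisect_right(ts, s) - 1, 0), len(ts) - 2)
        hh = ts[i + 1] - ts[i]
        x = (s - ts[i]) / hh
        return ((1 + 2 * x) * (1 - x) ** 2 * ys[i] + x * (1 - x) ** 2 * hh * fs[i]
                + x * x * (3 - 2 * x) * ys[i + 1] + x * x * (x - 1) * hh * fs[i + 1])

    t_lo, t_hi = grid_t[0], grid_t[-1]
    zs = np.empty((times.size, 2))
    for j, s in enumerate(np.clip(times, t_lo, t_hi)):
        zs[j, 0] = hermite(grid_t, grid_z1, grid_f1, s)
        zs[j, 1] = hist(s)
    vols = np.clip(zs.sum(axis=1), 0.0, None)  # transient Z2 < 0 is model-intrinsic
    return Trajectory(times=times, volumes=vols, compartments=zs)
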