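"""Numba-compiled integration kernels.

These are exact ports of the inner loops in :mod:`tumornlme.dynamics`
(classical RK4, breakpoint-aligned; cubic-Hermite history for the delay
system).  They exist purely for speed inside estimation loops — the pure
Python implementations remain the reference and the two are cross-checked in
the test suite.  If numba is unavailable the package falls back to the
Python paths transparently.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap(a[0]) if a and callable(a[0]) else wrap


@njit(cache=False)
def _tgf_rate(z1, v, l0, inv_ratio, psi):
    z1p = z1 if z1 > 0.0 else 0.0
    x = inv_ratio * (v if v > 0.0 else 0.0)
    if x <= 0.0:
        den = 1.0
    else:
        lx = psi * np.log(x)
        den = x if lx > 700.0 else (1.0 + np.exp(lx)) ** (1.0 / psi)
    return l0 * z1p / den


@njit(cache=False)
def _conc(t, amount, ke, td):
    if amount > 0.0 and t >= td:
        return amount * np.exp(-ke * (t - td))
    return 0.0


@njit(cache=False)
def transit_rk4(l0, l1, psi, k1, k2, v0, n_comp, amount, ke, td, times, h_target):
    """Fixed-step RK4 for the transit chain, stepping exactly between the
    requested output times (no interpolation needed)."""
    inv_ratio = l0 / l1
    nz = n_comp + 1
    z = np.zeros(nz)
    z[0] = v0
    dz = np.empty(nz)
    k_a = np.empty(nz)
    k_b = np.empty(nz)
    k_c = np.empty(nz)
    k_d = np.empty(nz)
    ztmp = np.empty(nz)
    out = np.empty((times.size, nz))
    t = 0.0
    j0 = 0
    if times[0] == 0.0:
        out[0] = z
        j0 = 1
    for j in range(j0, times.size):
        gap = times[j] - t
        nsteps = int(np.ceil(gap / h_target))
        if nsteps < 1:
            nsteps = 1
        h = gap / nsteps
        for _ in range(nsteps):
            for stage in range(4):
                if stage == 0:
                    ts = t
                    for m in range(nz):
                        ztmp[m] = z[m]
                elif stage == 1 or stage == 2:
                    ts = t + 0.5 * h
                    kk = k_a if stage == 1 else k_b
                    for m in range(nz):
                        ztmp[m] = z[m] + 0.5 * h * kk[m]
                else:
                    ts = t + h
                    for m in range(nz):
                        ztmp[m] = z[m] + h * k_c[m]
                v = 0.0
                for m in range(nz):
                    v += ztmp[m]
                c = _conc(ts, amount, ke, td)
                kill = k1 * c * (ztmp[0] if ztmp[0] > 0.0 else 0.0)
                dz[0] = _tgf_rate(ztmp[0], v, l0, inv_ratio, psi) - kill
                dz[1] = kill - k2 * ztmp[1]
                for m in range(2, nz):
                    dz[m] = k2 * (ztmp[m - 1] - ztmp[m])
                if stage == 0:
                    for m in range(nz):
                        k_a[m] = dz[m]
                elif stage == 1:
                    for m in range(nz):
                        k_b[m] = dz[m]
                elif stage == 2:
                    for m in range(nz):
                        k_c[m] = dz[m]
                else:
                    for m in range(nz):
                        k_d[m] = dz[m]
            for m in range(nz):
                z[m] += h / 6.0 * (k_a[m] + 2.0 * k_b[m] + 2.0 * k_c[m] + k_d[m])
            t += h
        out[j] = z
    return out


@njit(cache=False)
def _hist_z2(ts, z2s, f2s, count, s):
    """Cubic-Hermite interpolation of Z2 over the filled grid prefix."""
    if s < 0.0:
        return 0.0
    lo, hi = 0, count - 1
    if s >= ts[hi]:
        return z2s[hi]
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ts[mid] <= s:
            lo = mid
        else:
            hi = mid
    h = ts[lo + 1] - ts[lo]
    x = (s - ts[lo]) / h
    return ((1.0 + 2.0 * x) * (1.0 - x) ** 2 * z2s[lo]
            + x * (1.0 - x) ** 2 * h * f2s[lo]
            + x * x * (3.0 - 2.0 * x) * z2s[lo + 1]
            + x * x * (x - 1.0) * h * f2s[lo + 1])


@njit(cache=False)
def dde_rk4(l0, l1, psi, k1, k2, t2, v0, amount, ke, td, bounds, h_target, times):
    """Method-of-steps RK4 for the delay system; returns states at `times`."""
    inv_ratio = l0 / l1
    nseg = bounds.size - 1
    max_steps = 1
    for s in range(nseg):
        max_steps += int(np.ceil((bounds[s + 1] - bounds[s]) / h_target))
    ts = np.empty(max_steps)
    z1s = np.empty(max_steps)
    z2s = np.empty(max_steps)
    f1s = np.empty(max_steps)
    f2s = np.empty(max_steps)

    z1, z2 = v0, 0.0
    # derivative at t=0
    c = _conc(0.0, amount, ke, td)
    kill = k1 * c * z1
    f1 = _tgf_rate(z1, z1 + z2, l0, inv_ratio, psi) - kill
    f2 = kill - k2 * _hist_z2(ts, z2s, f2s, 1, -t2)
    ts[0], z1s[0], z2s[0], f1s[0], f2s[0] = 0.0, z1, z2, f1, f2
    count = 1

    for s in range(nseg):
        lo, hi = bounds[s], bounds[s + 1]
        nsteps = int(np.ceil((hi - lo) / h_target))
        if nsteps < 1:
            nsteps = 1
        h = (hi - lo) / nsteps
        for i in range(nsteps):
            t = lo + i * h
            a1, a2 = f1, f2
            # stage 2
            tb = t + 0.5 * h
            y1, y2 = z1 + 0.5 * h * a1, z2 + 0.5 * h * a2
            c = _conc(tb, amount, ke, td)
            kill = k1 * c * (y1 if y1 > 0.0 else 0.0)
            b1 = _tgf_rate(y1, y1 + y2, l0, inv_ratio, psi) - kill
            b2 = kill - k2 * _hist_z2(ts, z2s, f2s, count, tb - t2)
            # stage 3
            y1, y2 = z1 + 0.5 * h * b1, z2 + 0.5 * h * b2
            kill = k1 * c * (y1 if y1 > 0.0 else 0.0)
            c1 = _tgf_rate(y1, y1 + y2, l0, inv_ratio, psi) - kill
            c2 = kill - k2 * _hist_z2(ts, z2s, f2s, count, tb - t2)
            # stage 4
            td_ = t + h
            y1, y2 = z1 + h * c1, z2 + h * c2
            c = _conc(td_, amount, ke, td)
            kill = k1 * c * (y1 if y1 > 0.0 else 0.0)
            d1 = _tgf_rate(y1, y1 + y2, l0, inv_ratio, psi) - kill
            d2 = kill - k2 * _hist_z2(ts, z2s, f2s, count, td_ - t2)

            z1 += h / 6.0 * (a1 + 2.0 * b1 + 2.0 * c1 + d1)
            z2 += h / 6.0 * (a2 + 2.0 * b2 + 2.0 * c2 + d2)
            c = _conc(td_, amount, ke, td)
            kill = k1 * c * (z1 if z1 > 0.0 else 0.0)
            f1 = _tgf_rate(z1, z1 + z2, l0, inv_ratio, psi) - kill
            f2 = kill - k2 * _hist_z2(ts, z2s, f2s, count, td_ - t2)
            ts[count], z1s[count], z2s[count] = td_, z1, z2
            f1s[count], f2s[count] = f1, f2
            count += 1
            if not (np.isfinite(z1) and np.isfinite(z2)):
                return np.full((times.size, 2), np.nan)

    out = np.empty((times.size, 2))
    for j in range(times.size):
        s = times[j]
        if s <= 0.0:
            out[j, 0], out[j, 1] = v0, 0.0
            continue
        if s >= ts[count - 1]:
            out[j, 0], out[j, 1] = z1s[count - 1], z2s[count - 1]
            continue
        lo = 0
        hi = count - 1
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if ts[mid] <= s:
                lo = mid
            else:
                hi = mid
        h = ts[lo + 1] - ts[lo]
        x = (s - ts[lo]) / h
        h00 = (1.0 + 2.0 * x) * (1.0 - x) ** 2
        h10 = x * (1.0 - x) ** 2 * h
        h01 = x * x * (3.0 - 2.0 * x)
        h11 = x * x * (x - 1.0) * h
        out[j, 0] = h00 * z1s[lo] + h10 * f1s[lo] + h01 * z1s[lo + 1] + h11 * f1s[lo + 1]
        out[j, 1] = h00 * z2s[lo] + h10 * f2s[lo] + h01 * z2s[lo + 1] + h11 * f2s[lo + 1]
    return out
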