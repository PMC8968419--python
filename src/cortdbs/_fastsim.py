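"""Compiled single-subject simulation kernel.

The population machinery (Laplace likelihood, SIR, VPC) evaluates on the
order of 1e5 concentration profiles; this module provides a numba-compiled
Dormand-Prince 5(4) integrator for the structural system so those loops
stay tractable on one CPU.  The scipy-based
:func:`cortdbs.structural.simulate_profile` remains the reference
implementation; the two paths are cross-checked in the test suite.

Parameter vector layout (float64, length 12):

    0 CL   1 V_c   2 Q     3 V_p   4 Km      5 Vmax
    6 Kd   7 Bmax  8 NSAlb 9 KR    10 V_delta 11 F

All individual-level scaling (allometry, random effects) happens before
the vector is built.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_PARAMS = 12
(I_CL, I_VC, I_Q, I_VP, I_KM, I_VMAX,
 I_KD, I_BMAX, I_NSALB, I_KR, I_VDELTA, I_F) = range(N_PARAMS)

# Dormand-Prince 5(4) tableau
_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [1 / 5, 0.0, 0.0, 0.0, 0.0, 0.0],
    [3 / 40, 9 / 40, 0.0, 0.0, 0.0, 0.0],
    [44 / 45, -56 / 15, 32 / 9, 0.0, 0.0, 0.0],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0.0, 0.0],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656, 0.0],
])
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0])
_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_B4 = np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640,
                -92097 / 339200, 187 / 2100, 1 / 40])


@njit(cache=True)
def _unbound(a_total, vc, kd, bmax, ns_alb, kr):
    """Nonnegative root of the binding quadratic (cancellation-safe)."""
    if a_total <= 0.0:
        return 0.0
    L = vc * (1.0 + ns_alb + kr)
    b = L * kd + bmax * vc - a_total
    c = -a_total * kd
    disc = np.sqrt(b * b - 4.0 * L * c)
    if b <= 0.0:
        return (-b + disc) / (2.0 * L)
    return (2.0 * c) / (-b - disc)


@njit(cache=True)
def _rhs(y, p, dy):
    a_dep = y[0] if y[0] > 0.0 else 0.0
    a_cen = y[1] if y[1] > 0.0 else 0.0
    ra = p[I_VMAX] * a_dep / (p[I_KM] + a_dep)
    cu = _unbound(a_cen, p[I_VC], p[I_KD], p[I_BMAX], p[I_NSALB], p[I_KR])
    flux = p[I_Q] * (cu - y[2] / p[I_VP])
    dy[0] = -ra
    dy[1] = ra - p[I_CL] * cu - flux
    dy[2] = flux
    dy[3] = p[I_CL] * cu


@njit(cache=True)
def integrate(times, y0, p, rtol, atol):
    """Integrate from t=0 with initial state ``y0`` (4,) and return the
    state matrix (len(times), 4) at the sorted nonnegative output times."""
    n = times.shape[0]
    out = np.empty((n, 4))
    y = y0.copy()
    t = 0.0
    k = np.empty((7, 4))
    ynew = np.empty(4)
    yerr = np.empty(4)
    dy = np.empty(4)
    h = 1e-3
    io = 0
    nsteps = 0
    while io < n and times[io] <= t:
        out[io] = y
        io += 1
    _rhs(y, p, dy)
    for j in range(4):
        k[0, j] = dy[j]
    while io < n:
        nsteps += 1
        if nsteps > 1_000_000:
            # pathological parameters: give up, flag with NaN
            while io < n:
                out[io] = np.nan
                io += 1
            break
        t_target = times[io]
        dt = t_target - t
        if dt <= 1e-12:
            out[io] = y
            io += 1
            continue
        if h > dt:
            h = dt
        # one Dormand-Prince step (FSAL: k[0] holds f(t, y))
        for s in range(1, 6):
            for j in range(4):
                acc = 0.0
                for m in range(s):
                    acc += _A[s, m] * k[m, j]
                ynew[j] = y[j] + h * acc
            _rhs(ynew, p, dy)
            for j in range(4):
                k[s, j] = dy[j]
        for j in range(4):
            acc = 0.0
            for m in range(6):
                acc += _B5[m] * k[m, j]
            ynew[j] = y[j] + h * acc
        _rhs(ynew, p, dy)
        for j in range(4):
            k[6, j] = dy[j]
        errnorm = 0.0
        for j in range(4):
            acc = 0.0
            for m in range(7):
                acc += (_B5[m] - _B4[m]) * k[m, j]
            yj = y[j] if np.abs(y[j]) > np.abs(ynew[j]) else ynew[j]
            sc = atol + rtol * np.abs(yj)
            e = h * acc / sc
            errnorm += e * e
        errnorm = np.sqrt(errnorm / 4.0)
        if not np.isfinite(errnorm):
            # reject and shrink hard; bail out once h underflows
            h *= 0.1
            if h < 1e-13:
                while io < n:
                    out[io] = np.nan
                    io += 1
                break
            continue
        if errnorm <= 1.0:
            t += h
            for j in range(4):
                y[j] = ynew[j]
                k[0, j] = k[6, j]   # FSAL
            while io < n and times[io] <= t + 1e-12:
                out[io] = y
                io += 1
        fac = 0.9 * errnorm ** -0.2 if errnorm > 0.0 else 5.0
        if fac < 0.2:
            fac = 0.2
        elif fac > 5.0:
            fac = 5.0
        h *= fac
        if h > 2.0:
            h = 2.0
        if h < 1e-14 or h != h:
            # step size collapsed (or went NaN): integration failure
            while io < n:
                out[io] = np.nan
                io += 1
            break
    return out


@njit(cache=True)
def observe(states, p):
    """Plasma and whole-blood concentrations (no baselines) from states."""
    n = states.shape[0]
    c_pla = np.empty(n)
    c_dbs = np.empty(n)
    vb = p[I_VC] + p[I_VDELTA]
    for i in range(n):
        a_cen = states[i, 1]
        if a_cen < 0.0:      # keep NaN (failure flag) intact
            a_cen = 0.0
        cu = _unbound(a_cen, p[I_VC], p[I_KD], p[I_BMAX], p[I_NSALB], p[I_KR])
        a_rbc = cu * p[I_VC] * p[I_KR]
        c_pla[i] = (a_cen - a_rbc) / p[I_VC]
        c_dbs[i] = a_cen / vb
    return c_pla, c_dbs


def simulate_observations(times, dose_nmol, p, rtol=1e-6, atol=1e-8):
    """Concentrations (c_pla, c_dbs) at ``times`` after a single oral dose
    at t=0 of ``dose_nmol`` (already in nmol; bioavailability applied via
    p[I_F]).  Baselines are not added here."""
    times = np.ascontiguousarray(times, dtype=np.float64)
    y0 = np.zeros(4)
    y0[0] = p[I_F] * dose_nmol
    states = integrate(times, y0, p, rtol, atol)
    return observe(states, p)
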