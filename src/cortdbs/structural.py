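"""Dose-to-concentration simulation for one individual.

Oral hydrocortisone enters a depot and is absorbed with Michaelis-Menten
kinetics (rate Vmax * A_depot / (Km + A_depot)).  Disposition is a
two-compartment model acting on the *unbound* plasma concentration, which
is obtained at every instant by inverting the whole-blood binding
equilibrium (rapid-equilibrium assumption):

    dA_depot/dt   = -Vmax * A_depot / (Km + A_depot)
    dA_central/dt = +Vmax * A_depot / (Km + A_depot)
                    - CL * Cu - Q * (Cu - A_per / V_p)
    dA_per/dt     = Q * (Cu - A_per / V_p)

where A_central is the *total* central amount (unbound + CBG + albumin +
RBC-associated) and Cu = unbound_from_total(A_central).  Observations:

    C_pla(t) = (A_central - A_RBC) / V_c          + BASE_pla
    C_DBS(t) = A_central / (V_c + V_delta)        + BASE_DBS

with additive constant baselines on each observation scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .binding import BindingParams, BloodGeometry, partition_from_unbound, unbound_from_total
from .params import StructuralParams, allometric_scale, dose_to_nmol

__all__ = ["DoseEvent", "SimProfile", "ode_rhs", "simulate_profile"]


@dataclass(frozen=True)
class DoseEvent:
    """One oral dose; the nmol amount is derived from mg at construction."""

    time: float                 # h
    amount_mg: float            # mg
    amount_nmol: float = field(init=False)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be nonnegative, got {self.time}")
        object.__setattr__(self, "amount_nmol", dose_to_nmol(self.amount_mg))


@dataclass
class SimProfile:
    """Simulated trajectories of one individual (times in h, conc in nmol/L)."""

    times: np.ndarray
    c_pla: np.ndarray
    c_dbs: np.ndarray
    cu: np.ndarray
    a_depot: np.ndarray
    a_central: np.ndarray      # total central amount incl. RBC pool, nmol
    a_per: np.ndarray
    a_elim: np.ndarray         # cumulative eliminated, nmol

    @property
    def cmax_pla(self) -> float:
        return float(np.max(self.c_pla))

    @property
    def cmax_dbs(self) -> float:
        return float(np.max(self.c_dbs))

    def tmax(self, which: str = "dbs") -> float:
        y = self.c_dbs if which == "dbs" else self.c_pla
        return float(self.times[int(np.argmax(y))])


def ode_rhs(state, t, p: StructuralParams, binding: BindingParams,
            geometry: BloodGeometry):
    """Right-hand side of the structural ODE system.

    ``state`` is (A_depot, A_central_total, A_per) in nmol; a fourth
    cumulative-elimination component is appended by the integrator wrapper.
    Tiny negative amounts from the integrator are clamped to zero.
    """
    a_dep = max(state[0], 0.0)
    a_cen = max(state[1], 0.0)
    a_per = state[2]
    rate_abs = p.vmax * a_dep / (p.km + a_dep)
    cu = unbound_from_total(a_cen, binding, geometry)
    flux_per = p.q * (cu - a_per / p.v_p)
    return (
        -rate_abs,
        rate_abs - p.cl * cu - flux_per,
        flux_per,
    )


def simulate_profile(
    doses: Sequence[DoseEvent],
    p: StructuralParams,
    binding: BindingParams,
    geometry: BloodGeometry,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimProfile:
    """Integrate the structural model and evaluate both observation equations.

    Doses deposit F * amount into the depot at their event time; the
    integration restarts at each dose.  ``times`` must be sorted and
    nonnegative.  Raises ``RuntimeError`` with solver diagnostics on
    integration failure.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("need at least one output time")
    if np.any(np.diff(times) < 0) or times[0] < 0:
        raise ValueError("output times must be sorted and nonnegative")

    dose_times = sorted({d.time for d in doses})
    dose_amount = {t: sum(d.amount_nmol for d in doses if d.time == t) for t in dose_times}

    # integration segments split at dose events
    t_end = max(times[-1], dose_times[-1] if dose_times else 0.0)
    breaks = np.unique(np.concatenate([[0.0], dose_times, [t_end]]))

    y = np.zeros(4)  # depot, central, peripheral, eliminated
    out = np.empty((4, times.size))
    filled = 0

    def rhs(t, yv):
        d = ode_rhs(yv[:3], t, p, binding, geometry)
        cu = unbound_from_total(max(yv[1], 0.0), binding, geometry)
        return [d[0], d[1], d[2], p.cl * cu]

    for i in range(len(breaks)):
        t0 = breaks[i]
        # output times equal to a break point report the pre-dose state
        n_exact = int(np.sum(times == t0)) if (i == 0 or t0 in dose_amount or i == len(breaks) - 1) else 0
        for _ in range(n_exact):
            out[:, filled] = y
            filled += 1
        if t0 in dose_amount:
            y[0] += p.f * dose_amount[t0]
        if i == len(breaks) - 1:
            break
        t1 = breaks[i + 1]
        seg = times[(times > t0) & (times < t1)]
        t_eval = np.unique(np.append(seg, t1))
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol,
                        t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{t0}, {t1}]: {sol.message}")
        idx = np.searchsorted(t_eval, seg)
        out[:, filled:filled + seg.size] = sol.y[:, idx]
        filled += seg.size
        y = sol.y[:, -1].copy()
    assert filled == times.size, "internal bookkeeping error mapping output times"

    a_dep, a_cen, a_per, a_elim = np.maximum(out, 0.0)
    cu = np.array([unbound_from_total(a, binding, geometry) for a in a_cen])
    a_rbc = cu * geometry.v_c * binding.kr
    c_pla = (a_cen - a_rbc) / geometry.v_c + p.base_pla
    c_dbs = a_cen / geometry.v_blood + p.base_dbs
    return SimProfile(
        times=times, c_pla=c_pla, c_dbs=c_dbs, cu=cu,
        a_depot=a_dep, a_central=a_cen, a_per=a_per, a_elim=a_elim,
    )
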