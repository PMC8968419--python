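"""Equilibrium partition of cortisol in whole blood.

Total cortisol in whole blood distributes at each instant between four
species: unbound drug (plasma concentration ``Cu``), drug bound to
corticosteroid-binding globulin (CBG; saturable, capacity ``Bmax``,
dissociation constant ``Kd``), drug bound to albumin (linear, coefficient
``NS_Alb``) and drug associated with red blood cells (linear in the unbound
amount, effective coupling ``KR``).  Amounts (nmol) at unbound plasma
concentration Cu are

    A_u   = Cu * V_c
    A_CBG = V_c * Bmax * Cu / (Kd + Cu)
    A_Alb = V_c * NS_Alb * Cu
    A_RBC = V_c * KR * Cu

The plasma concentration pools everything except the RBC-associated
amount over the plasma volume V_c; the whole-blood (DBS) concentration
pools all four species over V_c + V_delta.  Binding is assumed to
equilibrate instantaneously relative to disposition.

The published model reports a raw RBC association constant KaRBC = 6.62
whose exact coupling to the apparent RBC volume is not reproducible from
the printed material; this module therefore works with the *effective*
RBC:unbound amount ratio KR, calibrated against the published fraction
curves (KR ~ 0.92 in both pediatric age groups), and stores the published
value for documentation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from .params import (
    AgeGroup,
    REF_WEIGHT,
    TYPICAL_WEIGHT,
    V_DELTA,
)

__all__ = [
    "BindingParams",
    "BloodGeometry",
    "SpeciesBreakdown",
    "partition_from_unbound",
    "unbound_from_total",
    "species_fractions",
    "plasma_dbs_ratio",
    "calibrate_binding",
    "default_anchors",
    "default_binding_params",
    "typical_geometry",
]


@dataclass(frozen=True)
class BindingParams:
    """Equilibrium constants governing the CBG/albumin/RBC partition."""

    kd: float = 9.71          # CBG dissociation constant, nmol/L
    bmax: float = 0.0         # CBG capacity, nmol/L (plasma referenced)
    ns_alb: float = 4.15      # linear albumin coefficient, dimensionless
    kr: float = 0.0           # effective RBC:unbound amount coupling
    ka_rbc_published: float = 6.62  # published estimate, documentation only

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError(f"Kd must be positive, got {self.kd}")
        for name in ("bmax", "ns_alb", "kr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def linear_coupling(self) -> float:
        """Total linear amount multiplier 1 + NS_Alb + KR."""
        return 1.0 + self.ns_alb + self.kr


@dataclass(frozen=True)
class BloodGeometry:
    """Plasma and apparent RBC volumes of one subject."""

    v_c: float                # central (plasma) volume, L
    v_delta: float            # apparent RBC volume, L
    weight: float             # body weight, kg
    age_group: AgeGroup = AgeGroup.CHILDREN_INFANTS

    def __post_init__(self) -> None:
        if self.v_c <= 0:
            raise ValueError(f"V_c must be positive, got {self.v_c}")
        if self.v_delta < 0:
            raise ValueError(f"V_delta must be nonnegative, got {self.v_delta}")
        if self.weight <= 0:
            raise ValueError(f"weight must be positive, got {self.weight}")

    @property
    def v_blood(self) -> float:
        """Whole-blood volume V_c + V_delta."""
        return self.v_c + self.v_delta


def typical_geometry(group: AgeGroup, v_c_ref: float = 10.6) -> BloodGeometry:
    """Geometry of the typical individual of an age group.

    V_c scales linearly with the group's typical weight (reference 70 kg);
    V_delta is the group estimate and is not scaled.
    """
    group = AgeGroup(group)
    w = TYPICAL_WEIGHT[group]
    return BloodGeometry(
        v_c=v_c_ref * w / REF_WEIGHT,
        v_delta=V_DELTA[group],
        weight=w,
        age_group=group,
    )


@dataclass(frozen=True)
class SpeciesBreakdown:
    """Amounts and concentrations of the four cortisol species at one instant."""

    a_u: float       # unbound amount, nmol
    a_cbg: float     # CBG-bound amount, nmol
    a_alb: float     # albumin-bound amount, nmol
    a_rbc: float     # RBC-associated amount, nmol
    cu: float        # unbound plasma concentration, nmol/L
    c_pla: float     # total plasma concentration, nmol/L
    c_dbs: float     # total whole-blood concentration, nmol/L

    @property
    def total(self) -> float:
        """Total amount in whole blood, nmol."""
        return self.a_u + self.a_cbg + self.a_alb + self.a_rbc


def partition_from_unbound(
    cu: float, p: BindingParams, g: BloodGeometry
) -> SpeciesBreakdown:
    """Species amounts/concentrations at unbound plasma concentration ``cu``."""
    if cu < 0:
        raise ValueError(f"unbound concentration must be nonnegative, got {cu}")
    a_u = cu * g.v_c
    a_cbg = g.v_c * p.bmax * cu / (p.kd + cu)
    a_alb = g.v_c * p.ns_alb * cu
    a_rbc = g.v_c * p.kr * cu
    return SpeciesBreakdown(
        a_u=a_u,
        a_cbg=a_cbg,
        a_alb=a_alb,
        a_rbc=a_rbc,
        cu=cu,
        c_pla=(a_u + a_cbg + a_alb) / g.v_c,
        c_dbs=(a_u + a_cbg + a_alb + a_rbc) / g.v_blood,
    )


def _unbound_from_total(a_total, kd, bmax, ns_alb, kr, v_c):
    """Vectorized positive root of the binding quadratic.

    Total amount A at unbound concentration Cu is
    A = L*Cu + V_c*Bmax*Cu/(Kd + Cu) with L = V_c*(1 + NS_Alb + KR),
    i.e. L*Cu^2 + (L*Kd + Bmax*V_c - A)*Cu - A*Kd = 0.
    The product of the roots is -A*Kd/L <= 0, so exactly one root is
    nonnegative; a cancellation-safe form is used when b <= 0.
    """
    a_total = np.asarray(a_total, dtype=float)
    L = v_c * (1.0 + ns_alb + kr)
    b = L * kd + bmax * v_c - a_total
    c = -a_total * kd
    disc = np.sqrt(b * b - 4.0 * L * c)
    # root via the numerically stable branch: when b > 0 use 2c/(-b - disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        cu = np.where(
            b <= 0.0,
            (-b + disc) / (2.0 * L),
            np.where(c == 0.0, 0.0, (2.0 * c) / (-b - disc)),
        )
    return np.maximum(cu, 0.0)


def unbound_from_total(
    a_total: float, p: BindingParams, g: BloodGeometry
) -> float:
    """Unique Cu >= 0 whose total whole-blood amount equals ``a_total`` nmol."""
    if a_total < 0:
        raise ValueError(f"total amount must be nonnegative, got {a_total}")
    return float(_unbound_from_total(a_total, p.kd, p.bmax, p.ns_alb, p.kr, g.v_c))


def species_fractions(c_blood, p: BindingParams, g: BloodGeometry):
    """Fractions (f_u, f_Alb, f_CBG, f_RBC) of total whole-blood cortisol.

    Accepts a scalar or array whole-blood concentration (nmol/L); fractions
    sum to one.  The linear couplings imply f_Alb = NS_Alb * f_u and
    f_RBC = KR * f_u at every concentration.
    """
    arr = np.asarray(c_blood, dtype=float)
    if np.any(arr < 0):
        raise ValueError("whole-blood concentration must be nonnegative")
    a_total = arr * g.v_blood
    cu = _unbound_from_total(a_total, p.kd, p.bmax, p.ns_alb, p.kr, g.v_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_u = np.where(a_total > 0, cu * g.v_c / a_total, np.nan)
    f_alb = p.ns_alb * f_u
    f_rbc = p.kr * f_u
    f_cbg = 1.0 - f_u - f_alb - f_rbc
    if np.isscalar(c_blood) or arr.ndim == 0:
        return float(f_u), float(f_alb), float(f_cbg), float(f_rbc)
    return f_u, f_alb, f_cbg, f_rbc


def plasma_dbs_ratio(c_blood, p: BindingParams, g: BloodGeometry):
    """Plasma/DBS total concentration ratio at whole-blood concentration
    ``c_blood``; equals (1 + V_delta/V_c) * (1 - f_RBC) and decreases with
    concentration whenever CBG binding saturates (Bmax > 0)."""
    arr = np.asarray(c_blood, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("whole-blood concentration must be positive")
    f_u, f_alb, f_cbg, f_rbc = species_fractions(c_blood, p, g)
    ratio = (1.0 + g.v_delta / g.v_c) * (1.0 - np.asarray(f_rbc))
    if np.isscalar(c_blood) or arr.ndim == 0:
        return float(ratio)
    return ratio


# ---------------------------------------------------------------------------
# Calibration of (Bmax, KR) against published fraction-curve anchors
# ---------------------------------------------------------------------------

_SPECIES_INDEX = {"u": 0, "alb": 1, "cbg": 2, "rbc": 3}


def default_anchors() -> list[tuple[BloodGeometry, float, str, float]]:
    """Endpoint anchors of the published fraction curves.

    Low end (1.8 nmol/L, assay LLOQ): CBG fraction ~90%.  High end (group
    Cmax): RBC and unbound fractions, whose ratio pins the effective RBC
    coupling KR at ~0.92 in both age groups.
    """
    child = typical_geometry(AgeGroup.CHILDREN_INFANTS)
    neo = typical_geometry(AgeGroup.NEONATE)
    return [
        (child, 1.8, "cbg", 0.90),
        (child, 180.0, "rbc", 0.083),
        (child, 180.0, "u", 0.090),
        (neo, 820.0, "rbc", 0.12),
        (neo, 820.0, "u", 0.13),
    ]


def calibrate_binding(
    anchors: Sequence[tuple[BloodGeometry, float, str, float]],
    kd: float = 9.71,
    ns_alb: float = 4.15,
) -> BindingParams:
    """Calibrate (Bmax, KR) to fraction anchors with Kd and NS_Alb fixed.

    Each anchor is ``(geometry, c_blood, species, fraction)`` with species
    one of ``'u' | 'alb' | 'cbg' | 'rbc'``.  The calibration is a
    two-stage deterministic procedure:

    1. KR is fixed by the saturated-end anchors: wherever both the RBC and
       the unbound fraction are anchored at the same (geometry, c_blood),
       their ratio equals KR exactly; KR is the mean of those ratios.
       (If no such pair exists KR joins the least-squares stage.)
    2. Bmax (and KR if still free) minimizes the squared error between
       predicted and anchored fractions on a log grid followed by a
       Nelder-Mead polish.

    Raises ``ValueError`` for an unidentifiable anchor set (fewer than two
    anchors, or all anchors at one species and concentration).
    """
    anchors = list(anchors)
    if len(anchors) < 2:
        raise ValueError("need at least two anchors to calibrate (Bmax, KR)")
    keys = {(round(c, 9), s.lower()) for _, c, s, _ in anchors}
    if len(keys) < 2:
        raise ValueError(
            "anchor set is unidentifiable: all anchors share one species "
            "and concentration"
        )
    for _, c, s, frac in anchors:
        if s.lower() not in _SPECIES_INDEX:
            raise ValueError(f"unknown species {s!r}")
        if not (0.0 < frac < 1.0) or c <= 0:
            raise ValueError("anchors need c_blood > 0 and fraction in (0, 1)")

    # stage 1: KR from paired RBC/unbound anchors at the same point
    pairs: dict[tuple[int, float], dict[str, float]] = {}
    for g, c, s, frac in anchors:
        pairs.setdefault((id(g), c), {})[s.lower()] = frac
    ratios = [
        d["rbc"] / d["u"] for d in pairs.values() if "rbc" in d and "u" in d
    ]
    kr_fixed = float(np.mean(ratios)) if ratios else None

    def residuals(log_bmax: float, kr: float) -> np.ndarray:
        p = BindingParams(kd=kd, bmax=math.exp(log_bmax), ns_alb=ns_alb, kr=kr)
        out = []
        for g, c, s, frac in anchors:
            fr = species_fractions(c, p, g)[_SPECIES_INDEX[s.lower()]]
            out.append(fr - frac)
        return np.asarray(out)

    def objective(x: np.ndarray) -> float:
        kr = kr_fixed if kr_fixed is not None else math.exp(x[1])
        return float(np.sum(residuals(x[0], kr) ** 2))

    # coarse log grid on Bmax (and KR when free), then polish
    grid_b = np.log(np.geomspace(10.0, 1e4, 40))
    if kr_fixed is not None:
        x0 = np.array([min(grid_b, key=lambda lb: objective(np.array([lb])))])
    else:
        grid_k = np.log(np.geomspace(0.05, 20.0, 25))
        best = min(
            ((lb, lk) for lb in grid_b for lk in grid_k),
            key=lambda xy: objective(np.array(xy)),
        )
        x0 = np.asarray(best)
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14})
    kr = kr_fixed if kr_fixed is not None else float(math.exp(res.x[1]))
    return BindingParams(kd=kd, bmax=float(math.exp(res.x[0])), ns_alb=ns_alb, kr=kr)


@lru_cache(maxsize=1)
def default_binding_params() -> BindingParams:
    """Binding parameters calibrated once against the published anchors."""
    return calibrate_binding(default_anchors())
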