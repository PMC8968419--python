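"""Default model parameterization for the hydrocortisone plasma/DBS PK model.

Typical values come from the published population estimate of the extended
whole-blood cortisol model: a two-compartment disposition model with
Michaelis-Menten absorption, saturable binding to corticosteroid-binding
globulin (CBG), linear binding to albumin, and a linear association of
unbound cortisol with red blood cells (RBCs).  Clearances scale with body
weight to the 0.75 power and volumes linearly, both referenced to 70 kg.

Interindividual variability (IIV) is log-normal; a variability reported as
%CV corresponds to a log-scale standard deviation omega through
CV = sqrt(exp(omega^2) - 1).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

#: Hydrocortisone (cortisol) molar mass, g/mol.
HC_MOLAR_MASS = 362.46

#: Reference body weight for allometric scaling, kg.
REF_WEIGHT = 70.0

#: Allometric exponents on clearances and volumes.
ALLOMETRIC_EXP_CL = 0.75
ALLOMETRIC_EXP_V = 1.0

#: Lower limits of quantification, nmol/L.
LLOQ_PLASMA = 14.1
LLOQ_DBS = 1.8


class AgeGroup(str, enum.Enum):
    """Dichotomous age-group covariate selecting the apparent RBC volume."""

    ADULT = "adult"
    CHILDREN_INFANTS = "children_infants"
    NEONATE = "neonate"


def cv_to_omega(cv_percent: float) -> float:
    """Log-scale SD omega for a log-normal with the given coefficient of
    variation in percent: omega = sqrt(ln(1 + CV^2))."""
    cv = cv_percent / 100.0
    return math.sqrt(math.log1p(cv * cv))


def omega_to_cv(omega: float) -> float:
    """Inverse of :func:`cv_to_omega`, in percent."""
    return 100.0 * math.sqrt(math.expm1(omega * omega))


@dataclass(frozen=True)
class StructuralParams:
    """Structural PK parameters for one (typical or individual) subject.

    Clearance ``cl`` and intercompartmental clearance ``q`` act on the
    *unbound* plasma concentration; ``v_c``/``v_p`` are central (plasma)
    and peripheral volumes.  Absorption from the depot is Michaelis-Menten
    with maximum rate ``vmax`` (nmol/h) and half-saturation depot amount
    ``km`` (nmol).  Baselines are additive constants on the respective
    observation scale (nmol/L).
    """

    cl: float = 400.0        # unbound clearance, L/h (70 kg reference)
    v_c: float = 10.6        # central volume, L
    q: float = 160.0         # intercompartmental clearance, L/h
    v_p: float = 124.0       # peripheral volume, L
    km: float = 4810.0       # depot amount at half Vmax, nmol
    vmax: float = 21388.0    # maximum absorption rate, nmol/h
    f: float = 1.0           # bioavailability (relative)
    base_pla: float = 0.0    # plasma baseline, nmol/L
    base_dbs: float = 0.0    # DBS (whole blood) baseline, nmol/L

    def __post_init__(self) -> None:
        for name in ("cl", "v_c", "q", "v_p", "km", "vmax", "f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.base_pla < 0 or self.base_dbs < 0:
            raise ValueError("baselines must be nonnegative")


def allometric_scale(p: StructuralParams, weight: float) -> StructuralParams:
    """Scale clearances by (weight/70)^0.75 and volumes by (weight/70)^1.

    ``km``, ``vmax``, ``f`` and the baselines are left unchanged; the
    apparent RBC volume lives in :class:`~cortdbs.binding.BloodGeometry`
    and is estimated per age group, not scaled.
    """
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    s = weight / REF_WEIGHT
    return replace(
        p,
        cl=p.cl * s**ALLOMETRIC_EXP_CL,
        q=p.q * s**ALLOMETRIC_EXP_CL,
        v_c=p.v_c * s**ALLOMETRIC_EXP_V,
        v_p=p.v_p * s**ALLOMETRIC_EXP_V,
    )


def dose_to_nmol(mg: float) -> float:
    """Convert a hydrocortisone dose from mg to nmol."""
    if mg < 0:
        raise ValueError(f"dose must be nonnegative, got {mg} mg")
    return mg * 1e6 / HC_MOLAR_MASS


# Published V_delta per pediatric age group (L) and the typical body weights
# implied by the reported per-kg values (11.1/0.82 and 1.05/0.29 kg).
V_DELTA = {
    AgeGroup.ADULT: 0.0,
    AgeGroup.CHILDREN_INFANTS: 11.1,
    AgeGroup.NEONATE: 1.05,
}
TYPICAL_WEIGHT = {
    AgeGroup.ADULT: REF_WEIGHT,
    AgeGroup.CHILDREN_INFANTS: 11.1 / 0.82,
    AgeGroup.NEONATE: 1.05 / 0.29,
}

#: Typical baselines, nmol/L.
BASE_ADULT_PLA = 15.2
BASE_CHILD_PLA = 9.41
BASE_CHILD_DBS = 4.22


@dataclass(frozen=True)
class PopulationParams:
    """Typical values plus variability terms of the population model.

    ``omega`` maps parameter names to log-scale IIV standard deviations;
    ``sigma_exp`` is the SD of the additive-on-log (exponential) residual
    error, shared across observation types and populations.
    """

    structural: StructuralParams = field(default_factory=StructuralParams)
    kd: float = 9.71          # CBG dissociation constant, nmol/L (fixed)
    ns_alb: float = 4.15      # linear albumin binding coefficient (fixed)
    ka_rbc_published: float = 6.62  # published RBC association constant (doc only)
    kr: float | None = None   # effective RBC:unbound coupling; None = calibrated
    bmax: float | None = None  # CBG capacity, nmol/L; None = calibrated
    v_delta: dict = field(default_factory=lambda: dict(V_DELTA))
    base_adult_pla: float = BASE_ADULT_PLA
    base_child_pla: float = BASE_CHILD_PLA
    base_child_dbs: float = BASE_CHILD_DBS
    omega: dict = field(
        default_factory=lambda: {
            "cl": cv_to_omega(25.8),
            "km": cv_to_omega(55.7),
            "vmax": cv_to_omega(46.5),
            "f": cv_to_omega(36.1),
            "v_delta": cv_to_omega(43.4),
            "base_adult_pla": cv_to_omega(35.3),
            "base_child": cv_to_omega(131.1),  # shared plasma/DBS, fixed
        }
    )
    sigma_exp: float = cv_to_omega(14.4)

    def __post_init__(self) -> None:
        if self.sigma_exp <= 0:
            raise ValueError("sigma_exp must be positive")
        if any(w < 0 for w in self.omega.values()):
            raise ValueError("omegas must be nonnegative")
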