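"""Synthetic study generation.

Emulates the two source designs so the whole pipeline is testable without
clinical data:

* a rich-sampling adult study — 30 dexamethasone-suppressed healthy adults,
  single oral hydrocortisone doses spanning 0.5-20 mg, plasma sampling only,
  constant (suppressed) cortisol baseline;
* a sparse pediatric study — 12 young children (2-6 y), 6 infants
  (28 d-2 y) and 6 term neonates (0-28 d) on their regular 1-4 mg morning
  dose, paired plasma+DBS samples pre-dose and 1 and 4 h post-dose
  (children get two extra samples at 0.5-1.5 h and a late 6 h sample), with
  LLOQ censoring flags at 14.1 nmol/L (plasma) and 1.8 nmol/L (DBS).

Weight-for-age uses coarse bands (neonates 2.5-4.5 kg, infants 4-11 kg,
children 10-22 kg) with log-normal noise — enough statistical structure
for testing, not a growth-chart reproduction.  Dose assignment is
deterministic given the weight band, with neonates receiving the highest
dose per kg, mirroring the phase-3 dosing that produced the high neonatal
concentrations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import DVID_DBS, DVID_PLASMA, REQUIRED_COLUMNS, StudyDataset
from .params import (
    AgeGroup,
    LLOQ_DBS,
    LLOQ_PLASMA,
    PopulationParams,
    dose_to_nmol,
)
from .population import simulate_from_design

__all__ = [
    "Arm", "StudyDesign", "pediatric_design", "adult_design",
    "rich_pediatric_design", "generate_study", "generate_pediatric_study",
    "generate_adult_study", "truth_record", "save_truth", "load_truth",
]


@dataclass(frozen=True)
class Arm:
    """One study arm: who is enrolled, how they are dosed and sampled."""

    label: str
    n_subjects: int
    age_group: AgeGroup
    age_range: tuple          # years
    weight_range: tuple       # kg
    dose_rule: Callable       # (weight, index, rng) -> dose mg
    sampling_times: Callable  # rng -> array of h
    observation_types: tuple  # DVIDs
    lloq: dict                # DVID -> nmol/L


@dataclass(frozen=True)
class StudyDesign:
    arms: tuple

    @property
    def n_subjects(self) -> int:
        return sum(a.n_subjects for a in self.arms)


def _band_weight(age, age_range, weight_range, rng):
    """Weight from linear age interpolation across the band, log-normal noise."""
    lo, hi = age_range
    frac = (age - lo) / (hi - lo) if hi > lo else 0.5
    mid = weight_range[0] + frac * (weight_range[1] - weight_range[0])
    w = mid * math.exp(rng.normal(0.0, 0.08))
    return float(np.clip(w, *weight_range))


def _pediatric_times(extra_early: int = 0, late: bool = False):
    def sample(rng):
        t = [0.0, 1.0, 4.0]
        t += list(np.round(rng.uniform(0.5, 1.5, size=extra_early), 2))
        if late:
            t.append(6.0)
        return np.unique(t)
    return sample


def pediatric_design() -> StudyDesign:
    """Default sparse pediatric design (24 subjects, 108 paired samples)."""
    both = (DVID_PLASMA, DVID_DBS)
    lloq = {DVID_PLASMA: LLOQ_PLASMA, DVID_DBS: LLOQ_DBS}
    return StudyDesign(arms=(
        Arm("children", 12, AgeGroup.CHILDREN_INFANTS, (2.0, 6.0), (10.0, 22.0),
            lambda w, i, rng: 2.0 if w < 16 else 3.0,
            _pediatric_times(extra_early=2, late=True), both, lloq),
        Arm("infants", 6, AgeGroup.CHILDREN_INFANTS, (28 / 365, 2.0), (4.0, 11.0),
            lambda w, i, rng: 1.0 if w < 7 else 2.0,
            _pediatric_times(), both, lloq),
        Arm("neonates", 6, AgeGroup.NEONATE, (0.0, 28 / 365), (2.5, 4.5),
            lambda w, i, rng: 3.0 if w < 3.5 else 4.0,
            _pediatric_times(), both, lloq),
    ))


#: Dose ladder of the adult single-ascending-dose study, mg.
ADULT_DOSES = (0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0)

#: Rich adult sampling grid over 12 h (12 samples incl. pre-dose).
ADULT_TIMES = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0)


def adult_design(n_subjects: int = 30, n_samples: int = len(ADULT_TIMES)) -> StudyDesign:
    times = np.asarray(ADULT_TIMES[:n_samples])
    return StudyDesign(arms=(
        Arm("adults", n_subjects, AgeGroup.ADULT, (18.0, 60.0), (55.0, 100.0),
            lambda w, i, rng: ADULT_DOSES[i % len(ADULT_DOSES)],
            lambda rng: times, (DVID_PLASMA,), {DVID_PLASMA: 0.0}),
    ))


def rich_pediatric_design(n_subjects: int = 50) -> StudyDesign:
    """Rich paired-sampling design for parameter-recovery experiments:
    half children/infants, half neonates, 12 samples over 12 h each."""
    times = np.array([0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 9.0, 12.0])
    both = (DVID_PLASMA, DVID_DBS)
    lloq = {DVID_PLASMA: LLOQ_PLASMA, DVID_DBS: LLOQ_DBS}
    n_ci = n_subjects - n_subjects // 2
    return StudyDesign(arms=(
        Arm("children_infants", n_ci, AgeGroup.CHILDREN_INFANTS,
            (0.5, 6.0), (8.0, 20.0),
            lambda w, i, rng: 2.0 if w < 14 else 3.0,
            lambda rng: times, both, lloq),
        Arm("neonates", n_subjects // 2, AgeGroup.NEONATE,
            (0.0, 28 / 365), (2.5, 4.5),
            lambda w, i, rng: 3.0 if w < 3.5 else 4.0,
            lambda rng: times, both, lloq),
    ))


def pooled_recovery_design(n_adult: int = 20, n_pediatric: int = 30) -> StudyDesign:
    """Pooled adult + pediatric rich design for parameter recovery.

    Mirrors the source model's pooled estimation data: the adult
    ascending-dose arm spans the Michaelis-Menten absorption range and
    anchors the bioavailability scale, without which a finite-sample shift
    in the F random effects is near-unidentifiable from the volume terms;
    the pediatric arms carry the V_delta/DBS information.
    """
    return StudyDesign(arms=adult_design(n_adult).arms
                       + rich_pediatric_design(n_pediatric).arms)


def _skeleton(design: StudyDesign, rng) -> pd.DataFrame:
    """Dose/observation records with covariates but no DV yet."""
    rows = []
    sid = 0
    for arm in design.arms:
        for i in range(arm.n_subjects):
            sid += 1
            age = rng.uniform(*arm.age_range)
            wt = _band_weight(age, arm.age_range, arm.weight_range, rng)
            dose_mg = arm.dose_rule(wt, i, rng)
            common = dict(ID=sid, WT=wt, AGEGRP=arm.age_group.value)
            rows.append(dict(common, TIME=0.0, EVID=1, AMT=dose_to_nmol(dose_mg),
                             DV=np.nan, DVID=0, MDV=1, LLOQ=0.0, BLQ=0))
            for t in arm.sampling_times(rng):
                for dvid in arm.observation_types:
                    rows.append(dict(common, TIME=float(t), EVID=0, AMT=np.nan,
                                     DV=np.nan, DVID=dvid, MDV=0,
                                     LLOQ=arm.lloq[dvid], BLQ=0))
    df = pd.DataFrame(rows)[REQUIRED_COLUMNS]
    return df.sort_values(["ID", "TIME", "EVID", "DVID"],
                          ascending=[True, True, False, True]).reset_index(drop=True)


def generate_study(design: StudyDesign, pop: Optional[PopulationParams] = None,
                   seed: int = 0):
    """Generate one synthetic study.

    Returns ``(dataset, truth)`` where truth records the generating
    population parameters and every subject's realized individual
    parameters (for parameter-recovery tests).  Fixed seed, identical
    output.
    """
    pop = pop if pop is not None else PopulationParams()
    rng = np.random.default_rng(seed)
    skeleton = StudyDataset(_skeleton(design, rng))
    ds, individuals = simulate_from_design(skeleton, pop, rng)
    truth = truth_record(seed, pop, individuals=individuals)
    return ds, truth


def generate_pediatric_study(design: Optional[StudyDesign] = None,
                             pop: Optional[PopulationParams] = None,
                             seed: int = 0):
    """Sparse pediatric study (default design: 12 children + 6 infants +
    6 neonates, paired plasma/DBS, BLQ flags applied)."""
    return generate_study(design or pediatric_design(), pop, seed)


def generate_adult_study(design: Optional[StudyDesign] = None,
                         pop: Optional[PopulationParams] = None,
                         seed: int = 0):
    """Rich adult plasma-only study (default: 30 subjects, doses 0.5-20 mg)."""
    return generate_study(design or adult_design(), pop, seed)


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

def truth_record(seed: int, pop: PopulationParams,
                 individuals: Optional[dict] = None) -> dict:
    """Serializable record of the exact generating parameters."""
    rec = {
        "seed": int(seed),
        "population": {
            "structural": {k: getattr(pop.structural, k)
                           for k in ("cl", "v_c", "q", "v_p", "km", "vmax", "f")},
            "kd": pop.kd, "ns_alb": pop.ns_alb,
            "bmax": pop.bmax, "kr": pop.kr,
            "v_delta": {g.value: v for g, v in pop.v_delta.items()},
            "base_adult_pla": pop.base_adult_pla,
            "base_child_pla": pop.base_child_pla,
            "base_child_dbs": pop.base_child_dbs,
            "omega": dict(pop.omega),
            "sigma_exp": pop.sigma_exp,
        },
    }
    if individuals is not None:
        rec["individuals"] = {
            str(sid): {
                "weight": ind.geometry.weight,
                "age_group": ind.geometry.age_group.value,
                "v_delta": ind.geometry.v_delta,
                "etas": dict(ind.etas),
                "structural": {k: getattr(ind.structural, k)
                               for k in ("cl", "v_c", "q", "v_p", "km", "vmax",
                                         "f", "base_pla", "base_dbs")},
            }
            for sid, ind in individuals.items()
        }
    return rec


def save_truth(truth: dict, path) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(truth, indent=2))


def load_truth(path) -> dict:
    return json.loads(Path(path).read_text())
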