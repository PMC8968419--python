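"""Headline analyses: binding-species fraction curves, plasma/DBS ratio
summaries, and deterministic typical-individual dose simulations."""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .binding import (
    BindingParams,
    default_binding_params,
    plasma_dbs_ratio,
    species_fractions,
    typical_geometry,
)
from .io import DVID_DBS, DVID_PLASMA, StudyDataset
from .params import AgeGroup, LLOQ_DBS, StructuralParams, allometric_scale
from .structural import DoseEvent, simulate_profile

__all__ = ["GROUP_CMAX", "fraction_curves", "ratio_analysis", "typical_dose_simulation"]

#: Highest simulated whole-blood concentration per pediatric group, nmol/L
#: (7 mg dose in the typical individual).
GROUP_CMAX = {AgeGroup.CHILDREN_INFANTS: 180.0, AgeGroup.NEONATE: 820.0}


def fraction_curves(group: AgeGroup, conc_grid=None,
                    params: Optional[BindingParams] = None,
                    n_points: int = 200) -> pd.DataFrame:
    """Binding-species fractions over whole-blood concentration.

    The default grid is ``n_points`` log-spaced concentrations from the DBS
    LLOQ (1.8 nmol/L) to the group's simulated Cmax (180 nmol/L for
    children/infants, 820 nmol/L for neonates); a user grid outside that
    domain raises.  Each row holds (conc, f_u, f_alb, f_cbg, f_rbc) and
    sums to one.
    """
    group = AgeGroup(group)
    if group not in GROUP_CMAX:
        raise ValueError(f"fraction curves are defined for pediatric groups, got {group}")
    cmax = GROUP_CMAX[group]
    if conc_grid is None:
        conc_grid = np.geomspace(LLOQ_DBS, cmax, n_points)
    else:
        conc_grid = np.asarray(conc_grid, dtype=float)
        if conc_grid.min() < LLOQ_DBS or conc_grid.max() > cmax:
            raise ValueError(
                f"grid must lie within [{LLOQ_DBS}, {cmax}] nmol/L for {group.value}"
            )
    p = params if params is not None else default_binding_params()
    g = typical_geometry(group)
    f_u, f_alb, f_cbg, f_rbc = species_fractions(conc_grid, p, g)
    return pd.DataFrame({
        "conc": conc_grid, "f_u": f_u, "f_alb": f_alb,
        "f_cbg": f_cbg, "f_rbc": f_rbc,
    })


def ratio_analysis(ds: StudyDataset, split: float = 200.0,
                   sub_split: float = 100.0) -> dict:
    """Plasma/DBS concentration-ratio summaries from paired observations.

    Pairs plasma and DBS observations of the same subject at the same time
    (both above their LLOQ), bins them by DBS concentration (default
    0-``split`` and ``split``-800 nmol/L), and additionally compares the
    two sub-bins below ``split`` with a two-sided Wilcoxon rank-sum test.

    Returns a dict with ``pairs`` (tidy frame), ``bins`` (per-bin n,
    median, min, max — overall and per age group) and ``sub_bin_test``.
    """
    obs = ds.observations
    obs = obs[(obs["MDV"] == 0) & (obs["DV"] >= obs["LLOQ"])]
    pla = obs[obs["DVID"] == DVID_PLASMA]
    dbs = obs[obs["DVID"] == DVID_DBS]
    merged = pla.merge(dbs, on=["ID", "TIME"], suffixes=("_pla", "_dbs"))
    if merged.empty:
        warnings.warn("no paired above-LLOQ plasma/DBS observations")
        return {"pairs": pd.DataFrame(), "bins": pd.DataFrame(), "sub_bin_test": None}
    pairs = pd.DataFrame({
        "ID": merged["ID"], "TIME": merged["TIME"],
        "AGEGRP": merged["AGEGRP_pla"],
        "c_pla": merged["DV_pla"], "c_dbs": merged["DV_dbs"],
        "ratio": merged["DV_pla"] / merged["DV_dbs"],
    })
    pairs["bin"] = np.where(pairs["c_dbs"] < split, f"0-{split:g}", f"{split:g}-800")

    def summarize(g):
        return pd.Series({"n": len(g), "median": g["ratio"].median(),
                          "min": g["ratio"].min(), "max": g["ratio"].max()})

    overall = pairs.groupby("bin").apply(summarize, include_groups=False)
    overall["AGEGRP"] = "all"
    by_group = (pairs.groupby(["bin", "AGEGRP"])
                .apply(summarize, include_groups=False).reset_index(level="AGEGRP"))
    bins = pd.concat([overall, by_group]).reset_index()

    low = pairs[pairs["c_dbs"] < sub_split]["ratio"]
    mid = pairs[(pairs["c_dbs"] >= sub_split) & (pairs["c_dbs"] < split)]["ratio"]
    test = None
    if len(low) and len(mid):
        stat, pval = stats.ranksums(low, mid)
        test = {"statistic": float(stat), "p_value": float(pval),
                "n_low": int(len(low)), "n_mid": int(len(mid)),
                "significant_at_0.05": bool(pval < 0.05)}
    return {"pairs": pairs, "bins": bins, "sub_bin_test": test}


def typical_dose_simulation(dose_mg: float, group: AgeGroup,
                            params: Optional[StructuralParams] = None,
                            binding: Optional[BindingParams] = None,
                            t_end: float = 6.0, n_times: int = 601):
    """Deterministic (zero IIV, zero baseline) dose simulation in the
    typical individual of a pediatric age group over ``t_end`` hours.

    Returns ``(cmax_dbs, table)`` where the table holds the whole-blood
    and plasma concentrations plus the four species amounts over time.
    """
    group = AgeGroup(group)
    if group not in GROUP_CMAX:
        raise ValueError(f"typical dose simulation targets pediatric groups, got {group}")
    g = typical_geometry(group)
    p = allometric_scale(params if params is not None else StructuralParams(), g.weight)
    b = binding if binding is not None else default_binding_params()
    times = np.linspace(0.0, t_end, n_times)
    prof = simulate_profile([DoseEvent(0.0, dose_mg)], p, b, g, times)
    a_u = prof.cu * g.v_c
    table = pd.DataFrame({
        "time": prof.times,
        "c_dbs": prof.c_dbs, "c_pla": prof.c_pla, "cu": prof.cu,
        "a_u": a_u,
        "a_cbg": g.v_c * b.bmax * prof.cu / (b.kd + prof.cu),
        "a_alb": a_u * b.ns_alb,
        "a_rbc": a_u * b.kr,
    })
    return prof.cmax_dbs, table
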