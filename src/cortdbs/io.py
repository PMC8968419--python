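"""Dataset and configuration I/O.

Study data travel as NONMEM-like CSV tables with one row per dose or
observation event.  Columns:

    ID      subject identifier (int)
    TIME    h
    EVID    1 = dose, 0 = observation
    AMT     dose amount, nmol (NaN on observation rows)
    DV      observed concentration, nmol/L (NaN on dose rows)
    DVID    observation type: 1 = plasma, 2 = DBS (0 on dose rows)
    MDV     1 if DV is missing/not to be used
    WT      body weight, kg
    AGEGRP  'adult' | 'children_infants' | 'neonate'
    LLOQ    lower limit of quantification for this record, nmol/L
    BLQ     1 if DV < LLOQ

Doses may alternatively be given in mg (``amt_unit='mg'`` at read time),
in which case they are converted once at ingestion.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .params import AgeGroup, dose_to_nmol

__all__ = ["StudyDataset", "read_dataset", "write_dataset", "RunConfig", "write_manifest"]

REQUIRED_COLUMNS = [
    "ID", "TIME", "EVID", "AMT", "DV", "DVID", "MDV", "WT", "AGEGRP", "LLOQ", "BLQ",
]

DVID_PLASMA = 1
DVID_DBS = 2


@dataclass
class StudyDataset:
    """Dosing events plus censorable plasma/DBS observations, many subjects."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset is missing required column(s): {missing}")
        obs = self.observations
        if ((obs["DV"] < 0) & (obs["MDV"] == 0)).any():
            bad = obs.loc[(obs["DV"] < 0) & (obs["MDV"] == 0), "ID"].tolist()
            raise ValueError(f"negative observed concentrations for subject(s) {bad}")
        for sid, sub in self.df.groupby("ID", sort=False):
            t = sub["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise ValueError(f"non-monotone record times within subject {sid}")
        bad_grp = set(self.df["AGEGRP"]) - {g.value for g in AgeGroup}
        if bad_grp:
            raise ValueError(f"unknown age group(s): {sorted(bad_grp)}")
        for sid, sub in self.df.groupby("ID", sort=False):
            if not (sub["EVID"] == 1).any():
                raise ValueError(f"subject {sid} has no dose record")

    @property
    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    @property
    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.df["ID"]))

    def n_subjects(self) -> int:
        return self.df["ID"].nunique()


def read_dataset(path, amt_unit: Literal["nmol", "mg"] = "nmol") -> StudyDataset:
    """Read a study CSV; with ``amt_unit='mg'`` dose amounts are converted
    to nmol at ingestion (the single unit boundary of the pipeline)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    if amt_unit == "mg":
        df = df.copy()
        df.loc[df["EVID"] == 1, "AMT"] = df.loc[df["EVID"] == 1, "AMT"].map(dose_to_nmol)
    return StudyDataset(df)


def write_dataset(ds: StudyDataset, path) -> None:
    """Write full-precision CSV so that write-then-read round-trips floats."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # shortest round-trip repr keeps write-then-read float-exact
    ds.df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


# ---------------------------------------------------------------------------
# Run configuration and manifests
# ---------------------------------------------------------------------------

class SirSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_samples: int = 1000
    n_resamples: int = 500
    inflation: float = 1.0


class VpcSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_sim: int = 1000


class EstimationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    free: list[str] = Field(
        default_factory=lambda: [
            "cl", "v_c", "vmax", "v_delta_children_infants", "v_delta_neonate",
            "omega_cl", "omega_vmax", "omega_f", "omega_v_delta", "sigma",
        ]
    )
    eta_names: list[str] = Field(default_factory=lambda: ["cl", "vmax", "f", "v_delta"])
    maxfev: int = 2000


class RunConfig(BaseModel):
    """Validated configuration for the CLI; unknown keys are rejected and
    the defaults reproduce the published parameterization."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 1
    dataset: Optional[str] = None
    output_dir: str = "results"
    parameter_overrides: dict[str, float] = Field(default_factory=dict)
    design_overrides: dict[str, float] = Field(default_factory=dict)
    solver_rtol: float = 1e-8
    solver_atol: float = 1e-10
    estimation: EstimationSettings = Field(default_factory=EstimationSettings)
    sir: SirSettings = Field(default_factory=SirSettings)
    vpc: VpcSettings = Field(default_factory=VpcSettings)


def write_manifest(path, config: RunConfig | None = None, seed: int | None = None,
                   extra: dict | None = None) -> dict:
    """Write a reproducibility manifest (seed, config hash, versions)."""
    import cortdbs

    cfg_json = config.model_dump_json() if config is not None else "{}"
    manifest = {
        "seed": seed if seed is not None else (config.seed if config else None),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": json.loads(cfg_json),
        "versions": {
            "cortdbs": getattr(cortdbs, "__version__", "unknown"),
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(manifest, indent=2))
    return manifest
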