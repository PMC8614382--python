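#!/usr/bin/env python
"""Tabulate best-practice adoption among the efficient farms.

For each surveyed farm type (the UK has no practice survey): which
practice categories the DEA-efficient farms flag, and the pooled
per-practice frequency ranking across all surveyed efficient farms.

Writes results/tables/<type>_category_adoption.csv and
results/tables/pooled_practice_ranking.csv
"""

from pathlib import Path

import pandas as pd

from flockbench import (
    DEAProblem,
    FarmType,
    category_adoption,
    classify_groups,
    default_catalog,
    practice_frequency_ranking,
    read_farm_table,
    solve_all,
)
from flockbench.best_practices import read_selection_matrix

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "tables"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    catalog = default_catalog()
    pooled = []
    pooled_total = 0
    for ftype in FarmType:
        matrix = ROOT / "synthetic" / f"{ftype.value}_practices.csv"
        if not matrix.exists():
            print(f"{ftype.value}: no practice survey")
            continue
        records = read_farm_table(ROOT / "synthetic" / f"{ftype.value}_farms.csv",
                                  farm_type=ftype)
        results = solve_all(DEAProblem.from_records(records))
        eff, _ = classify_groups(results)
        eff_ids = {records[i].farm_id for i in eff}
        sels = [s for s in read_selection_matrix(matrix, catalog)
                if s.farm_id in eff_ids]
        adoption = category_adoption(sels, catalog)
        adoption.to_csv(OUT / f"{ftype.value}_category_adoption.csv", index=False)
        top = adoption.iloc[0]
        print(f"{ftype.value}: top category {top['category']} "
              f"({top['farms_selecting']}/{top['n_farms']} efficient farms)")
        pooled.extend(sels)
        pooled_total += len(eff_ids)
    if pooled:
        ranking = practice_frequency_ranking(pooled, catalog, total_farms=pooled_total)
        ranking.to_csv(OUT / "pooled_practice_ranking.csv", index=False)
        top = ranking.iloc[0]
        print(f"pooled: most-adopted practice '{top['practice']}' "
              f"({top['count']}/{top['total_farms']}, {top['share_pct']:.0f}%)")


if __name__ == "__main__":
    main()
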