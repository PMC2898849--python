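#!/usr/bin/env python
"""Estimate crude and adjusted odds ratios on the synthetic cohort.

Builds the latency x scenario x duration-contrast grid (ever, >0-5, >5,
>10 years against the never-exposed referent), computes crude ORs with
Woolf 95% CIs and confounder-adjusted ORs by logistic regression, and
adds the bottled-water-stratified ever/never analysis.

Because the cohort was generated with a true exposure OR of 1.5 and a
positively confounded water-source assignment, the adjusted latency-0
ever/never estimates should sit near 1.5 while the crude ones sit
slightly higher.
"""

from pathlib import Path

import pandas as pd

from plumeepi import epi

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "analysis"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    subjects = pd.read_csv(ROOT / "inputs" / "subjects.csv")
    records = pd.read_csv(ROOT / "exposure" / "exposure_records.csv")
    scenarios = sorted(records["scenario_id"].unique())

    grid = epi.run_analysis_grid(
        subjects, records, scenarios, (0, 10, 15, 20),
        adjusted=True, covariates=["confounder"],
    )
    grid.to_csv(OUT / "analysis_grid.csv", index=False)
    (OUT / "analysis_grid.txt").write_text(epi.render_grid(grid) + "\n")

    strat_rows = []
    for scen in scenarios:
        for lat in (0, 10, 15, 20):
            res = epi.stratified_analysis(subjects, records, lat, scen)
            for value, entry in res.items():
                strat_rows.append({
                    "scenario_id": scen, "latency": lat,
                    "bottled_water_ever": value, "n": entry["n"],
                    "cor_formatted": entry["or"].formatted(),
                })
    pd.DataFrame(strat_rows).to_csv(OUT / "stratified.csv", index=False)

    ever0 = grid[(grid.latency == 0) & (grid.contrast == "ever")]
    print("latency-0 ever/never estimates (true OR = 1.5):")
    for r in ever0.itertuples():
        print(f"  {r.scenario_id}: COR {r.cor_formatted}   AOR {r.aor_formatted}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
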