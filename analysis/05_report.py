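"""Summarise the projections: change tables, regional richness, comparisons.

Reads the projection cube written by 04_fit_and_project.py and produces the
reporting tables: per-species mean occurrence probability by period with
relative changes versus the baseline decade, regional mean richness per
method, and the method (S-SDM vs MEM) and scenario (high- vs low-emission)
comparison tables.
"""

import pandas as pd

from _common import ensure_results, scratch
from riversdm import projection

results = ensure_results()
cube = pd.read_csv(scratch() / "projection_cube.csv")
species = sorted(
    t for t in cube["target"].unique() if not t.startswith("richness_")
)
regions = ["all"] + sorted(cube["region"].unique())

for scen, tag in [("RCP2.6", "rcp26"), ("RCP8.5", "rcp85")]:
    table = projection.build_change_table(cube, species, scen)
    table.to_csv(results / f"change_table_{tag}.csv", index=False)
    stats = projection.change_table_stats(table["delta_t3_pct"])
    print(f"{scen}: end-century changes in mean occurrence probability span "
          f"{stats['min']:+.1f}% to {stats['max']:+.1f}% "
          f"(median {stats['median']:+.1f}%).")

rows = []
for period in ("t2", "t3"):
    for region in regions:
        ssdm85 = projection.summarize_richness(cube, region, period, "RCP8.5", "ssdm")
        ssdm26 = projection.summarize_richness(cube, region, period, "RCP2.6", "ssdm")
        mem85 = projection.summarize_richness(cube, region, period, "RCP8.5", "mem")
        rows.append(
            {
                "period": period,
                "region": region,
                "richness_ssdm_rcp85": round(ssdm85, 1),
                "delta_method_pct": projection.relative_change(mem85, ssdm85)
                if mem85 > 0 else float("nan"),
                "richness_ssdm_rcp26": round(ssdm26, 1),
                "delta_scenario_pct": projection.relative_change(ssdm26, ssdm85),
            }
        )
regional = pd.DataFrame(rows)
regional.to_csv(results / "regional_richness_comparison.csv", index=False)

nat = regional[(regional["region"] == "all") & (regional["period"] == "t3")].iloc[0]
print(f"End-century national mean richness (S-SDM): "
      f"{nat['richness_ssdm_rcp85']} under RCP8.5 vs {nat['richness_ssdm_rcp26']} "
      f"under RCP2.6 ({nat['delta_scenario_pct']:+.1f}%); "
      f"S-SDM vs MEM difference {nat['delta_method_pct']:+.1f}%.")
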