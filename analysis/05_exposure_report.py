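"""Compute zone exposures and the final report.

Assembles the four exposure metrics (high-tide line, 100-year floodplain,
LECZ, expected annual exposure) per decade under the central SSP2 x
RCP-like 4.5 run, brackets them with the SSP3/5th-percentile and
SSP5/95th-percentile bound runs, and writes the report tables. Prints the
headline: whether hazard growth outpaces population growth.
"""

from pathlib import Path

import pandas as pd

from coastal_eae import rasters
from coastal_eae.config import PipelineConfig
from coastal_eae.exposure import exposure_report, percent_change
from coastal_eae.flood import ExceedanceLookup, nearest_station_map
from coastal_eae.pipeline import (
    build_lookups, compute_exposures, fit_stations, region_totals,
)
from coastal_eae.synth import SyntheticRegion

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    region = SyntheticRegion.load(OUT / "region")
    cfg = PipelineConfig(region=region.config)
    adjusted = rasters.read_raster(OUT / "adjusted_dem.tif",
                                   region.elevation).astype(float)
    lookup = ExceedanceLookup.from_frame(pd.read_csv(OUT / "lookup_tables.csv"))
    populations = pd.read_csv(OUT / "populations.csv")
    assignment = nearest_station_map(region.elevation.shape, region.stations)

    ze = compute_exposures(region, adjusted, lookup, assignment, populations,
                           cfg, cfg.report_ssp, cfg.report_scenario)
    totals = region_totals(ze)

    params = fit_stations(region, cfg)
    bounds = {}
    for name, (ssp, which) in (("low", cfg.bound_low), ("high", cfg.bound_high)):
        q = cfg.slr_quantile_low if which == "low" else cfg.slr_quantile_high
        lk = build_lookups(params, region.slr, cfg, quantile=q)
        zeb = compute_exposures(region, adjusted, lk, assignment, populations,
                                cfg, ssp, cfg.report_scenario, quantile=q)
        bounds[name] = region_totals(zeb)

    report = exposure_report(totals, ((2000, 2020), (2020, 2100)),
                             low=bounds["low"], high=bounds["high"])
    ze.to_csv(OUT / "zone_exposure.csv", index=False)
    report.table.to_csv(OUT / "report_table.csv")
    report.changes.to_csv(OUT / "report_changes.csv", index=False)

    wide = totals.pivot_table(index="decade", columns="zone", values="exposed")
    print("persons exposed, SSP2 x scenario 4.5 "
          "(low/high: SSP3 p5 / SSP5 p95):")
    print(report.table[["mhhw", "eae", "rl100", "lecz", "total"]]
          .round(0).to_string())
    print("\npercent changes (raw -> nearest 5%):")
    print(report.changes.to_string(index=False))
    pop_growth = percent_change(wide.loc[2000, "total"], wide.loc[2100, "total"])
    eae_growth = percent_change(wide.loc[2000, "eae"], wide.loc[2100, "eae"])
    print(f"\n2000->2100: population {pop_growth:+.0f}%, "
          f"EAE {eae_growth:+.0f}% -> flood hazard growth "
          f"{'outpaces' if eae_growth > pop_growth else 'trails'} "
          f"population growth")


if __name__ == "__main__":
    main()
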