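"""Backcast and project block-group populations, controlled to SSP totals.

Reads results/region/, writes the controlled population series to
results/populations.csv, and reports the region's population trajectory
under the central SSP2 scenario.
"""

from pathlib import Path

from coastal_eae.config import PipelineConfig
from coastal_eae.pipeline import project_populations
from coastal_eae.synth import SyntheticRegion

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    region = SyntheticRegion.load(OUT / "region")
    cfg = PipelineConfig(region=region.config)
    pops = project_populations(region, cfg)
    pops.to_csv(OUT / "populations.csv", index=False)

    ssp2 = (pops.query("ssp == 'SSP2'")
            .groupby("decade")["population"].sum())
    print("region population under SSP2 (persons):")
    for d in (2000, 2020, 2050, 2100):
        print(f"  {d}: {ssp2.loc[d]:>12,.0f}")
    growth = 100 * (ssp2.loc[2100] - ssp2.loc[2000]) / ssp2.loc[2000]
    print(f"2000->2100 growth: {growth:.1f}%")
    print(f"wrote {OUT / 'populations.csv'}")


if __name__ == "__main__":
    main()
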