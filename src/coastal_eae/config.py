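"""Configuration objects for the synthetic region and the pipeline.

All elevations are metres above MHHW (local mean higher high water, the
zero datum throughout). Geography is raster-native: counties and block
groups are integer-labelled pixel partitions on a common grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import yaml

#: decades covered by the projection horizon
DECADES: tuple[int, ...] = tuple(range(2000, 2101, 10))

#: housing-vintage bins of an ACS-style "year structure built" table,
#: keyed by the first year of the construction period (1930 = pre-1940)
VINTAGE_STARTS: tuple[int, ...] = tuple(range(1930, 2011, 10))

VINTAGE_LABELS: dict[int, str] = {
    1930: "pre1940",
    **{d: f"{d}s" for d in range(1940, 2011, 10)},
}

CENSUS_DECADES: tuple[int, ...] = tuple(range(1940, 2011, 10))


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class StationGPD:
    """True Poisson-GPD parameters of one synthetic tide station.

    shape
        GPD shape xi (dimensionless); negative values bound event heights.
    scale
        GPD scale sigma in metres, > 0.
    threshold
        POT threshold u in metres above MHHW.
    rate
        Mean extreme-event arrivals per year (Poisson), > 0.
    """

    shape: float = 0.1
    scale: float = 0.2
    threshold: float = 0.5
    rate: float = 3.0

    def violations(self, tag: str = "station") -> list[str]:
        out = []
        if self.scale <= 0:
            out.append(f"{tag}: GPD scale must be > 0 (got {self.scale})")
        if self.rate <= 0:
            out.append(f"{tag}: event rate must be > 0 (got {self.rate})")
        return out


@dataclass(frozen=True)
class RegionConfig:
    """Parameters of the synthetic coastal study region.

    The defaults define the study conditions every stage is exercised
    under: a coastal ramp with one isolated basin and one levee-protected
    lowland, two tide stations with 50-year extreme records, a 1000-sample
    SLR ensemble per scenario, and a three-county, twelve-block-group
    demographic fabric.
    """

    # grid
    nrows: int = 80
    ncols: int = 100
    cell_area_m2: float = 10_000.0  # 100 m pixels
    ocean_cols: int = 8

    # terrain
    ramp_max_m: float = 15.0
    noise_sd_m: float = 0.10
    n_basins: int = 1
    n_levee_areas: int = 1

    # political geography
    n_counties: int = 3
    blockgroups_per_county: int = 4

    # stations & extremes
    n_stations: int = 2
    station_gpd: tuple[StationGPD, ...] = ()
    record_years: int = 50
    min_record_years: int = 30

    # SLR ensemble
    scenarios: tuple[str, ...] = ("2.6", "4.5", "8.5")
    scenario_rise_2100_m: tuple[float, ...] = (0.5, 0.9, 1.5)
    slr_sample_spread: float = 0.35  # relative sd of per-sample amplitude
    slr_accel_frac: float = 0.6     # share of 2100 rise from the quadratic term
    vlm_rate_m_per_yr: float = 0.001  # subsidence, added per station
    n_samples: int = 1000

    # demographics
    init_units_range: tuple[float, float] = (50.0, 400.0)
    decadal_growth_range: tuple[float, float] = (-0.15, 0.35)
    pphu_range: tuple[float, float] = (1.5, 3.5)
    gq_mean: float = 30.0
    ssp_multipliers: tuple[tuple[str, float], ...] = (
        ("SSP1", 1.02),
        ("SSP2", 1.05),
        ("SSP3", 0.98),
        ("SSP4", 1.03),
        ("SSP5", 1.08),
    )

    seed: int = 42

    def violations(self) -> list[str]:
        v: list[str] = []
        for name in ("nrows", "ncols", "ocean_cols", "n_counties",
                     "blockgroups_per_county", "n_stations", "record_years",
                     "n_samples"):
            if int(getattr(self, name)) <= 0:
                v.append(f"{name} must be a positive integer")
        if self.record_years < self.min_record_years:
            v.append(
                f"record_years ({self.record_years}) below the station "
                f"inclusion floor ({self.min_record_years})"
            )
        if self.n_samples < 2:
            v.append("n_samples (M) must be >= 2")
        if self.ocean_cols >= self.ncols - 10:
            v.append("grid too small: fewer than 10 land columns")
        if self.nrows < 5 * self.n_counties:
            v.append("grid too small for the requested number of counties")
        if len(self.scenario_rise_2100_m) != len(self.scenarios):
            v.append("scenario_rise_2100_m must match scenarios in length")
        if any(r < 0 for r in self.scenario_rise_2100_m):
            v.append("scenario 2100 rise must be non-negative (non-monotone "
                     "trajectory parameters are not representable)")
        if self.slr_accel_frac < 0 or self.slr_accel_frac > 1:
            v.append("slr_accel_frac must lie in [0, 1]")
        if self.vlm_rate_m_per_yr < 0:
            v.append("vlm_rate_m_per_yr must be >= 0 to keep trajectories "
                     "non-decreasing")
        if self.pphu_range[0] <= 0:
            v.append("PPHU lower bound must be > 0")
        for g in self.station_params():
            v.extend(g.violations())
        return v

    def validate(self) -> "RegionConfig":
        v = self.violations()
        if v:
            raise ConfigError("; ".join(v))
        return self

    def station_params(self) -> tuple[StationGPD, ...]:
        """Per-station GPD truth, recycling the configured list if short."""
        if not self.station_gpd:
            return tuple(StationGPD() for _ in range(self.n_stations))
        return tuple(
            self.station_gpd[i % len(self.station_gpd)]
            for i in range(self.n_stations)
        )


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration: region, scenarios, horizon, seeds."""

    region: RegionConfig = field(default_factory=RegionConfig)
    ssps: tuple[str, ...] = ("SSP1", "SSP2", "SSP3", "SSP4", "SSP5")
    scenarios: tuple[str, ...] = ("2.6", "4.5", "8.5")
    decades: tuple[int, ...] = DECADES
    launch_year: int = 2010
    lookup_step_m: float = 0.1
    floodplain_prob: float = 0.01  # 100-year return period
    slr_quantile_low: float = 0.05
    slr_quantile_high: float = 0.95
    report_ssp: str = "SSP2"
    report_scenario: str = "4.5"
    bound_low: tuple[str, str] = ("SSP3", "low")
    bound_high: tuple[str, str] = ("SSP5", "high")
    seed: int = 42

    def violations(self) -> list[str]:
        v = self.region.violations()
        for d in self.decades:
            if d < 2000 or d > 2100 or d % 10:
                v.append(f"decade {d} outside 2000-2100 at step 10")
        if 2000 not in self.decades:
            v.append("decades must include the baseline year 2000")
        for s in self.ssps:
            if s not in dict(self.region.ssp_multipliers):
                v.append(f"SSP scenario {s!r} has no configured multiplier")
        for s in self.scenarios:
            if s not in self.region.scenarios:
                v.append(f"emissions scenario {s!r} not in region config")
        if not (0 < self.floodplain_prob < 1):
            v.append("floodplain_prob must lie in (0, 1)")
        if self.launch_year not in CENSUS_DECADES:
            v.append(f"launch_year {self.launch_year} is not a census decade")
        return v

    def validate(self) -> "PipelineConfig":
        v = self.violations()
        if v:
            raise ConfigError("; ".join(v))
        return self

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, region=replace(self.region, seed=seed))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        region_raw = raw.pop("region", {})
        gpd = tuple(StationGPD(**g) for g in region_raw.pop("station_gpd", []))

        def _tup(x):
            return tuple(tuple(i) if isinstance(i, list) else i for i in x) \
                if isinstance(x, list) else x

        region = RegionConfig(
            station_gpd=gpd, **{k: _tup(v) for k, v in region_raw.items()}
        )
        return cls(region=region, **{k: _tup(v) for k, v in raw.items()})
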