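"""Synthetic coastal study region generator.

Every downstream stage of the pipeline is exercised on a fully synthetic
region with the statistical structure the real analysis assumes: a coastal
elevation ramp with an isolated basin behind a ridge and a levee-protected
lowland (to exercise hydrological connectivity), tide stations whose
extreme-event records are drawn from known Poisson-GPD parameters (so
fits can be checked against truth), Monte Carlo sea-level-rise sample
trajectories that are non-decreasing in time and ordered across emissions
scenarios, and a county/block-group demographic fabric with ACS-style
housing vintages, census controls, and SSP county totals.

All randomness flows from one master seed through independent per-stage
streams, so regenerating with the same config is bit-identical and editing
one stage's parameters does not perturb another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from coastal_eae import demography, rasters
from coastal_eae.config import (
    CENSUS_DECADES, ConfigError, RegionConfig, VINTAGE_LABELS, VINTAGE_STARTS,
)

_STAGES = ("terrain", "stations", "slr", "demographics")


@dataclass
class SLREnsemble:
    """Monte Carlo local sea-level-rise samples.

    ``samples[s, c, d, j]`` is SLR_j(decade d) in metres at station s under
    scenario c; each sample trajectory is non-decreasing in the decade and
    zero in the year-2000 baseline.
    """

    station_ids: np.ndarray
    scenarios: tuple[str, ...]
    decades: tuple[int, ...]
    samples: np.ndarray  # (stations, scenarios, decades, M)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    def _ix(self, station_id: int, scenario: str, decade: int | None = None):
        s = int(np.flatnonzero(self.station_ids == station_id)[0])
        c = self.scenarios.index(str(scenario))
        if decade is None:
            return s, c
        return s, c, self.decades.index(int(decade))

    def samples_for(self, station_id: int, scenario: str,
                    decade: int) -> np.ndarray:
        return self.samples[self._ix(station_id, scenario, decade)]

    def median(self, station_id: int, scenario: str, decade: int) -> float:
        return float(np.median(self.samples_for(station_id, scenario, decade)))

    def quantile_trajectory(self, station_id: int, scenario: str,
                            q: float) -> dict[int, float]:
        """Pointwise quantile per decade (a one-sample bound ensemble)."""
        s, c = self._ix(station_id, scenario)
        qs = np.quantile(self.samples[s, c], q, axis=-1)
        return {d: float(v) for d, v in zip(self.decades, qs)}

    def to_frame(self) -> pd.DataFrame:
        s, c, d, m = self.samples.shape
        idx = pd.MultiIndex.from_product(
            [self.station_ids, self.scenarios, self.decades, range(m)],
            names=["station_id", "scenario", "decade", "sample"])
        return (pd.Series(self.samples.reshape(-1), index=idx, name="slr_m")
                .reset_index())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SLREnsemble":
        sids = np.sort(df["station_id"].unique())
        scens = tuple(sorted(df["scenario"].astype(str).unique()))
        decs = tuple(sorted(df["decade"].unique().astype(int)))
        m = int(df["sample"].max()) + 1
        cube = (df.sort_values(["station_id", "scenario", "decade", "sample"])
                ["slr_m"].to_numpy()
                .reshape(len(sids), len(scens), len(decs), m))
        return cls(sids, scens, decs, cube)


@dataclass
class SyntheticRegion:
    """One generated study region plus its input tables."""

    config: RegionConfig
    elevation: np.ndarray      # float32, m above MHHW
    ocean_mask: np.ndarray     # bool; the flood-fill seed
    levee_mask: np.ndarray
    wetland_mask: np.ndarray
    blockgroup_raster: np.ndarray  # uint32, 0 = no block group (ocean)
    county_raster: np.ndarray      # uint32, 0 = no county (ocean)
    stations: pd.DataFrame
    extremes: pd.DataFrame
    slr: SLREnsemble
    vintages: pd.DataFrame
    controls: pd.DataFrame
    attributes: pd.DataFrame
    ssp_controls: pd.DataFrame

    @property
    def land_mask(self) -> np.ndarray:
        return ~self.ocean_mask

    @property
    def dry_mask(self) -> np.ndarray:
        """Dry land: land outside wetlands (the areal-weighting denominator)."""
        return self.land_mask & ~self.wetland_mask

    def bg_county_map(self) -> pd.Series:
        ids = self.blockgroup_raster[self.land_mask]
        cty = self.county_raster[self.land_mask]
        df = pd.DataFrame({"bg": ids, "county": cty}).drop_duplicates()
        return df.set_index("bg")["county"].sort_index()

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        rasters.write_raster(out / "elevation.tif",
                             self.elevation.astype(np.float32))
        for name in ("ocean_mask", "levee_mask", "wetland_mask"):
            rasters.write_raster(out / f"{name}.tif",
                                 getattr(self, name).astype(np.uint8))
        rasters.write_raster(out / "blockgroups.tif",
                             self.blockgroup_raster.astype(np.uint32))
        rasters.write_raster(out / "counties.tif",
                             self.county_raster.astype(np.uint32))
        for name in ("stations", "extremes", "vintages", "controls",
                     "attributes", "ssp_controls"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        self.slr.to_frame().to_csv(out / "slr_samples.csv", index=False)
        rasters.write_manifest(out / "region_manifest.json",
                               shape=self.elevation.shape,
                               cell_area_m2=self.config.cell_area_m2)
        with open(out / "region_config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.config), fh, sort_keys=False)

    @classmethod
    def load(cls, outdir) -> "SyntheticRegion":
        out = Path(outdir)
        with open(out / "region_config.yaml") as fh:
            raw = yaml.safe_load(fh)
        from coastal_eae.config import StationGPD
        gpd = tuple(StationGPD(**g) for g in raw.pop("station_gpd", []))
        cfg = RegionConfig(station_gpd=gpd, **{
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        elev = rasters.read_raster(out / "elevation.tif")
        return cls(
            config=cfg,
            elevation=elev,
            ocean_mask=rasters.read_raster(out / "ocean_mask.tif", elev).astype(bool),
            levee_mask=rasters.read_raster(out / "levee_mask.tif", elev).astype(bool),
            wetland_mask=rasters.read_raster(out / "wetland_mask.tif", elev).astype(bool),
            blockgroup_raster=rasters.read_raster(out / "blockgroups.tif", elev),
            county_raster=rasters.read_raster(out / "counties.tif", elev),
            stations=pd.read_csv(out / "stations.csv"),
            extremes=pd.read_csv(out / "extremes.csv"),
            slr=SLREnsemble.from_frame(pd.read_csv(out / "slr_samples.csv")),
            vintages=pd.read_csv(out / "vintages.csv"),
            controls=pd.read_csv(out / "controls.csv"),
            attributes=pd.read_csv(out / "attributes.csv"),
            ssp_controls=pd.read_csv(out / "ssp_controls.csv"),
        )


def _stage_rngs(config: RegionConfig) -> dict[str, np.random.Generator]:
    seqs = np.random.SeedSequence(config.seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(seq)
            for name, seq in zip(_STAGES, seqs)}


def generate_terrain(config: RegionConfig,
                     rng: np.random.Generator | None = None):
    """Build the elevation raster and feature masks.

    A linear ramp rises from the ocean edge past 10 m inland, with
    additive Gaussian roughness. Each basin is a low rectangle enclosed by
    a ridge one step higher than nearby terrain; each levee area is a low
    rectangle whose rim is flagged impassable in the levee mask. Wetland
    patches sit on the near-shore land strip.

    Returns (elevation, ocean_mask, levee_mask, wetland_mask).
    """
    config.validate()
    rng = rng or _stage_rngs(config)["terrain"]
    nr, nc, oc = config.nrows, config.ncols, config.ocean_cols

    elevation = np.zeros((nr, nc), dtype=np.float64)
    ocean = np.zeros((nr, nc), dtype=bool)
    levee = np.zeros((nr, nc), dtype=bool)
    wetland = np.zeros((nr, nc), dtype=bool)

    # ocean floor slopes down offshore; land ramps up inland
    cols = np.arange(nc)
    ocean[:, :oc] = True
    elevation[:, :oc] = -2.0 + 2.0 * (cols[:oc] / oc)  # <= 0 everywhere
    land_x = (cols[oc:] - oc + 1) / (nc - oc)
    elevation[:, oc:] = config.ramp_max_m * land_x
    elevation[:, oc:] += rng.normal(0.0, config.noise_sd_m, size=(nr, nc - oc))
    elevation[:, oc:] = np.maximum(elevation[:, oc:], 0.05)
    # intertidal fringe: the first land column sits just below MHHW
    elevation[:, oc] = rng.uniform(-0.15, -0.01, size=nr)

    n_features = config.n_basins + config.n_levee_areas
    if n_features:
        fh, fw = 8, 8
        # column where the ramp is ~2 m: low enough to matter, behind shore
        c0 = oc + max(2, int(round(2.0 / config.ramp_max_m * (nc - oc))))
        if c0 + fw + 1 >= nc or (fh + 2) * n_features >= nr:
            raise ConfigError(
                "grid too small to place the requested basins and levee areas")
        slots = np.linspace(2, nr - fh - 2, n_features).astype(int)
        for k in range(config.n_basins):
            r0 = slots[k]
            block = np.s_[r0:r0 + fh, c0:c0 + fw]
            elevation[block] = 3.0                       # ridge crest
            elevation[r0 + 1:r0 + fh - 1, c0 + 1:c0 + fw - 1] = 0.4
        for k in range(config.n_basins, n_features):
            r0 = slots[k]
            interior = np.s_[r0 + 1:r0 + fh - 1, c0 + 1:c0 + fw - 1]
            ring = np.zeros((nr, nc), dtype=bool)
            ring[r0:r0 + fh, c0:c0 + fw] = True
            ring[interior] = False
            elevation[r0:r0 + fh, c0:c0 + fw] = 1.0
            elevation[interior] = 0.3
            levee |= ring

    # wetland fringe on the first land columns, in patches between features
    patch_rows = rng.choice(nr, size=max(2, nr // 8), replace=False)
    for r in patch_rows:
        wetland[r, oc:oc + 4] = True
    wetland &= ~ocean & ~levee

    return elevation, ocean, levee, wetland


def generate_zones(config: RegionConfig, ocean_mask: np.ndarray):
    """Partition land pixels into counties (row bands) and block groups
    (column slices within each county). Returns (county, blockgroup) rasters
    with 0 on ocean."""
    nr, nc = ocean_mask.shape
    county = np.zeros((nr, nc), dtype=np.uint32)
    bg = np.zeros((nr, nc), dtype=np.uint32)
    row_edges = np.linspace(0, nr, config.n_counties + 1).astype(int)
    col_edges = np.linspace(config.ocean_cols, nc,
                            config.blockgroups_per_county + 1).astype(int)
    for j in range(config.n_counties):
        rows = np.s_[row_edges[j]:row_edges[j + 1]]
        county[rows, :] = j + 1
        for k in range(config.blockgroups_per_county):
            bg[rows, col_edges[k]:col_edges[k + 1]] = (j + 1) * 100 + k + 1
    county[ocean_mask] = 0
    bg[ocean_mask] = 0
    return county, bg


def generate_stations_and_extremes(config: RegionConfig,
                                   rng: np.random.Generator | None = None):
    """Place tide stations on the ocean edge and draw their event records.

    Yearly event counts are Poisson(rate); event heights are the station
    threshold plus GPD(shape, scale) excesses, so fits can be validated
    against known truth.

    Returns (stations DataFrame, extremes DataFrame).
    """
    config.validate()
    rng = rng or _stage_rngs(config)["stations"]
    n = config.n_stations
    rows = ((np.arange(n) + 0.5) * config.nrows / n).astype(int)
    col = config.ocean_cols - 1
    params = config.station_params()
    stations = pd.DataFrame({
        "station_id": np.arange(1, n + 1),
        "row": rows,
        "col": col,
        "true_shape": [p.shape for p in params],
        "true_scale": [p.scale for p in params],
        "true_threshold": [p.threshold for p in params],
        "true_rate": [p.rate for p in params],
        "record_years": config.record_years,
    })
    recs = []
    for sid, p in zip(stations["station_id"], params):
        counts = rng.poisson(p.rate, size=config.record_years)
        total = int(counts.sum())
        heights = p.threshold + stats.genpareto.rvs(
            p.shape, scale=p.scale, size=total, random_state=rng)
        years = np.repeat(np.arange(1, config.record_years + 1), counts)
        recs.append(pd.DataFrame({
            "station_id": sid, "year": years, "height_m": heights}))
    extremes = (pd.concat(recs, ignore_index=True) if recs
                else pd.DataFrame(columns=["station_id", "year", "height_m"]))
    return stations, extremes


def generate_slr_ensemble(config: RegionConfig,
                          decades: tuple[int, ...] = tuple(range(2000, 2101, 10)),
                          rng: np.random.Generator | None = None) -> SLREnsemble:
    """Draw Monte Carlo local SLR trajectories.

    Each sample j shares one amplitude draw across scenarios and follows
    a mixed linear/quadratic curve of time scaled by the scenario's 2100
    rise, plus a constant per-station subsidence rate; this yields smooth,
    accelerating, uncertainty-widening trajectories that are zero in 2000,
    non-decreasing in time, and pointwise ordered across scenarios.
    """
    config.validate()
    rng = rng or _stage_rngs(config)["slr"]
    t = (np.asarray(decades) - 2000) / 100.0
    curve = (1 - config.slr_accel_frac) * t + config.slr_accel_frac * t ** 2
    amp = np.maximum(
        rng.normal(1.0, config.slr_sample_spread,
                   size=(config.n_stations, config.n_samples)), 0.0)
    vlm = config.vlm_rate_m_per_yr * (np.asarray(decades) - 2000)
    cube = np.empty((config.n_stations, len(config.scenarios),
                     len(decades), config.n_samples))
    for c, rise in enumerate(config.scenario_rise_2100_m):
        cube[:, c] = (amp[:, None, :] * rise * curve[None, :, None]
                      + vlm[None, :, None])
    return SLREnsemble(np.arange(1, config.n_stations + 1),
                       tuple(config.scenarios), tuple(int(d) for d in decades),
                       cube)


def generate_demographics(config: RegionConfig, blockgroup_raster: np.ndarray,
                          county_raster: np.ndarray,
                          rng: np.random.Generator | None = None):
    """Draw housing vintages, census controls, attributes and SSP totals.

    Vintage counts follow per-block-group compound decadal growth (drawn
    from the configured range, so some groups decline), guaranteeing a
    positive pre-1940 stock everywhere so the backcast denominator never
    vanishes. Census controls are the county vintage stock perturbed by
    +/-20% multiplicative noise. SSP county totals are the county sums of
    the package's own unconstrained projection scaled by compounding
    per-decade SSP multipliers, so the neutral 2020 totals match the
    unconstrained projection by construction.
    """
    config.validate()
    rng = rng or _stage_rngs(config)["demographics"]
    land = blockgroup_raster > 0
    pairs = np.unique(np.stack([blockgroup_raster[land],
                                county_raster[land]]), axis=1)
    bg_ids, counties = pairs[0], pairs[1]

    vint_rows = []
    for bg, cty in zip(bg_ids, counties):
        init = rng.uniform(*config.init_units_range)
        g = rng.uniform(*config.decadal_growth_range)
        units = init
        for start in VINTAGE_STARTS:
            built = max(1.0, units * rng.lognormal(0.0, 0.15))
            vint_rows.append({
                "block_group_id": int(bg), "county_id": int(cty),
                "vintage_bin": VINTAGE_LABELS[start],
                "units": round(built, 2)})
            units *= (1.0 + g)
    vintages = pd.DataFrame(vint_rows)

    wide = vintages.pivot_table(index="county_id", columns="vintage_bin",
                                values="units", aggfunc="sum")
    ctl_rows = []
    starts = np.array(VINTAGE_STARTS)
    for cty in np.unique(counties):
        for v in CENSUS_DECADES:
            labels = [VINTAGE_LABELS[s] for s in starts[starts < v]]
            stock = wide.loc[cty, labels].sum()
            ctl_rows.append({
                "county_id": int(cty), "decade": v,
                "units": round(stock * rng.uniform(0.85, 1.25), 1)})
    controls = pd.DataFrame(ctl_rows)

    attributes = pd.DataFrame({
        "block_group_id": bg_ids.astype(int),
        "pphu": np.round(rng.uniform(*config.pphu_range, size=len(bg_ids)), 3),
        "gq": rng.poisson(config.gq_mean, size=len(bg_ids)).astype(float),
    })

    # SSP controls from the unconstrained projection of this very fabric
    hist = demography.backcast_housing(vintages, controls)
    proj = demography.project_housing(hist)
    housing = pd.concat([hist[[2000, 2010]], proj], axis=1)
    pop = demography.compute_population(housing, attributes)
    bg_cty = pd.Series(counties, index=bg_ids)
    county_pop = pop.groupby(bg_cty.reindex(pop.index)).sum()

    ssp_rows = []
    for ssp, mult in config.ssp_multipliers:
        for d in range(2020, 2101, 10):
            factor = mult ** ((d - 2020) / 10)
            for cty in county_pop.index:
                ssp_rows.append({
                    "county_id": int(cty), "ssp": ssp, "decade": d,
                    "population": county_pop.loc[cty, d] * factor})
    ssp_controls = pd.DataFrame(ssp_rows)
    return vintages, controls, attributes, ssp_controls


def generate_region(config: RegionConfig | None = None) -> SyntheticRegion:
    """Generate a complete synthetic region from one seeded config."""
    config = (config or RegionConfig()).validate()
    rngs = _stage_rngs(config)
    elevation, ocean, levee, wetland = generate_terrain(config, rngs["terrain"])
    county, bg = generate_zones(config, ocean)
    stations, extremes = generate_stations_and_extremes(config, rngs["stations"])
    slr = generate_slr_ensemble(config, rng=rngs["slr"])
    vintages, controls, attributes, ssp_controls = generate_demographics(
        config, bg, county, rngs["demographics"])
    return SyntheticRegion(
        config=config,
        elevation=elevation.astype(np.float32),
        ocean_mask=ocean, levee_mask=levee, wetland_mask=wetland,
        blockgroup_raster=bg, county_raster=county,
        stations=stations, extremes=extremes, slr=slr,
        vintages=vintages, controls=controls, attributes=attributes,
        ssp_controls=ssp_controls,
    )
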