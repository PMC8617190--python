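"""Population exposure in four spatio-temporal coastal flood zones.

For a scenario x decade the pipeline derives three binary inundation
layers on the adjusted DEM — land below the local median SLR (the rising
high-tide line, MHHW), land in the SLR-adjusted 100-year floodplain
(annual exceedance probability >= 0.01), and the dynamic low-elevation
coastal zone (land below 10 m + SLR) — plus the expected annual exposure
(EAE): the population-density-weighted sum of per-pixel annual flood
probabilities, i.e. the expected number of people on land flooded at
least once in the year.

Populations are allocated by dry-land areal weighting: a block group
contributes its population times the fraction of its dry-land (non-
wetland) pixels inside the layer. The three layers nest
(MHHW <= RL100 <= LECZ), so do their populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ZONES = ("mhhw", "rl100", "lecz")


class ExposureError(ValueError):
    pass


def zone_layers(adjusted_elevation: np.ndarray, land_mask: np.ndarray,
                probability_surface: np.ndarray, median_slr: np.ndarray,
                floodplain_prob: float = 0.01) -> dict[str, np.ndarray]:
    """Threshold the adjusted DEM and probability surface into the three
    binary inundation layers for one scenario x decade.

    ``median_slr`` is the per-pixel ensemble-median SLR (each pixel's
    nearest station's median), in metres.
    """
    elev = np.asarray(adjusted_elevation, dtype=float)
    slr = np.broadcast_to(np.asarray(median_slr, dtype=float), elev.shape)
    return {
        "mhhw": land_mask & (elev <= slr),
        "rl100": land_mask & (np.asarray(probability_surface) >= floodplain_prob),
        "lecz": land_mask & (elev <= 10.0 + slr),
    }


def _dry_counts(blockgroups: np.ndarray, dry_mask: np.ndarray,
                where: np.ndarray | None = None) -> pd.Series:
    sel = dry_mask if where is None else (dry_mask & where)
    ids, counts = np.unique(blockgroups[sel & (blockgroups > 0)],
                            return_counts=True)
    return pd.Series(counts, index=ids, dtype=float)


def zone_population(layer: np.ndarray, blockgroups: np.ndarray,
                    dry_mask: np.ndarray, population: pd.Series) -> pd.Series:
    """Dry-land areal weighting of block-group populations into a layer.

    exposed_i = pop_i * (dry pixels of i inside the layer) / (dry pixels
    of i); block groups with no dry land contribute zero.
    """
    all_ids = np.unique(blockgroups[blockgroups > 0])
    missing = set(all_ids) - set(population.index)
    if missing:
        raise ExposureError(
            f"block groups missing from population table: {sorted(missing)}")
    total = _dry_counts(blockgroups, dry_mask).reindex(all_ids, fill_value=0.0)
    inside = _dry_counts(blockgroups, dry_mask, layer).reindex(
        all_ids, fill_value=0.0)
    frac = np.where(total > 0, inside / total.replace(0, np.nan), 0.0)
    return pd.Series(population.reindex(all_ids).to_numpy() * frac,
                     index=all_ids, name="exposed")


def expected_annual_exposure(probability_surface: np.ndarray,
                             blockgroups: np.ndarray, dry_mask: np.ndarray,
                             population: pd.Series) -> pd.Series:
    """EAE per block group: sum over dry pixels of probability x density.

    Density is the block group's population divided by its dry-land pixel
    count (zero on wetlands), so a probability-1 surface returns the full
    population.
    """
    all_ids = np.unique(blockgroups[blockgroups > 0])
    missing = set(all_ids) - set(population.index)
    if missing:
        raise ExposureError(
            f"block groups missing from population table: {sorted(missing)}")
    total = _dry_counts(blockgroups, dry_mask).reindex(all_ids, fill_value=0.0)
    sel = dry_mask & (blockgroups > 0)
    psum = pd.Series(
        np.bincount(
            np.searchsorted(all_ids, blockgroups[sel]),
            weights=np.asarray(probability_surface, dtype=float)[sel],
            minlength=len(all_ids)),
        index=all_ids)
    density = population.reindex(all_ids) / total.replace(0, np.nan)
    return (psum * density).fillna(0.0).rename("eae")


def aggregate(per_blockgroup: pd.Series, bg_county: pd.Series
              ) -> tuple[pd.Series, float]:
    """Sum block-group values to counties and the region total."""
    by_county = per_blockgroup.groupby(
        bg_county.reindex(per_blockgroup.index)).sum()
    return by_county, float(per_blockgroup.sum())


def percent_change(base: float, later: float) -> float:
    """100 * (later - base) / base; NaN when the base is zero."""
    if base == 0:
        return float("nan")
    return 100.0 * (later - base) / base


def round_to_nearest(x: float, base: float = 5.0) -> float:
    """Round to the reporting granularity (nearest 5% by default)."""
    if not np.isfinite(x):
        return x
    return float(base * round(x / base))


@dataclass
class ExposureReport:
    """Zone totals by decade plus percent changes between named decades."""

    table: pd.DataFrame    # index decade, one column per zone (+ bounds)
    changes: pd.DataFrame  # zone, from, to, raw_pct, nearest5_pct


def exposure_report(totals: pd.DataFrame,
                    comparisons: tuple[tuple[int, int], ...] = (),
                    low: pd.DataFrame | None = None,
                    high: pd.DataFrame | None = None) -> ExposureReport:
    """Assemble the report table from region zone totals.

    ``totals`` (and the optional ``low``/``high`` bound runs) are long
    tables with columns (decade, zone, exposed). Percent changes are
    reported raw and rounded to the nearest 5%, the granularity at which
    such relative changes are typically quoted; a zero base yields an
    undefined (NaN) change.
    """
    table = totals.pivot_table(index="decade", columns="zone",
                               values="exposed").sort_index()
    for name, bound in (("low", low), ("high", high)):
        if bound is not None:
            b = bound.pivot_table(index="decade", columns="zone",
                                  values="exposed").sort_index()
            for z in b.columns:
                table[f"{z}_{name}"] = b[z]
    rows = []
    for a, b in comparisons:
        for zone in [c for c in table.columns if c in set(totals["zone"])]:
            raw = percent_change(table.loc[a, zone], table.loc[b, zone])
            rows.append({"zone": zone, "from": a, "to": b, "raw_pct": raw,
                         "nearest5_pct": round_to_nearest(raw)})
    changes = pd.DataFrame(
        rows, columns=["zone", "from", "to", "raw_pct", "nearest5_pct"])
    return ExposureReport(table=table, changes=changes)
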