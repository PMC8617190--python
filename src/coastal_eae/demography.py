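"""Small-area population estimation and projection by the housing-unit method.

The block-group housing stock for census decades 1940-2010 is reconstructed
by proportional fitting: the county census count for decade v is allocated
to block groups in proportion to their ACS-style housing stock built before
v, so county sums reproduce the census controls exactly. The series is then
projected to 2100 with a mixed model — a linear trend for growing block
groups, a power-law trend for declining ones — anchored to pass through the
launch-year stock. Population is housing units times persons-per-housing-
unit plus group quarters, and projections are controlled (raked) to SSP
county totals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from coastal_eae.config import CENSUS_DECADES, VINTAGE_STARTS, VINTAGE_LABELS

log = logging.getLogger(__name__)

_LABEL_TO_START = {lab: start for start, lab in VINTAGE_LABELS.items()}


class DemographyError(ValueError):
    pass


def _vintage_wide(vintages: pd.DataFrame) -> pd.DataFrame:
    """Long vintage table -> block groups x vintage-start-year matrix."""
    df = vintages.copy()
    df["vintage_start"] = df["vintage_bin"].map(_LABEL_TO_START)
    if df["vintage_start"].isna().any():
        bad = sorted(df.loc[df["vintage_start"].isna(), "vintage_bin"].unique())
        raise DemographyError(f"unknown vintage bins: {bad}")
    wide = df.pivot_table(
        index="block_group_id", columns="vintage_start", values="units",
        aggfunc="sum", fill_value=0.0,
    ).reindex(columns=list(VINTAGE_STARTS), fill_value=0.0)
    return wide


def backcast_housing(vintages: pd.DataFrame,
                     controls: pd.DataFrame) -> pd.DataFrame:
    """Proportionally allocate census housing counts to block groups.

    For each county j and census decade v, the control count C_j^v is split
    across the county's block groups in proportion to each group's housing
    units built before v (the pre-v vintage stock). County sums of the
    result equal the controls exactly.

    Parameters
    ----------
    vintages
        Long table (block_group_id, county_id, vintage_bin, units).
    controls
        Long table (county_id, decade, units) for decades 1940-2010.

    Returns
    -------
    DataFrame indexed by block_group_id with one column per census decade.
    """
    wide = _vintage_wide(vintages)
    bg_county = (vintages[["block_group_id", "county_id"]]
                 .drop_duplicates().set_index("block_group_id")["county_id"]
                 .reindex(wide.index))
    ctl = controls.pivot_table(index="county_id", columns="decade",
                               values="units", aggfunc="sum")

    out = pd.DataFrame(index=wide.index, columns=list(CENSUS_DECADES),
                       dtype=float)
    starts = np.array(VINTAGE_STARTS)
    for v in CENSUS_DECADES:
        pre_v = wide.loc[:, starts[starts < v]].sum(axis=1)
        county_pre = pre_v.groupby(bg_county).transform("sum")
        c_v = bg_county.map(ctl.get(v, pd.Series(dtype=float)))
        zero_den = (county_pre <= 0) & (c_v > 0)
        if zero_den.any():
            bad = sorted(bg_county[zero_den].unique())
            raise DemographyError(
                f"county pre-{v} vintage stock is zero but census control is "
                f"positive for counties {bad} in decade {v}"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(county_pre > 0, pre_v / county_pre, 0.0)
        out[v] = c_v.fillna(0.0).to_numpy() * share
    out.columns.name = "decade"
    return out


def _fit_linear(tau: np.ndarray, h: np.ndarray) -> tuple[float, float]:
    """OLS fit h = alpha + beta*tau; returns (alpha, beta)."""
    beta, alpha = np.polyfit(tau, h, 1)
    return float(alpha), float(beta)


def _fit_power(tau: np.ndarray, h: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of log h on log tau: h = e^a * tau^b -> (a, b).

    Zero observations carry no information about a multiplicative decline
    curve and are dropped; with fewer than two positive points the curve
    degenerates to the last positive level (b = 0).
    """
    pos = h > 0
    if pos.sum() < 2:
        level = h[pos][-1] if pos.any() else 0.0
        return (float(np.log(level)) if level > 0 else -np.inf, 0.0)
    b, a = np.polyfit(np.log(tau[pos]), np.log(h[pos]), 1)
    return float(a), float(b)


def _power_eval(a: float, b: float, tau: np.ndarray) -> np.ndarray:
    if np.isneginf(a):
        return np.zeros_like(np.asarray(tau, dtype=float))
    return np.exp(a) * np.asarray(tau, dtype=float) ** b


def project_housing(history: pd.DataFrame,
                    horizon: tuple[int, ...] = tuple(range(2020, 2101, 10)),
                    launch_year: int = 2010) -> pd.DataFrame:
    """Project block-group housing stocks beyond the census record.

    Each block group is classified by the sign of the OLS slope of its
    1940-2010 series: growing groups follow the fitted line, declining
    groups a fitted power law e^a * tau^b (tau = decades since 1930). Both
    forms carry an additive anchor term [H^t - fit(t)] so the projection
    passes through the observed launch-year stock, and are floored at zero.

    Returns a DataFrame indexed like ``history`` with horizon columns.
    """
    hist_years = np.array([c for c in history.columns if c <= launch_year])
    if hist_years.size < 3:
        raise DemographyError("need at least 3 historical decades to fit")
    tau_hist = (hist_years - 1930) / 10.0
    tau_t = (launch_year - 1930) / 10.0
    tau_z = (np.asarray(horizon) - 1930) / 10.0

    out = pd.DataFrame(index=history.index, columns=list(horizon), dtype=float)
    for bg, row in history[hist_years].iterrows():
        h = row.to_numpy(dtype=float)
        h_t = h[hist_years == launch_year][0]
        if not h.any():
            out.loc[bg] = 0.0
            continue
        alpha, beta = _fit_linear(tau_hist, h)
        if beta >= 0:
            proj = (alpha + beta * tau_z) + (h_t - (alpha + beta * tau_t))
        else:
            a, b = _fit_power(tau_hist, h)
            proj = _power_eval(a, b, tau_z) + (h_t - _power_eval(a, b, np.array([tau_t]))[0])
        out.loc[bg] = np.maximum(proj, 0.0)
    out.columns.name = "decade"
    return out


def compute_population(housing: pd.DataFrame,
                       attributes: pd.DataFrame) -> pd.DataFrame:
    """P = H * PPHU + GQ, elementwise per block group and decade.

    PPHU and GQ are held constant over the horizon. ``attributes`` has
    columns (block_group_id, pphu, gq).
    """
    attrs = attributes.set_index("block_group_id")
    missing = housing.index.difference(attrs.index)
    if len(missing):
        raise DemographyError(f"block groups missing attributes: {list(missing)}")
    pphu = attrs.loc[housing.index, "pphu"].to_numpy()[:, None]
    gq = attrs.loc[housing.index, "gq"].to_numpy()[:, None]
    if (pphu <= 0).any():
        raise DemographyError("PPHU must be > 0")
    if (gq < 0).any():
        raise DemographyError("GQ must be >= 0")
    return housing.mul(1.0) * pphu + gq


def _interp_controls(ssp_controls: pd.DataFrame,
                     decades: tuple[int, ...]) -> pd.DataFrame:
    """Linearly interpolate SSP control totals to the requested decades."""
    out = []
    for (county, ssp), grp in ssp_controls.groupby(["county_id", "ssp"]):
        grp = grp.sort_values("decade")
        lo, hi = grp["decade"].min(), grp["decade"].max()
        want = [d for d in decades if lo <= d <= hi]
        vals = np.interp(want, grp["decade"], grp["population"])
        out.append(pd.DataFrame({
            "county_id": county, "ssp": ssp, "decade": want, "population": vals,
        }))
    return pd.concat(out, ignore_index=True)


def control_to_ssp(population: pd.DataFrame, bg_county: pd.Series,
                   ssp_controls: pd.DataFrame,
                   decades: tuple[int, ...] | None = None) -> pd.DataFrame:
    """Rake unconstrained block-group populations to SSP county totals.

    Every block group's population is scaled by the ratio of the SSP county
    control to the county sum of the unconstrained projection, so county
    sums match the controls to numerical precision. A county whose
    unconstrained sum is zero but whose control is positive has the control
    spread uniformly over its block groups (logged).

    Parameters
    ----------
    population
        Unconstrained P, block groups x decades.
    bg_county
        block_group_id -> county_id.
    ssp_controls
        Long table (county_id, ssp, decade, population); interpolated
        linearly to the requested decades when supplied at coarser steps.

    Returns
    -------
    Long DataFrame (block_group_id, county_id, ssp, decade, population).
    """
    if decades is None:
        decades = tuple(int(c) for c in population.columns)
    ctl_decades = [d for d in decades
                   if ssp_controls["decade"].min() <= d <= ssp_controls["decade"].max()]
    ctl = _interp_controls(ssp_controls, tuple(ctl_decades))
    county = bg_county.reindex(population.index)

    records = []
    for ssp, grp in ctl.groupby("ssp"):
        totals = grp.pivot_table(index="county_id", columns="decade",
                                 values="population")
        for d in decades:
            p = population[d]
            if d in totals.columns:
                county_sum = p.groupby(county).transform("sum")
                target = county.map(totals[d])
                if target.isna().any():
                    bad = sorted(county[target.isna()].unique())
                    raise DemographyError(
                        f"SSP control missing for counties {bad}, "
                        f"scenario {ssp}, decade {d}"
                    )
                scaled = np.where(county_sum > 0, p * target / county_sum, np.nan)
                if np.isnan(scaled).any():
                    n_bg = county.groupby(county).transform("size")
                    log.warning(
                        "scenario %s decade %d: zero county sum with positive "
                        "control; distributing uniformly", ssp, d)
                    scaled = np.where(np.isnan(scaled), target / n_bg, scaled)
            else:
                # pre-control decades (e.g. 2000/2010) pass through unchanged
                scaled = p.to_numpy()
            records.append(pd.DataFrame({
                "block_group_id": population.index,
                "county_id": county.to_numpy(),
                "ssp": ssp, "decade": d, "population": scaled,
            }))
    return pd.concat(records, ignore_index=True)
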