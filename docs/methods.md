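# Methods

This note documents the models implemented in `coastal_eae`, the choices
made where the design was genuinely open, and what the synthetic study
region does and does not establish about real coastal data.

## Overview

The pipeline estimates how many people live in harm's way on a coast, now
and through 2100, by combining two independent models on a shared raster:

1. a **small-area demographic model** (housing-unit method) that
   reconstructs block-group populations for 1940–2010 and projects them to
   2100 under Shared Socioeconomic Pathway (SSP) county controls, and
2. a **flood-hazard model** that turns tide-station extreme-value records
   and Monte Carlo sea-level-rise (SLR) ensembles into per-pixel annual
   flood-exceedance probabilities over a hydrologically refined bathtub
   DEM.

Their product is population exposure in four cumulative zones per decade
and emissions scenario: land below the high-tide line (MHHW), the
SLR-adjusted 100-year floodplain (annual exceedance probability ≥ 0.01),
the dynamic low-elevation coastal zone (LECZ, below 10 m + SLR), and the
expected annual exposure (EAE), the density-weighted sum of per-pixel
annual flood probabilities.

## Demographic model

Population follows the housing-unit identity P = H·PPHU + GQ (housing
units × persons per housing unit + group-quarters persons). PPHU and GQ
are ACS-style block-group attributes held constant over the horizon.

**Backcast (1940–2010).** The county census control C_j^v for decade v is
allocated to block groups proportionally to their housing stock built
before v (the pre-v vintage sum from a "year structure built" table):

    Ĥ_ij^v = C_j^v · (pre-v vintage sum of block group i) / (county pre-v sum)

County sums reproduce the controls exactly. A zero county denominator with
a positive control is a hard error naming the county and decade; the
synthetic generator guarantees a positive pre-1940 stock everywhere.

**Projection (2020–2100).** Each block group is classified by the sign of
the OLS slope of its 1940–2010 series (the simplest deterministic reading
of "growing" vs "declining"). Growing groups follow the fitted line;
declining groups follow a power law e^a·τ^b fitted by least squares of
log H on log τ, with τ = decades since 1930 so log τ is defined at 1940.
Both branches carry an additive anchor term [H^t − fit(t)] forcing the
curve through the launch-year stock (default launch 2010, configurable),
and are floored at zero. The same fitted curve is evaluated at both the
future time and the launch time; using two different coefficient orderings
in the two terms would break launch-year continuity.

**SSP control.** Unconstrained projections are raked to SSP county totals:
every block group in a county is scaled by (control / county sum), giving
exact conservation (relative tolerance ~1e−16 in practice, asserted at
1e−9). Controls supplied at coarser time steps are interpolated linearly;
a county with zero unconstrained population but a positive control has the
control spread uniformly (logged). Decades before the first control year
(2000, 2010) pass through uncontrolled and are identical across SSPs.

## DEM refinement

A bathtub rule floods everything below the water level, including inland
basins the ocean cannot reach. Rather than re-running connected components
for every water level of every scenario, the DEM is refined once over a
ladder of 41 water heights h_i = 0.25·i m (0–10 m above MHHW):

- `ThresholdIndexSurface`: the first ladder level at which a pixel is wet
  (elevation ≤ h_i);
- `ConnectedIndexSurface`: the first level at which it is wet **and**
  4-connected to the ocean seed through wet, non-levee pixels.

Pixels with ThresholdIndex < ConnectedIndex are isolated; their elevation
is raised to h_ConnectedIndex, after which plain thresholding of the
adjusted DEM agrees with connectivity-aware flooding at every ladder level
(the operation is idempotent). Numerical choices:

- **Ties are wet** (elevation ≤ h_i, not <). A strict inequality would
  leave a pixel raised to exactly h_i dry at its own connection level,
  breaking idempotence.
- **4-connectivity** (rook moves), so one-pixel levees cannot leak
  diagonally.
- **Levees are impassable at every level** (never wet); no overtopping or
  failure model.
- **The ocean seed is an explicit mask**, not inferred from elevation, so
  inland depressions below 0 m are not misread as ocean.
- Pixels above the 10 m ladder top carry a sentinel (−1) and are never
  adjusted. A levee-sealed basin that never connects at any level has no
  defined connection height; it is raised one ladder step above the top
  (10.25 m), removing it from the modelled flood domain — the only
  assignment under which re-refinement is a fixed point.

Connected components use `scipy.ndimage.label`; the test oracle is an
independent hand-coded breadth-first flood fill.

## Flood-frequency model

Each station's extremes form a marked Poisson process: events arrive at
rate λ/yr; heights above threshold u follow a generalized Pareto
distribution GPD(ξ, σ). ξ and σ are maximum-likelihood estimates on the
threshold excesses (`scipy.stats.genpareto.fit`, location fixed at 0);
λ is the exceedance count over the record length. Records shorter than
30 years or with fewer than 10 exceedances are rejected; zero-variance
excesses drive σ to its boundary and are returned flagged degenerate.
Station records here are event-level exceedances of a known threshold, so
the pipeline fits at that threshold; for raw height series the default is
the 95th percentile of recorded heights.

The expected number of annual events exceeding elevation E is

    N(E) = λ·(1 + ξ(E − u)/σ)^(−1/ξ)        (λ·e^{−(E−u)/σ} as ξ→0)

extrapolated below the threshold for 0 < E < u and zero beyond the upper
support bound u − σ/ξ when ξ < 0. Under Poisson arrivals the annual
exceedance probability is P = 1 − exp(−N(E)), clamped to [0, 1] and to
P = 1 at E ≤ 0: land at or below MHHW floods every year by definition.
This Poisson-GPD construction is the standard peaks-over-threshold route
from "heights and frequencies" to an annual probability.

**SLR integration.** For year y and Monte Carlo SLR samples SLR_j(y), the
law of total probability gives

    P(H ≥ E | Y=y) = (1/M) Σ_j P(H ≥ E − SLR_j(y) | Y=2000).

Curves are tabulated at E = 0–10 m in 0.1 m steps per station × scenario ×
decade. A constant-shift ensemble short-circuits to the baseline curve
evaluated at the shifted elevations, making the zero-SLR identity
bit-exact. Low/high bound runs replace the ensemble by its pointwise 5th/
95th-percentile trajectory (duplicated into a two-sample ensemble, which
the sample mean ignores).

**Rasterization.** Every land pixel ≤ 10 m takes its nearest station
(Euclidean grid distance, ties to the lowest station id) and its curve
value at the pixel's adjusted elevation; land above 10 m gets 0, ocean 1.
Interpolation between the 0.1 m nodes is **monotone cubic (PCHIP)**, not
piecewise linear: linear interpolation at this node spacing leaves errors
of several 1e−3 on the steep shoulder of the averaged curve, while PCHIP
is exact at the nodes, shape-preserving (so interpolated probabilities
inherit the column's monotone decrease), deterministic, and measured at
≤ ~7e−4 against direct per-pixel evaluation. Land below MHHW is clamped to
the E = 0 node (probability 1).

## Exposure

Per scenario × decade, three binary layers on the adjusted DEM: MHHW
(elevation ≤ median-ensemble SLR of the nearest station), RL100 (pixel
probability ≥ 0.01), LECZ (elevation ≤ 10 + median SLR). The median is
used for the deterministic layers because "the" SLR of an ensemble needs a
statistic; the median is robust and matches the central trajectory. The
100-year layer uses probability **≥** 0.01 — the inward side of the
threshold — since the floodplain is the land flooding at least once per
century on average. The LECZ is dynamic (10 m + SLR), so all three layers
nest: a submerged pixel has P ≥ 0.5 ≥ 0.01, and any pixel with P > 0 lies
within the 0–10 m lookup domain.

Populations are allocated by dry-land areal weighting: exposed = block
group population × (dry-land pixels in the layer / total dry-land pixels),
where dry land excludes wetlands. EAE sums probability × density over the
block group's dry pixels, with density = population / dry-land pixel
count; a group with no dry land contributes zero to everything. Fractional
persons are kept until report formatting. Percent changes are reported raw
and rounded to the nearest 5%, the granularity at which such relative
changes are conventionally quoted; a zero base yields an undefined (NaN)
change.

## Synthetic region

The generator emulates the statistical structure of the real inputs, not
their geography:

- **Terrain**: a linear ramp from an ocean edge past 10 m inland
  (default 80×100 grid of 100 m pixels), Gaussian roughness (σ = 0.10 m),
  a one-pixel intertidal fringe just below MHHW, one rectangular basin
  behind a 3 m ridge, one levee-enclosed lowland, and wetland patches on
  the near-shore strip. Counties are row bands, block groups column slices
  within them — areal weighting reduces to pixel counting, so polygon
  geometry adds nothing.
- **Stations**: 2 stations on the ocean edge, 50-year records, yearly
  event counts Poisson(λ = 3), heights u + GPD(ξ = 0.1, σ = 0.2 m) with
  u = 0.5 m — magnitudes typical of hourly-gauge surge climatologies.
  Records are event-level exceedances; declustering of hourly series is
  out of scope (no declustering rule is modelled, by design).
- **SLR**: M = 1000 samples (configurable; desk-scale stand-in for the
  10⁴-sample ensembles of published projections). Each sample shares one
  non-negative amplitude draw across scenarios and follows
  amp·R_s·(0.4·t + 0.6·t²) + VLM·(y−2000) with t = (y−2000)/100, scenario
  2100 rises R = (0.5, 0.9, 1.5) m and 1 mm/yr subsidence: smooth,
  accelerating, uncertainty-widening, zero at 2000, non-decreasing in
  time, and pointwise dominated across scenarios by construction.
- **Demographics**: per-block-group vintages by compound decadal growth
  drawn from (−15 %, +35 %) per decade (so both branches of the projection
  are exercised), census controls = county vintage stock × U(0.85, 1.25)
  noise, PPHU ∈ [1.5, 3.5], GQ ~ Poisson(30), SSP multipliers 0.98–1.08
  per decade anchored to the unconstrained 2020 projection.

One master seed feeds independent per-stage RNG streams
(`numpy.random.SeedSequence.spawn`), so outputs are bit-reproducible and
stage parameters are independent.

**What the synthetic region does not show.** It contains no real
topography, tides, datum transformations, storm climatology or migration;
its extremes are exactly GPD (no model misspecification), its SLR
trajectories exactly quadratic, and its wetlands static. Passing tests
therefore demonstrate the *computational* correctness of each stage
(conservation, connectivity, oracle equivalence, ordering, recovery of
known truth) and the qualitative hazard-outpaces-population result — not
the accuracy of any national exposure estimate, which requires licensed
elevation and population inputs.

## Problem sizes and runtime

Defaults — 80×100 grid, 2 stations, 1000-sample ensembles, 3 scenarios ×
11 decades, 5 SSPs — run the full pipeline in ~2 s and the whole test
suite in a few seconds; these sizes give Monte Carlo and estimator noise
far below every asserted tolerance (GPD recovery is checked as a median
over 20 independent 50-year records).

## Known limitations

- Nearest-station assignment with no between-station interpolation of
  return curves; exposure near the 1 % threshold is the most sensitive to
  this.
- No hydrodynamics, waves, rainfall compounding, levee overtopping, or
  adaptation; the bathtub model is known to overestimate extent.
- PPHU and GQ frozen at their base-period values; no age/sex/race
  decomposition or migration.
- The EAE density denominator is dry-land pixel count (consistent with the
  dry-land areal weighting of the binary zones); using total block-group
  area instead would lower densities where wetlands are extensive.
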