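"""Hydrological refinement of the elevation model.

A bathtub inundation rule floods every pixel below a water level, but land
behind ridges or levees is not actually reachable by the ocean. Rather than
re-running connected-components for every water level of every scenario,
the DEM itself is refined once: for the ladder of water heights 0-10 m at
0.25 m steps, two index surfaces record the first ladder level at which a
pixel is wet unconditionally (ThresholdIndexSurface) and the first level at
which it is wet AND 4-connected to the ocean through wet, non-levee pixels
(ConnectedIndexSurface). Pixels whose connected index exceeds their
threshold index are hydrologically isolated, and their elevation is raised
to the ladder height of their connected index, after which simple
thresholding of the adjusted DEM agrees with connectivity-aware flooding
at every level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

#: ladder of water heights above MHHW: h_i = 0.25 * i for i = 0..40
LADDER_STEP = 0.25
N_LEVELS = 41
LADDER = np.round(np.arange(N_LEVELS) * LADDER_STEP, 10)

#: index value for pixels never wet at any ladder level <= 10 m
SENTINEL = np.int16(-1)

_STRUCTURE_4 = ndimage.generate_binary_structure(2, 1)  # rook moves


@dataclass
class IndexSurfacePair:
    threshold_index: np.ndarray  # int16, SENTINEL where never wet
    connected_index: np.ndarray


def build_index_surfaces(elevation: np.ndarray, ocean_seed: np.ndarray,
                         levee: np.ndarray | None = None) -> IndexSurfacePair:
    """Compute threshold and connected index surfaces over the 41-level ladder.

    A pixel is wet at level i iff its elevation <= h_i (ties wet, so that a
    pixel raised to exactly h_i by :func:`adjust_dem` floods at its own
    connection level). Levee pixels are impassable and never wet. Connected
    wetness requires 4-connectivity to the ocean seed through wet pixels.

    Returns
    -------
    IndexSurfacePair with int16 surfaces; SENTINEL marks pixels never wet
    (elevation above the ladder top, levees, or — in the connected
    surface — land sealed off at every level).
    """
    elevation = np.asarray(elevation, dtype=np.float64)
    ocean_seed = np.asarray(ocean_seed, dtype=bool)
    levee = (np.zeros_like(ocean_seed) if levee is None
             else np.asarray(levee, dtype=bool))
    if not ocean_seed.any():
        raise ValueError("ocean seed mask is empty")

    # threshold index: first i with elevation <= 0.25*i, i.e. ceil(elev/0.25)
    thr = np.ceil(np.maximum(elevation, 0.0) / LADDER_STEP - 1e-9)
    thr_idx = np.where((elevation <= LADDER[-1]) & ~levee,
                       thr, float(SENTINEL)).astype(np.int16)

    conn_idx = np.full(elevation.shape, SENTINEL, dtype=np.int16)
    if (thr_idx == SENTINEL).all():
        log.warning("no pixel at or below the %.1f m ladder top", LADDER[-1])
        return IndexSurfacePair(thr_idx, conn_idx)

    for i, h in enumerate(LADDER):
        wet = (elevation <= h) & ~levee
        if not (wet & ocean_seed).any():
            continue
        labels, _ = ndimage.label(wet, structure=_STRUCTURE_4)
        ocean_labels = np.unique(labels[wet & ocean_seed])
        connected = wet & np.isin(labels, ocean_labels)
        newly = connected & (conn_idx == SENTINEL)
        conn_idx[newly] = i
    return IndexSurfacePair(thr_idx, conn_idx)


def adjust_dem(elevation: np.ndarray, surfaces: IndexSurfacePair
               ) -> tuple[np.ndarray, np.ndarray]:
    """Raise hydrologically isolated pixels to their connection height.

    Pixels with threshold index < connected index are isolated: simple
    thresholding would flood them before the ocean can reach them. Their
    elevation becomes h_connected_index. Pixels that never connect at any
    ladder level (levee-sealed basins) are raised just above the ladder
    top, so they are excluded from the modelled flood domain entirely.

    Returns
    -------
    (adjusted elevation float array, bool mask of adjusted pixels).
    Adjusted elevations are >= the originals; re-deriving index surfaces
    on the result gives threshold == connected everywhere (idempotence).
    """
    elevation = np.asarray(elevation, dtype=np.float64)
    thr, conn = surfaces.threshold_index, surfaces.connected_index

    wettable = thr != SENTINEL
    isolated = wettable & (conn != SENTINEL) & (thr < conn)
    sealed = wettable & (conn == SENTINEL)

    adjusted = elevation.copy()
    adjusted[isolated] = LADDER[conn[isolated]]
    adjusted[sealed] = LADDER[-1] + LADDER_STEP
    flags = isolated | sealed
    if flags.any():
        log.info("adjusted %d isolated pixels (%d sealed beyond ladder top)",
                 int(flags.sum()), int(sealed.sum()))
    return adjusted, flags


def refine(elevation: np.ndarray, ocean_seed: np.ndarray,
           levee: np.ndarray | None = None
           ) -> tuple[np.ndarray, np.ndarray, IndexSurfacePair]:
    """Convenience wrapper: build surfaces then adjust the DEM."""
    surfaces = build_index_surfaces(elevation, ocean_seed, levee)
    adjusted, flags = adjust_dem(elevation, surfaces)
    return adjusted, flags, surfaces
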