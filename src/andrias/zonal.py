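"""Zonal statistics: percent suitable habitat per administrative unit.

Zones (counties) are supplied either as an integer label raster aligned with
the suitability raster, or as polygons that are first rasterized by
cell-centre containment. Percentages are computed over assessed (non-nodata)
suitability cells only, so a county's figure reflects the area the model
actually evaluated.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import shapely

from .raster import GridAlignmentError, RasterGrid

__all__ = ["rasterize_zones", "percent_suitable_by_zone"]


def rasterize_zones(
    polygons: Sequence[tuple[int, "shapely.Geometry"]],
    target: RasterGrid,
) -> RasterGrid:
    """Burn zone polygons into an integer label raster.

    Each cell receives the id of the polygon containing its centre; cells in
    no polygon become nodata. Polygons whose *interiors* overlap are an
    error. Where a shared boundary passes exactly through a cell centre the
    first-listed polygon wins (deterministic tie rule).
    """
    ids = [int(zid) for zid, _ in polygons]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate zone ids in polygon list")
    xs, ys = target.cell_centers()
    flat_x, flat_y = xs.ravel(), ys.ravel()
    labels = np.full(flat_x.shape, target.nodata)
    interior_hits = np.zeros(flat_x.shape, dtype=int)
    for zid, geom in polygons:
        if not geom.is_valid:
            raise ValueError(f"zone {zid} has an invalid (self-intersecting?) geometry")
        touches = shapely.intersects_xy(geom, flat_x, flat_y)
        interior_hits += shapely.contains_xy(geom, flat_x, flat_y)
        unassigned = labels == target.nodata
        labels[touches & unassigned] = zid
    if (interior_hits > 1).any():
        n_bad = int((interior_hits > 1).sum())
        raise ValueError(
            f"overlapping zone polygons: {n_bad} cell centres fall strictly "
            "inside more than one polygon"
        )
    return target.like(labels.reshape(target.shape))


def percent_suitable_by_zone(
    suitability: RasterGrid,
    zones: RasterGrid,
    province_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-zone counts of assessed and suitable cells and percent suitable.

    Returns a DataFrame with columns ``zone_id``, ``n_cells`` (assessed
    cells: zoned and valid in the suitability layer), ``n_suitable`` and
    ``percent_suitable`` (NaN for zones whose every cell is nodata in the
    suitability layer). ``province_map`` (columns ``zone_id``, ``province``)
    is merged in when given.
    """
    if not suitability.same_grid(zones):
        raise GridAlignmentError("suitability and zone rasters are not aligned")
    zoned = zones.valid_mask()
    zone_ids = np.unique(zones.values[zoned]).astype(int)
    labels = zones.values.astype(int)
    assessed = zoned & suitability.valid_mask()

    # bincount over a compact relabelling keeps this O(cells)
    lut = {zid: k for k, zid in enumerate(zone_ids)}
    compact = np.full(labels.shape, -1)
    for zid, k in lut.items():
        compact[labels == zid] = k
    idx = compact[assessed]
    n_cells = np.bincount(idx, minlength=len(zone_ids)).astype(int)
    n_suitable = np.bincount(
        idx, weights=(suitability.values[assessed] == 1.0), minlength=len(zone_ids)
    ).astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_cells > 0, 100.0 * n_suitable / np.maximum(n_cells, 1), np.nan)
    table = pd.DataFrame(
        {
            "zone_id": zone_ids,
            "n_cells": n_cells,
            "n_suitable": n_suitable,
            "percent_suitable": pct,
        }
    )
    if province_map is not None:
        table = table.merge(
            province_map.rename(columns={province_map.columns[0]: "zone_id"}),
            on="zone_id",
            how="left",
        )
    return table
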