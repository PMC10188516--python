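"""Agricultural landscape generator: axis-aligned rectangular parcels on a
jittered grid, so parcels never overlap and areas are exact."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ..config import ACRE_M2, SimConfig

MIN_CELL_M = 40.0  # smallest usable grid cell edge


def gen_landscape(config: SimConfig) -> pd.DataFrame:
    """Lay out ``config.n_parcels`` rectangular parcels inside the region.

    Returns a DataFrame with columns ``parcel_id, x0, y0, x1, y1, acres, crop``
    (coordinates in planar meters).  Raises ``ValueError`` when the extent is
    too small to host the requested number of parcels.
    """
    width, height = config.region_extent
    n = config.n_parcels
    ncols = max(1, math.ceil(math.sqrt(n * width / height)))
    nrows = math.ceil(n / ncols)
    cell_w, cell_h = width / ncols, height / nrows
    if cell_w < MIN_CELL_M or cell_h < MIN_CELL_M:
        raise ValueError(
            f"region extent {config.region_extent} too small for {n} parcels "
            f"(grid cell {cell_w:.0f}x{cell_h:.0f} m)"
        )

    rng = config.rng("landscape")
    rows = []
    weights = np.asarray(config.crop_weights, dtype=float)
    weights = weights / weights.sum()
    for i in range(n):
        r, c = divmod(i, ncols)
        # jittered margins keep every parcel strictly inside its own cell
        mx0, mx1 = rng.uniform(0.03, 0.18, size=2) * cell_w
        my0, my1 = rng.uniform(0.03, 0.18, size=2) * cell_h
        x0 = c * cell_w + mx0
        x1 = (c + 1) * cell_w - mx1
        y0 = r * cell_h + my0
        y1 = (r + 1) * cell_h - my1
        crop = str(rng.choice(config.crops, p=weights))
        rows.append({
            "parcel_id": f"P{i:04d}",
            "x0": x0, "y0": y0, "x1": x1, "y1": y1,
            "acres": (x1 - x0) * (y1 - y0) / ACRE_M2,
            "crop": crop,
        })
    return pd.DataFrame(rows)


def parcels_to_geojson(parcels: pd.DataFrame) -> dict:
    """GeoJSON FeatureCollection (planar meters) for the parcel table."""
    feats = []
    for _, p in parcels.iterrows():
        ring = [[p.x0, p.y0], [p.x1, p.y0], [p.x1, p.y1], [p.x0, p.y1], [p.x0, p.y0]]
        feats.append({
            "type": "Feature",
            "properties": {"parcel_id": p.parcel_id, "acres": p.acres, "crop": p.crop},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    return {"type": "FeatureCollection", "features": feats}


def parcels_from_geojson(gj: dict) -> pd.DataFrame:
    """Inverse of :func:`parcels_to_geojson` for rectangular parcels."""
    rows = []
    for f in gj["features"]:
        xs, ys = zip(*f["geometry"]["coordinates"][0])
        rows.append({
            "parcel_id": f["properties"]["parcel_id"],
            "x0": min(xs), "y0": min(ys), "x1": max(xs), "y1": max(ys),
            "acres": f["properties"]["acres"], "crop": f["properties"]["crop"],
        })
    return pd.DataFrame(rows)
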