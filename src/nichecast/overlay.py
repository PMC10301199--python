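"""Risk classification of the current suitability surface and its
intersection with migration-route corridors.

Suitability is cut into three risk classes (low / medium / high) over
continuous boundaries; polyline routes are buffered into corridors and
the grid cells whose centers fall inside each corridor are tallied per
class, giving a per-route risk report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .model import SuitabilityMap
from .preprocess import KM_PER_DEG_LAT
from .raster import GridRaster
from .vector import VectorLayer

logger = logging.getLogger(__name__)

#: class boundaries (b0, b1, b2, b3): outside < b0 <= low <= b1 < medium
#: <= b2 < high <= b3.  The interior defaults split published touching
#: ranges (0.38|0.39 and 0.52|0.53) at their midpoints so that every
#: suitability value classifies.
DEFAULT_BREAKS = (0.15, 0.385, 0.525, 0.86)

CLASS_CODES = {"outside": 0, "low": 1, "medium": 2, "high": 3}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}


@dataclass
class RiskClassification:
    raster: GridRaster  # codes 0..3 per CLASS_CODES; nodata preserved
    breaks: tuple[float, float, float, float]

    def counts(self) -> dict[str, int]:
        valid = ~self.raster.nodata_mask
        vals = self.raster.values[valid].astype(int)
        return {name: int((vals == code).sum()) for name, code in CLASS_CODES.items()}


def classify_risk(suitability: SuitabilityMap,
                  breaks: tuple[float, float, float, float] = DEFAULT_BREAKS
                  ) -> RiskClassification:
    """Classify suitability into outside / low / medium / high.

    low = [b0, b1], medium = (b1, b2], high = (b2, b3]; values below
    b0 are outside, values above b3 are clamped into high with a
    warning.
    """
    b0, b1, b2, b3 = breaks
    if not b0 < b1 < b2 < b3:
        raise ValueError("breaks must be strictly increasing")
    r = suitability.raster
    v = r.values
    codes = np.zeros(r.shape, dtype=int)
    codes[(v >= b0) & (v <= b1)] = CLASS_CODES["low"]
    codes[(v > b1) & (v <= b2)] = CLASS_CODES["medium"]
    codes[(v > b2) & (v <= b3)] = CLASS_CODES["high"]
    over = (v > b3) & ~r.nodata_mask
    if over.any():
        logger.warning("classify_risk: %d cell(s) above the top break clamped into high",
                       int(over.sum()))
        codes[over] = CLASS_CODES["high"]
    codes[r.nodata_mask] = 0
    return RiskClassification(
        GridRaster(codes.astype(float), r.nodata_mask.copy(), r.transform, r.crs),
        tuple(float(b) for b in breaks))


def _buffer_route_deg(route, corridor_km: float, ref_lat: float):
    """Corridor polygon: route buffered by corridor_km (local degrees)."""
    deg = corridor_km / (KM_PER_DEG_LAT * max(math.cos(math.radians(ref_lat)), 1e-6))
    # buffer in degrees; anisotropy over a few degrees of latitude is
    # below the cell size for desk-scale corridors
    return route.buffer(max(deg, 1e-9))


def route_risk(classes: RiskClassification, routes: VectorLayer,
               corridor_km: float = 10.0) -> pd.DataFrame:
    """Per-route tallies of risk-class cells within a corridor.

    Each route is buffered to a corridor of half-width ``corridor_km``;
    grid cells whose centers fall inside are tallied per class.  The
    modal class is the most frequent non-outside class (ties go to the
    higher risk).  Routes entirely off-grid yield a zero row with a
    warning.
    """
    r = classes.raster
    lon, lat = r.cell_centers()
    lon_f, lat_f = lon.ravel(), lat.ravel()
    valid = ~r.nodata_mask.ravel()
    codes = r.values.ravel().astype(int)
    rows = []
    for i, route in enumerate(routes.geometries):
        attrs = routes.attributes[i]
        route_id = attrs.get("route_id", i)
        ref_lat = float(np.asarray(route.coords)[:, 1].mean()) if route.geom_type == "LineString" \
            else float(lat_f.mean())
        corridor = _buffer_route_deg(route, corridor_km, ref_lat)
        inside = shapely.contains_xy(corridor, lon_f, lat_f) & valid
        if not inside.any():
            logger.warning("route %s: corridor contains no grid cells", route_id)
        counts = {name: int((codes[inside] == code).sum())
                  for name, code in CLASS_CODES.items()}
        nz = [(counts[n], CLASS_CODES[n]) for n in ("low", "medium", "high")
              if counts[n] > 0]
        if nz:
            best = max(nz, key=lambda t: (t[0], t[1]))  # ties -> higher risk
            modal = CLASS_NAMES[best[1]]
            max_class = CLASS_NAMES[max(c for _, c in nz)]
        else:
            modal = "outside"
            max_class = "outside"
        length_km = _route_length_km(route)
        rows.append({"route_id": route_id, "length_km": length_km,
                     "cells_low": counts["low"], "cells_medium": counts["medium"],
                     "cells_high": counts["high"], "cells_outside": counts["outside"],
                     "modal_class": modal, "max_class": max_class})
    return pd.DataFrame(rows)


def _route_length_km(route) -> float:
    from .preprocess import great_circle_km
    coords = np.asarray(route.coords)
    total = 0.0
    for a, b in zip(coords[:-1], coords[1:]):
        total += great_circle_km((a[0], a[1]), (b[0], b[1]))
    return float(total)
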