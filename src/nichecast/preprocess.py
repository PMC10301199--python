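"""Occurrence preprocessing: de-duplication, spatial thinning, the
accessible (M) calibration region, and the calibration/test split.

Thinning follows the randomized-greedy maximum-independent-set strategy
used by spThin: repeatedly delete one of the records with the most
neighbours closer than the minimum distance, restart many times with
different substreams, and keep the largest surviving set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

from .occurrences import OccurrenceSet
from .vector import VectorLayer

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG_LAT = math.pi * EARTH_RADIUS_KM / 180.0


class EmptyRegionError(ValueError):
    """No ecoregion intersects any occurrence buffer."""


@dataclass(frozen=True)
class ThinningResult:
    retained: OccurrenceSet
    removed_count: int
    min_distance_km: float
    n_repetitions: int
    seed: int


@dataclass(frozen=True)
class CalibrationRegion:
    polygons: VectorLayer
    buffer_km: float
    source_occurrences: int

    def union(self):
        return self.polygons.union()


@dataclass(frozen=True)
class SplitResult:
    train: OccurrenceSet
    test: OccurrenceSet
    train_fraction: float
    seed: int


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in km between (lon, lat) points."""
    lon1, lat1 = math.radians(a[0]), math.radians(a[1])
    lon2, lat2 = math.radians(b[0]), math.radians(b[1])
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def pairwise_great_circle_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Full haversine distance matrix (km) for small point sets."""
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = (np.sin(dphi / 2) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def deduplicate(occs: OccurrenceSet, decimals: int = 6) -> OccurrenceSet:
    """Collapse exact coordinate duplicates (after rounding) to one record."""
    seen: set[tuple[float, float]] = set()
    kept = []
    for rec in occs.records:
        key = (round(rec[1], decimals), round(rec[2], decimals))
        if key not in seen:
            seen.add(key)
            kept.append(rec)
    return OccurrenceSet(tuple(kept))


def thin(occs: OccurrenceSet, min_distance_km: float = 5.0,
         n_repetitions: int = 100, seed: int = 0) -> ThinningResult:
    """Randomized greedy spatial thinning with restarts.

    Each repetition deletes, among the records with the largest number
    of neighbours within ``min_distance_km``, one chosen uniformly at
    random, until no violating pair remains; the largest retained set
    over all repetitions wins (ties: first found).  Deterministic given
    the seed.
    """
    if min_distance_km <= 0:
        raise ValueError("min_distance_km must be positive")
    if len(occs) == 0:
        raise ValueError("no occurrences to thin")
    n = len(occs)
    dist = pairwise_great_circle_km(occs.lon, occs.lat)
    adj = (dist < min_distance_km)
    np.fill_diagonal(adj, False)
    if not adj.any():
        return ThinningResult(occs, 0, min_distance_km, n_repetitions, seed)

    ss = np.random.SeedSequence(seed)
    best: np.ndarray | None = None
    for child in ss.spawn(n_repetitions):
        rng = np.random.default_rng(child)
        alive = np.ones(n, dtype=bool)
        deg = adj.sum(axis=1).astype(int)
        while True:
            worst = deg[alive].max() if alive.any() else 0
            if worst == 0:
                break
            cand = np.flatnonzero(alive & (deg == worst))
            victim = int(rng.choice(cand))
            alive[victim] = False
            deg[adj[victim]] -= 1
            deg[victim] = 0
        if best is None or alive.sum() > best.sum():
            best = alive.copy()
    retained = OccurrenceSet(tuple(r for r, a in zip(occs.records, best) if a))
    # retained pairs must all be >= min_distance_km apart
    sub = dist[np.ix_(best.nonzero()[0], best.nonzero()[0])]
    np.fill_diagonal(sub, np.inf)
    assert (sub >= min_distance_km).all(), "thinning produced a violating pair"
    return ThinningResult(retained, n - len(retained), min_distance_km,
                          n_repetitions, seed)


def max_retained_exhaustive(occs: OccurrenceSet, min_distance_km: float = 5.0) -> int:
    """Exhaustive maximum-independent-set size for tiny point sets (<= ~16).

    Test oracle for :func:`thin`; exponential in the number of points.
    """
    n = len(occs)
    if n > 16:
        raise ValueError("exhaustive search is limited to small instances")
    dist = pairwise_great_circle_km(occs.lon, occs.lat)
    conflict = [0] * n
    for i in range(n):
        for j in range(n):
            if i != j and dist[i, j] < min_distance_km:
                conflict[i] |= 1 << j
    best = 0
    for subset in range(1 << n):
        size = subset.bit_count()
        if size <= best:
            continue
        ok = True
        for i in range(n):
            if subset >> i & 1 and subset & conflict[i]:
                ok = False
                break
        if ok:
            best = size
    return best


def _buffer_polygon(lon: float, lat: float, radius_km: float,
                    n_vertices: int = 64) -> Polygon:
    """Geodesic-approximate circle: per-point polygon with local degree scaling."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    dlat = radius_km * np.cos(theta) / KM_PER_DEG_LAT
    coslat = max(math.cos(math.radians(lat)), 1e-6)
    dlon = radius_km * np.sin(theta) / (KM_PER_DEG_LAT * coslat)
    return Polygon(np.column_stack([lon + dlon, lat + dlat]))


def build_m_region(occs: OccurrenceSet, ecoregions: VectorLayer,
                   buffer_km: float = 100.0) -> CalibrationRegion:
    """Accessible-area M: ecoregions intersecting the occurrence buffers.

    Each occurrence gets a ~``buffer_km`` circle (64 vertices, local
    degree scaling); every whole ecoregion polygon intersecting the
    dissolved buffer union enters M.
    """
    if len(occs) == 0:
        raise ValueError("no occurrences")
    if buffer_km > 0:
        buffers = [_buffer_polygon(lo, la, buffer_km)
                   for lo, la in zip(occs.lon, occs.lat)]
        blob = shapely.unary_union(buffers)
    else:
        blob = shapely.unary_union([Point(lo, la) for lo, la in zip(occs.lon, occs.lat)])
    keep_idx = [i for i, g in enumerate(ecoregions.geometries) if g.intersects(blob)]
    if not keep_idx:
        raise EmptyRegionError("no ecoregion intersects any occurrence buffer")
    layer = VectorLayer([ecoregions.geometries[i] for i in keep_idx],
                        [ecoregions.attributes[i] for i in keep_idx])
    return CalibrationRegion(layer, buffer_km, len(occs))


def rasterize_region(region: CalibrationRegion, transform, shape) -> np.ndarray:
    """Boolean in-region mask on a grid (True = cell center inside M)."""
    nrows, ncols = shape
    rows, cols = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    lon, lat = transform.cell_center(rows, cols)
    geom = region.union()
    inside = shapely.contains_xy(geom, lon.ravel(), lat.ravel())
    # points exactly on the boundary count as inside
    inside |= shapely.intersects_xy(geom, lon.ravel(), lat.ravel())
    return inside.reshape(shape)


def split(occs: OccurrenceSet, train_fraction: float = 0.7,
          seed: int = 0) -> SplitResult:
    """Uniform random partition into calibration and test subsets."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(occs)
    n_train = int(round(train_fraction * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = set(order[:n_train].tolist())
    train = tuple(r for i, r in enumerate(occs.records) if i in train_idx)
    test = tuple(r for i, r in enumerate(occs.records) if i not in train_idx)
    return SplitResult(OccurrenceSet(train), OccurrenceSet(test),
                       train_fraction, seed)
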