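"""Scenario projection products: binary maps, range-change accounting,
scenario overlap and between-scenario variation.

One threshold — the least-training-presence threshold derived from the
CURRENT-period suitability at the calibration occurrences — binarizes
every scenario of a run.  Range change between two binary maps is
reported as conserved / gained / lost pixel counts; because published
percentage bases for these quantities are often ambiguous, the raw
counts and all denominators are always part of the summary so any
convention can be recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import calibration_threshold
from .model import SuitabilityMap
from .raster import GridRaster, RasterStack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    stack: RasterStack
    co2_ppm_label: str = ""


@dataclass
class BinaryMap:
    raster: GridRaster
    threshold: float
    E_percent: float
    scenario: str = ""

    @property
    def presence_mask(self) -> np.ndarray:
        return (self.raster.values > 0.5) & ~self.raster.nodata_mask

    @property
    def presence_count(self) -> int:
        return int(self.presence_mask.sum())


@dataclass(frozen=True)
class ChangeSummary:
    scenario_pair: tuple[str, str]
    conserved_px: int
    gained_px: int
    lost_px: int
    conserved_pct: float
    gained_pct: float
    lost_pct: float
    denominators: dict = field(default_factory=dict)


def suitability_at_occurrences(suitability: SuitabilityMap, occs) -> np.ndarray:
    vals = suitability.raster.sample(occs.lon, occs.lat)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no calibration occurrence falls on the suitability grid")
    return vals


def threshold_from_occurrences(current: SuitabilityMap, calibration_occs,
                               E_percent: float = 5.0) -> float:
    """Least-training-presence threshold from the current-period map."""
    return calibration_threshold(suitability_at_occurrences(current, calibration_occs),
                                 E_percent)


def binarize(suitability: SuitabilityMap, calibration_occs=None,
             E_percent: float = 5.0, threshold: float | None = None,
             scenario: str = "") -> BinaryMap:
    """Presence/absence map: presence where suitability >= threshold.

    The threshold is either given explicitly (projections of future
    scenarios reuse the current-period threshold) or derived from the
    calibration occurrences on this map.
    """
    if threshold is None:
        if calibration_occs is None:
            raise ValueError("need calibration_occs or an explicit threshold")
        threshold = threshold_from_occurrences(suitability, calibration_occs, E_percent)
    r = suitability.raster
    binary = (r.values >= threshold).astype(float)
    binary[r.nodata_mask] = 0.0
    return BinaryMap(GridRaster(binary, r.nodata_mask.copy(), r.transform, r.crs),
                     float(threshold), E_percent, scenario)


def coverage_change(current: BinaryMap, future: BinaryMap,
                    pair: tuple[str, str] | None = None) -> ChangeSummary:
    """Conserved / gained / lost pixels between two binary maps.

    conserved = |A∩B|, gained = |B\\A|, lost = |A\\B|.  Percentages use
    the union as the conserved base and the current area for gained
    and lost; all denominators ship with the summary.
    """
    if current.raster.shape != future.raster.shape:
        raise ValueError("binary maps are on different grids")
    a = current.presence_mask
    b = future.presence_mask
    conserved = int((a & b).sum())
    gained = int((b & ~a).sum())
    lost = int((a & ~b).sum())
    n_a, n_b = int(a.sum()), int(b.sum())
    union = conserved + gained + lost
    if n_a == 0:
        raise ValueError("current map has no presence pixels; percentage bases undefined")
    assert conserved + lost == n_a and conserved + gained == n_b
    if pair is None:
        pair = (current.scenario or "current", future.scenario or "future")
    return ChangeSummary(
        scenario_pair=pair,
        conserved_px=conserved, gained_px=gained, lost_px=lost,
        conserved_pct=100.0 * conserved / union if union else 0.0,
        gained_pct=100.0 * gained / n_a,
        lost_pct=100.0 * lost / n_a,
        denominators={"conserved": union, "gained": n_a, "lost": n_a,
                      "area_current": n_a, "area_future": n_b})


def consensus_compare(map_a: BinaryMap, map_b: BinaryMap,
                      pair: tuple[str, str] | None = None) -> ChangeSummary:
    """Cross-family comparison (e.g. an RCP map against its paired SSP)."""
    return coverage_change(map_a, map_b, pair=pair)


#: overlap category encoding: code = 10*current + (count of futures present)
def scenario_overlap(current: BinaryMap, futures: list[BinaryMap]) -> tuple[GridRaster, dict]:
    """Categorical overlap raster of current and future presences.

    Cell code = 10·(current presence) + (number of future maps with
    presence); the legend maps codes to readable category names.
    """
    cur = current.presence_mask.astype(int)
    counts = np.zeros(current.raster.shape, dtype=int)
    for f in futures:
        if f.raster.shape != current.raster.shape:
            raise ValueError("future map grid differs from current")
        counts += f.presence_mask.astype(int)
    codes = 10 * cur + counts
    legend = {0: "absent"}
    n = len(futures)
    for j in range(1, n + 1):
        legend[j] = f"future only ({j} scenario{'s' if j > 1 else ''})"
    legend[10] = "current only"
    for j in range(1, n + 1):
        legend[10 + j] = f"current + {j} scenario{'s' if j > 1 else ''}"
    raster = GridRaster(codes.astype(float), current.raster.nodata_mask.copy(),
                        current.raster.transform, current.raster.crs)
    return raster, legend


def variation_map(binaries: list[BinaryMap],
                  n_classes: int = 3) -> tuple[GridRaster, dict]:
    """Between-scenario variation classed low / medium / high.

    Per cell, p̂ is the mean presence across the k scenario maps and
    the variation v = p̂(1 − p̂) (binomial variance, max 0.25 at maximal
    disagreement); cells are classed by equal-interval breaks on
    [0, 0.25].
    """
    if not binaries:
        raise ValueError("need at least one binary map")
    shape = binaries[0].raster.shape
    acc = np.zeros(shape)
    for b in binaries:
        if b.raster.shape != shape:
            raise ValueError("binary maps are on different grids")
        acc += b.presence_mask
    p = acc / len(binaries)
    v = p * (1.0 - p)
    edges = np.linspace(0.0, 0.25, n_classes + 1)
    classes = np.clip(np.digitize(v, edges[1:-1], right=True), 0, n_classes - 1)
    names = ["low", "medium", "high"] if n_classes == 3 else [
        f"class{i}" for i in range(n_classes)]
    legend = {i: names[i] for i in range(n_classes)}
    mask = binaries[0].raster.nodata_mask.copy()
    return GridRaster(classes.astype(float), mask,
                      binaries[0].raster.transform, binaries[0].raster.crs), legend
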