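"""Synthetic geodata with known truth.

Generates bioclim-like predictor stacks (spatially autocorrelated,
mutually correlated Gaussian random fields), a logistic-of-linear-
predictor suitability truth, presence samples drawn proportionally to
that truth, rectangular ecoregion tilings, migration-route polylines,
and additively shifted "future" stacks.  Every generator is a pure
function of its spec and seed.

The default desk-scale world is a 120x120-cell grid over a 3x3-degree
extent, which puts cells in the same 1-km size class as the real
bioclim products while keeping full pipeline runs at minutes scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, optimize
from shapely.geometry import LineString, box

from .occurrences import OccurrenceSet
from .raster import GridRaster, GridTransform, RasterStack
from .vector import VectorLayer


@dataclass
class SimulationSpec:
    """Parameters of the synthetic world.

    ``true_coefficients`` maps layer names to the coefficients of the
    linear predictor on z-scored layers; unnamed layers are noise.
    """

    grid_shape: tuple[int, int] = (120, 120)
    extent_deg: tuple[float, float, float, float] = (-100.0, 20.0, -97.0, 23.0)
    n_layers: int = 8
    spatial_corr_length: float = 8.0
    inter_layer_corr: np.ndarray | None = None
    true_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"env1": 1.5, "env2": -1.0})
    n_presences: int = 300
    target_prevalence: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_presences < 25:
            raise ValueError("n_presences must be at least 25")
        if not any(abs(c) > 0 for c in self.true_coefficients.values()):
            raise ValueError("true_coefficients needs at least one nonzero entry")
        if self.inter_layer_corr is not None:
            C = np.asarray(self.inter_layer_corr, dtype=float)
            if C.shape != (self.n_layers, self.n_layers):
                raise ValueError("inter_layer_corr shape mismatch")
            if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
                raise ValueError("inter_layer_corr must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ValueError("inter_layer_corr must be positive semidefinite")

    @property
    def layer_names(self) -> list[str]:
        return [f"env{i + 1}" for i in range(self.n_layers)]

    @property
    def transform(self) -> GridTransform:
        west, south, east, north = self.extent_deg
        nrows, ncols = self.grid_shape
        return GridTransform(west=west, north=north,
                             dx=(east - west) / ncols, dy=(north - south) / nrows)


def simulate_stack(spec: SimulationSpec) -> RasterStack:
    """Smoothed, cross-correlated Gaussian random fields as layers.

    White noise per layer is kernel-smoothed (Gaussian kernel,
    sigma = ``spatial_corr_length`` cells), standardized, then linearly
    mixed through the Cholesky-type factor of ``inter_layer_corr`` so
    empirical between-layer correlations approximate the target.
    Each layer is given a distinct affine scale so min-max feature
    scaling downstream is non-trivial.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.grid_shape
    fields = rng.standard_normal((spec.n_layers, nrows, ncols))
    for i in range(spec.n_layers):
        f = ndimage.gaussian_filter(fields[i], sigma=spec.spatial_corr_length,
                                    mode="reflect")
        fields[i] = (f - f.mean()) / f.std()
    if spec.n_layers > 1:
        # smoothing leaves few effective degrees of freedom, so raw
        # fields carry sizeable chance correlations; whiten empirically
        # before applying the target mixing so realized between-layer
        # correlations track inter_layer_corr closely
        flat = fields.reshape(spec.n_layers, -1)
        S = np.cov(flat)
        w_s, V_s = np.linalg.eigh(S)
        W = V_s @ np.diag(1.0 / np.sqrt(np.maximum(w_s, 1e-12))) @ V_s.T
        flat = W @ flat
        if spec.inter_layer_corr is not None:
            C = np.asarray(spec.inter_layer_corr, dtype=float)
            w, V = np.linalg.eigh(C)
            L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T
            flat = L @ flat
        flat /= flat.std(axis=1, keepdims=True)
        fields = flat.reshape(spec.n_layers, nrows, ncols)
    mask = np.zeros((nrows, ncols), dtype=bool)
    layers = {}
    for i, name in enumerate(spec.layer_names):
        scaled = fields[i] * (1.0 + 0.5 * i) + 10.0 * i
        layers[name] = GridRaster(scaled, mask.copy(), spec.transform)
    return RasterStack(layers)


def true_suitability(stack: RasterStack, spec: SimulationSpec) -> GridRaster:
    """Logistic suitability truth on z-scored layers.

    s(x) = sigmoid(a + sum_v c_v z_v(x)); the intercept a is solved so
    mean suitability over valid cells hits ``target_prevalence``.
    """
    bad = stack.combined_mask
    if bad.all():
        raise ValueError("stack has no valid cells")
    eta = np.zeros(stack.shape)
    for name, c in spec.true_coefficients.items():
        if c == 0 or name not in stack:
            continue
        vals = stack[name].values
        good = vals[~bad]
        z = (vals - good.mean()) / good.std()
        eta = eta + c * z

    def mean_suit(a: float) -> float:
        s = 1.0 / (1.0 + np.exp(-(a + eta[~bad])))
        return float(s.mean())

    a = optimize.brentq(lambda a: mean_suit(a) - spec.target_prevalence, -30, 30)
    s = 1.0 / (1.0 + np.exp(-(a + eta)))
    s[bad] = 0.0
    return GridRaster(s, bad.copy(), stack.transform, stack.crs)


def sample_occurrences(truth: GridRaster, n: int, seed: int,
                       species: str = "synthetic-species") -> OccurrenceSet:
    """Draw cells without replacement with probability proportional to truth.

    Records are placed at cell centers.  Deterministic given the seed.
    """
    valid = np.flatnonzero(~truth.nodata_mask.ravel())
    if n > valid.size:
        raise ValueError(f"cannot draw {n} cells from {valid.size} valid cells")
    w = truth.values.ravel()[valid].astype(float)
    if w.sum() <= 0:
        raise ValueError("truth has no positive suitability")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(valid, size=n, replace=False, p=w / w.sum())
    ncols = truth.shape[1]
    rows, cols = np.divmod(chosen, ncols)
    lon, lat = truth.transform.cell_center(rows, cols)
    return OccurrenceSet.from_arrays(lon, lat, species=species)


def perturb_future(stack: RasterStack, deltas: Mapping[str, float]) -> RasterStack:
    """Additively shift layers by per-layer deltas (grid and mask unchanged)."""
    layers = {}
    for name, lyr in stack.items():
        d = float(deltas.get(name, 0.0))
        layers[name] = lyr.copy_with(lyr.values + d)
    return RasterStack(layers)


def simulate_vectors(spec: SimulationSpec, k: int = 9,
                     n_routes: int = 3) -> tuple[VectorLayer, VectorLayer]:
    """Rectangular ecoregion tiling of the extent plus crossing routes.

    The tiling partitions the extent into ``k`` rectangles (nearest
    factorization grid); routes are jittered south-to-north polylines.
    Deterministic given ``spec.seed``.
    """
    west, south, east, north = spec.extent_deg
    kx = int(np.ceil(np.sqrt(k)))
    ky = int(np.ceil(k / kx))
    # trim so kx*ky tiles but only the first k kept when k < kx*ky
    xs = np.linspace(west, east, kx + 1)
    ys = np.linspace(south, north, ky + 1)
    tiles = []
    for j in range(ky):
        for i in range(kx):
            tiles.append(box(xs[i], ys[j], xs[i + 1], ys[j + 1]))
    if k < len(tiles):
        # merge the surplus tiles into the last kept tile so the
        # tiling still partitions the full extent
        import shapely
        keep = tiles[:k - 1]
        keep.append(shapely.unary_union(tiles[k - 1:]))
        tiles = keep
    eco = VectorLayer(tiles, [{"ecoregion_id": i} for i in range(len(tiles))])

    rng = np.random.default_rng(spec.seed + 104729)
    routes = []
    margin = 0.05 * (east - west)
    for r in range(n_routes):
        x0 = rng.uniform(west + margin, east - margin)
        n_pts = 12
        lats = np.linspace(south, north, n_pts)
        lons = np.clip(x0 + np.cumsum(rng.normal(0, 0.08 * (east - west), n_pts)),
                       west + 1e-9, east - 1e-9)
        lats = np.clip(lats, south + 1e-9, north - 1e-9)
        routes.append(LineString(np.column_stack([lons, lats])))
    rts = VectorLayer(routes, [{"route_id": i} for i in range(n_routes)])
    return eco, rts
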