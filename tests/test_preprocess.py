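import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nichecast.occurrences import OccurrenceSet
from nichecast.preprocess import (EmptyRegionError, build_m_region, deduplicate,
                                  great_circle_km, max_retained_exhaustive,
                                  rasterize_region, split, thin)
from nichecast.simulate import SimulationSpec, simulate_vectors

KM_PER_DEG = 111.19


def occ(*pts):
    return OccurrenceSet.from_arrays([p[0] for p in pts], [p[1] for p in pts])


class TestDeduplicate:
    def test_exact_duplicates_collapse(self):
        assert len(deduplicate(occ((1.0, 2.0), (1.0, 2.0)))) == 1

    def test_fifth_decimal_difference_kept(self):
        # ~1 m apart: not duplicates
        assert len(deduplicate(occ((1.00001, 2.0), (1.00002, 2.0)))) == 2

    def test_unique_input_unchanged(self):
        o = occ((1.0, 2.0), (3.0, 4.0))
        assert deduplicate(o).records == o.records


class TestGreatCircle:
    def test_identical_points_zero(self):
        assert great_circle_km((5.0, 5.0), (5.0, 5.0)) == 0.0

    def test_one_degree_latitude(self):
        # haversine closed form with R = 6371.0088
        assert great_circle_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(111.19, abs=0.01)

    def test_symmetric(self):
        a, b = (-99.0, 20.0), (-98.3, 21.7)
        assert great_circle_km(a, b) == great_circle_km(b, a)


class TestThin:
    def test_already_sparse_identity(self):
        o = occ((0.0, 0.0), (0.0, 0.1), (0.0, 0.2))  # ~11 km apart
        res = thin(o, 5.0, 10, seed=1)
        assert res.removed_count == 0
        assert res.retained.records == o.records

    def test_collinear_points_keep_endpoints(self):
        # points at 0, 4, 8 km along a meridian: only the middle conflicts
        d = 4.0 / KM_PER_DEG
        o = occ((0.0, 0.0), (0.0, d), (0.0, 2 * d))
        res = thin(o, 5.0, 10, seed=1)
        assert len(res.retained) == 2
        lats = sorted(r[2] for r in res.retained.records)
        assert lats == pytest.approx([0.0, 2 * d])

    def test_matches_exhaustive_maximum(self):
        # 15 km square in degrees
        side = 15.0 / KM_PER_DEG
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            o = OccurrenceSet.from_arrays(rng.uniform(0, side, 10),
                                          rng.uniform(0, side, 10))
            res = thin(o, 5.0, 100, seed=seed)
            wins += len(res.retained) == max_retained_exhaustive(o, 5.0)
        assert wins >= 19

    def test_retained_pairs_respect_min_distance(self):
        rng = np.random.default_rng(5)
        o = OccurrenceSet.from_arrays(rng.uniform(0, 0.3, 40), rng.uniform(0, 0.3, 40))
        res = thin(o, 5.0, 20, seed=2)
        pts = list(zip(res.retained.lon, res.retained.lat))
        for i, a in enumerate(pts):
            for b in pts[i + 1:]:
                assert great_circle_km(a, b) >= 5.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        o = OccurrenceSet.from_arrays(rng.uniform(0, 0.2, 30), rng.uniform(0, 0.2, 30))
        assert thin(o, 5, 10, seed=9).retained.records == thin(o, 5, 10, seed=9).retained.records

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            thin(occ((0, 0)), min_distance_km=0.0)


class TestMRegion:
    @pytest.fixture(scope="class")
    def eco(self):
        spec = SimulationSpec(seed=0)
        return simulate_vectors(spec, k=9)[0]

    def test_single_occurrence_selects_nearby_tiles(self, eco):
        # center of the middle tile of a 3x3 tiling over (-100,20)-(-97,23)
        o = occ((-98.5, 21.5))
        region = build_m_region(o, eco, buffer_km=100.0)
        ids = {a["ecoregion_id"] for a in region.polygons.attributes}
        assert 4 in ids  # middle tile always selected
        # oracle: exactly the tiles within 100 km of the point
        expected = {i for i, g in enumerate(eco.geometries)
                    if g.distance(__import__("shapely").geometry.Point(-98.5, 21.5))
                    * KM_PER_DEG <= 100.0 + 1.0}
        assert ids == expected

    def test_zero_buffer_keeps_only_containing_tiles(self, eco):
        o = occ((-98.5, 21.5))
        region = build_m_region(o, eco, buffer_km=0.0)
        assert {a["ecoregion_id"] for a in region.polygons.attributes} == {4}

    def test_area_monotone_in_buffer(self, eco):
        o = occ((-98.5, 21.5))
        areas = [build_m_region(o, eco, buffer_km=b).union().area
                 for b in (0.0, 50.0, 100.0, 200.0)]
        assert all(a2 >= a1 for a1, a2 in zip(areas, areas[1:]))

    def test_region_at_least_one_selected_polygon_area(self, eco):
        o = occ((-98.5, 21.5))
        region = build_m_region(o, eco, buffer_km=100.0)
        union_area = region.union().area
        for g in region.polygons.geometries:
            assert union_area >= g.area - 1e-12

    def test_disjoint_ecoregions_raise(self, eco):
        far = occ((10.0, 10.0))
        with pytest.raises(EmptyRegionError):
            build_m_region(far, eco, buffer_km=10.0)

    def test_rasterized_mask_covers_occurrence_cells(self, eco):
        spec = SimulationSpec(seed=0)
        o = occ((-98.5, 21.5))
        region = build_m_region(o, eco, buffer_km=100.0)
        mask = rasterize_region(region, spec.transform, spec.grid_shape)
        row, col = spec.transform.locate(-98.5, 21.5)
        assert mask[row, col]


class TestSplit:
    def test_seventy_thirty_arithmetic(self):
        o = OccurrenceSet.from_arrays(np.arange(10, dtype=float), np.zeros(10))
        res = split(o, 0.7, seed=0)
        assert (len(res.train), len(res.test)) == (7, 3)

    def test_deterministic_and_seed_sensitive(self):
        o = OccurrenceSet.from_arrays(np.arange(50, dtype=float), np.zeros(50))
        a, b = split(o, 0.7, seed=1), split(o, 0.7, seed=1)
        assert a.train.records == b.train.records
        c = split(o, 0.7, seed=2)
        assert c.train.records != a.train.records

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(n=st.integers(2, 200), frac=st.floats(0.1, 0.9), seed=st.integers(0, 10**6))
    def test_partition_invariants(self, n, frac, seed):
        o = OccurrenceSet.from_arrays(np.linspace(-10, 10, n), np.zeros(n))
        res = split(o, frac, seed=seed)
        train, test = set(res.train.records), set(res.test.records)
        assert train | test == set(o.records)
        assert not (train & test)
        assert abs(len(train) - frac * n) <= 1
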