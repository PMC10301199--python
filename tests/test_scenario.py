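import numpy as np
import pytest

from nichecast.model import SuitabilityMap
from nichecast.occurrences import OccurrenceSet
from nichecast.raster import GridRaster, GridTransform
from nichecast.scenario import (BinaryMap, binarize, consensus_compare,
                                coverage_change, scenario_overlap,
                                variation_map)

T = GridTransform(0.0, 10.0, 1.0, 1.0)


def suit_map(vals, mask=None):
    vals = np.asarray(vals, dtype=float)
    if mask is None:
        mask = np.zeros(vals.shape, dtype=bool)
    return SuitabilityMap(GridRaster(vals, mask, T))


def binary(mask_arr, scenario=""):
    vals = np.asarray(mask_arr, dtype=float)
    return BinaryMap(GridRaster(vals, np.zeros(vals.shape, bool), T),
                     threshold=0.5, E_percent=5.0, scenario=scenario)


class TestBinarize:
    def test_E0_single_occurrence_at_max(self):
        vals = np.linspace(0, 1, 100).reshape(10, 10)
        m = suit_map(vals)
        r, c = np.unravel_index(np.argmax(vals), vals.shape)
        lon, lat = T.cell_center(r, c)
        occs = OccurrenceSet.from_arrays([lon], [lat])
        bm = binarize(m, calibration_occs=occs, E_percent=0)
        assert bm.presence_count == 1
        assert bm.raster.values[r, c] == 1.0

    def test_coverage_of_calibration_occurrences(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, (20, 20))
        m = suit_map(vals)
        rows, cols = np.divmod(rng.choice(400, 50, replace=False), 20)
        lon, lat = T.cell_center(rows, cols)
        occs = OccurrenceSet.from_arrays(lon, lat)
        E = 10
        bm = binarize(m, calibration_occs=occs, E_percent=E)
        at = m.raster.sample(occs.lon, occs.lat)
        inside = (at >= bm.threshold).mean()
        assert inside >= (100 - E) / 100.0

    def test_presence_area_non_increasing_in_E(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, (15, 15))
        m = suit_map(vals)
        rows, cols = np.divmod(rng.choice(225, 40, replace=False), 15)
        lon, lat = T.cell_center(rows, cols)
        occs = OccurrenceSet.from_arrays(lon, lat)
        # a larger tolerated omission E raises the threshold, so the
        # predicted presence area can only shrink or stay equal
        areas = [binarize(m, calibration_occs=occs, E_percent=E).presence_count
                 for E in (0, 5, 10, 25)]
        assert all(b <= a for a, b in zip(areas, areas[1:]))

    def test_explicit_threshold_respected(self):
        vals = np.array([[0.2, 0.6], [0.7, 0.1]])
        bm = binarize(suit_map(vals), threshold=0.5)
        assert bm.presence_count == 2


class TestCoverageChange:
    def test_identity_future(self):
        a = binary(np.eye(5), "current")
        ch = coverage_change(a, binary(np.eye(5), "future"))
        assert (ch.conserved_pct, ch.gained_px, ch.lost_px) == (100.0, 0, 0)

    def test_doubling_future(self):
        cur = np.zeros((4, 4)); cur[0, :2] = 1
        fut = np.zeros((4, 4)); fut[0, :4] = 1
        ch = coverage_change(binary(cur), binary(fut))
        assert ch.lost_px == 0
        assert ch.conserved_pct == pytest.approx(50.0)
        assert ch.gained_pct == pytest.approx(100.0)

    def test_identities_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a = rng.integers(0, 2, (8, 8)).astype(float)
            if a.sum() == 0:
                a[0, 0] = 1
            b = rng.integers(0, 2, (8, 8)).astype(float)
            ch = coverage_change(binary(a), binary(b))
            assert ch.conserved_px + ch.lost_px == int(a.sum())
            assert ch.conserved_px + ch.gained_px == int(b.sum())

    def test_empty_current_errors(self):
        with pytest.raises(ValueError):
            coverage_change(binary(np.zeros((3, 3))), binary(np.eye(3)))

    def test_denominators_reported(self):
        ch = coverage_change(binary(np.eye(4)), binary(np.ones((4, 4))))
        assert ch.denominators["gained"] == 4
        assert ch.denominators["conserved"] == 16


class TestConsensusCompare:
    def test_identical_maps(self):
        ch = consensus_compare(binary(np.eye(5)), binary(np.eye(5)))
        assert ch.conserved_pct == 100.0 and ch.gained_px == 0 and ch.lost_px == 0

    def test_disjoint_maps(self):
        a = np.zeros((4, 4)); a[0] = 1
        b = np.zeros((4, 4)); b[1] = 1
        ch = consensus_compare(binary(a), binary(b))
        assert ch.conserved_px == 0

    def test_gained_lost_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, (6, 6)).astype(float); a[0, 0] = 1
        b = rng.integers(0, 2, (6, 6)).astype(float); b[0, 0] = 1
        assert (consensus_compare(binary(a), binary(b)).gained_px
                == consensus_compare(binary(b), binary(a)).lost_px)


class TestOverlap:
    def test_no_futures_two_categories(self):
        cur = binary(np.eye(4))
        codes, legend = scenario_overlap(cur, [])
        assert set(np.unique(codes.values)) <= {0.0, 10.0}
        assert legend[0] == "absent" and legend[10] == "current only"

    def test_present_everywhere_code(self):
        cur = binary(np.ones((3, 3)))
        futs = [binary(np.ones((3, 3))) for _ in range(4)]
        codes, legend = scenario_overlap(cur, futs)
        assert np.all(codes.values == 14)
        assert "current + 4" in legend[14]

    def test_category_counts_partition_grid(self):
        rng = np.random.default_rng(4)
        cur = binary(rng.integers(0, 2, (6, 6)).astype(float))
        futs = [binary(rng.integers(0, 2, (6, 6)).astype(float)) for _ in range(3)]
        codes, _ = scenario_overlap(cur, futs)
        vals, counts = np.unique(codes.values, return_counts=True)
        assert counts.sum() == 36


class TestVariation:
    def test_full_agreement_is_low(self):
        maps = [binary(np.eye(4)) for _ in range(4)]
        classes, legend = variation_map(maps)
        assert np.all(classes.values == 0)
        assert legend[0] == "low"

    def test_half_disagreement_is_high(self):
        on = binary(np.ones((3, 3)))
        off = binary(np.zeros((3, 3)))
        classes, legend = variation_map([on, on, off, off])
        assert np.all(classes.values == 2)
        assert legend[2] == "high"

    def test_invariant_to_scenario_order(self):
        rng = np.random.default_rng(5)
        maps = [binary(rng.integers(0, 2, (5, 5)).astype(float)) for _ in range(4)]
        a, _ = variation_map(maps)
        b, _ = variation_map(maps[::-1])
        assert np.array_equal(a.values, b.values)
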