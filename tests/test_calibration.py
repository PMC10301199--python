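import numpy as np
import pandas as pd
import pytest

from nichecast.calibration import (DEFAULT_RM_GRID, build_final,
                                   enumerate_candidates, pick_primary,
                                   results_table, run_calibration)
from nichecast.features import CLASS_COMBINATIONS, FeatureConfig
from nichecast.variables import VariableSet


def _sets(k=4, vars_=("a", "b")):
    return [VariableSet(f"Set{i + 1}", vars_) for i in range(k)]


class TestEnumerate:
    def test_full_grid_has_280_candidates(self):
        specs = enumerate_candidates(_sets(4), DEFAULT_RM_GRID, CLASS_COMBINATIONS)
        assert len(specs) == 280

    def test_minimal_grid_single_candidate(self):
        specs = enumerate_candidates(_sets(1), (1.0,), ("l",))
        assert len(specs) == 1

    def test_rm_grid_default_is_one_to_ten(self):
        assert DEFAULT_RM_GRID == tuple(float(i) for i in range(1, 11))

    def test_deterministic_canonical_order(self):
        specs = enumerate_candidates(_sets(1), (2.0, 1.0), ("l", "lq"))
        labels = [s.label for s in specs]
        assert labels == ["Set1_RM1_l", "Set1_RM1_lq", "Set1_RM2_l", "Set1_RM2_lq"]


@pytest.fixture(scope="module")
def sweep_tables():
    rng = np.random.default_rng(31)
    n = 1200
    bg = pd.DataFrame({"a": rng.uniform(0, 1, n), "b": rng.uniform(0, 1, n),
                       "c": rng.uniform(0, 1, n)})
    eta = np.array([3.0, -2.0, 0.0])
    w = np.exp(bg.to_numpy() @ eta)
    pres = bg.iloc[rng.choice(n, 200, p=w / w.sum())].reset_index(drop=True)
    return pres.iloc[:140], pres.iloc[140:], bg


class TestRunCalibration:
    def test_bookkeeping_includes_failures(self, sweep_tables):
        train, test, bg = sweep_tables
        bad_bg = bg.copy()
        bad_bg["k"] = 1.0  # constant layer: single-variable candidate fails
        bad_train = train.copy(); bad_train["k"] = 1.0
        bad_test = test.copy(); bad_test["k"] = 1.0
        sets = [VariableSet("good", ("a", "b")), VariableSet("broken", ("k",))]
        cands = enumerate_candidates(sets, (1.0,), ("l",))
        out = run_calibration(cands, bad_train, bad_test, bad_bg,
                              n_bootstrap=50, raise_if_empty=False)
        assert len(out) == len(cands)
        assert any(cr.failed for cr in out)
        assert any(not cr.failed for cr in out)

    def test_selection_monotone_in_delta(self, sweep_tables):
        train, test, bg = sweep_tables
        cands = enumerate_candidates([VariableSet("S", ("a", "b", "c"))],
                                     (1.0, 5.0), ("l", "lq"))
        loose = run_calibration(cands, train, test, bg, delta_max=2.0,
                                n_bootstrap=100, raise_if_empty=False)
        tight = run_calibration(cands, train, test, bg, delta_max=0.0,
                                n_bootstrap=100, raise_if_empty=False)
        sel_loose = {cr.spec.label for cr in loose if cr.selected}
        sel_tight = {cr.spec.label for cr in tight if cr.selected}
        assert sel_tight <= sel_loose

    def test_selected_implies_all_three_criteria(self, sweep_tables):
        train, test, bg = sweep_tables
        cands = enumerate_candidates([VariableSet("S", ("a", "b"))],
                                     (1.0, 2.0), ("l",))
        out = run_calibration(cands, train, test, bg, n_bootstrap=100,
                              raise_if_empty=False)
        cut = max(cr.omission.rate for cr in out if cr.selected)
        for cr in out:
            if cr.selected:
                assert cr.significant
                assert cr.omission.rate <= cut
                assert cr.delta_aicc <= 2.0

    def test_results_table_one_row_per_candidate(self, sweep_tables):
        train, test, bg = sweep_tables
        cands = enumerate_candidates([VariableSet("S", ("a", "b"))], (1.0,), ("l",))
        out = run_calibration(cands, train, test, bg, n_bootstrap=50,
                              raise_if_empty=False)
        df = results_table(out)
        assert len(df) == len(cands)
        assert {"mean_auc_ratio", "p_value", "omission_rate", "k", "aicc",
                "delta_aicc", "selected"} <= set(df.columns)

    def test_pick_primary_is_lowest_aicc_selected(self, sweep_tables):
        train, test, bg = sweep_tables
        cands = enumerate_candidates([VariableSet("S", ("a", "b", "c"))],
                                     (1.0, 2.0), ("l", "lq"))
        out = run_calibration(cands, train, test, bg, n_bootstrap=100,
                              raise_if_empty=False)
        primary = pick_primary(out)
        assert primary.selected
        assert primary.aicc.aicc == min(cr.aicc.aicc for cr in out if cr.selected)


class TestBuildFinal:
    @pytest.fixture(scope="class")
    def spec_and_world(self, small_stack, small_occs):
        from nichecast.calibration import CandidateSpec
        spec = CandidateSpec(VariableSet("S", ("env1", "env2")),
                             FeatureConfig(classes="l", regularization_multiplier=1.0))
        return spec, small_stack, small_occs

    def test_single_replicate_consensus_equals_map(self, spec_and_world):
        spec, stack, occs = spec_and_world
        fm = build_final(spec, stack, occs, n_replicates=1, seed=5)
        rep_map = fm.replicates[0].project(stack)
        assert np.allclose(fm.consensus_map.raster.values, rep_map.raster.values)

    def test_consensus_within_replicate_envelope(self, spec_and_world):
        spec, stack, occs = spec_and_world
        fm = build_final(spec, stack, occs, n_replicates=5, seed=6)
        maps = np.stack([r.project(stack).raster.values for r in fm.replicates])
        cons = fm.consensus_map.raster.values
        assert (cons >= maps.min(axis=0) - 1e-12).all()
        assert (cons <= maps.max(axis=0) + 1e-12).all()

    def test_replicate_spread_shrinks_with_sample_size(self, small_stack, small_truth):
        from nichecast.calibration import CandidateSpec
        from nichecast.simulate import sample_occurrences
        spec = CandidateSpec(VariableSet("S", ("env1", "env2")),
                             FeatureConfig(classes="l", regularization_multiplier=1.0))
        iqrs = {}
        for n in (60, 240):
            occs = sample_occurrences(small_truth, n, seed=77)
            fm = build_final(spec, small_stack, occs, n_replicates=5, seed=8)
            maps = np.stack([r.project(small_stack).raster.values
                             for r in fm.replicates])
            q75, q25 = np.percentile(maps, [75, 25], axis=0)
            iqrs[n] = (q75 - q25).mean()
        assert iqrs[240] < iqrs[60]

    def test_deterministic_given_seed(self, spec_and_world):
        spec, stack, occs = spec_and_world
        a = build_final(spec, stack, occs, n_replicates=2, seed=9)
        b = build_final(spec, stack, occs, n_replicates=2, seed=9)
        assert np.array_equal(a.consensus_map.raster.values,
                              b.consensus_map.raster.values)
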