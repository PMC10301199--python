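"""End-to-end synthetic recovery harness.

Wires every stage together on a synthetic world with known truth:
simulate predictors and presences -> deduplicate -> thin -> build the
accessible region -> split -> build variable sets -> calibrate the
candidate grid -> build the final consensus model -> project, binarize
and summarize scenario change.  Used by the recovery tests, the
acceptance script and the CLI's one-shot mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import preprocess, scenario as scen, simulate
from .calibration import (CandidateResult, FinalModel, build_final,
                          enumerate_candidates, pick_primary, run_calibration)
from .features import CLASS_COMBINATIONS
from .raster import RasterStack, extract_values
from .simulate import SimulationSpec
from .variables import build_variable_sets

logger = logging.getLogger(__name__)


@dataclass
class PipelineSettings:
    """Knobs of the desk-scale recovery run.

    The default candidate grid is a reduced but representative slice of
    the full 4 x 10 x 7 grid (three variable sets crossed with three
    multipliers and three class combinations) so a full run stays at
    minutes scale; the full grid is available by passing explicit
    grids.
    """

    thin_km: float = 5.0
    thin_reps: int = 20
    buffer_km: float = 100.0
    train_fraction: float = 0.7
    E_percent: float = 5.0
    rm_grid: tuple[float, ...] = (1.0, 2.0, 5.0)
    class_grid: tuple[str, ...] = ("l", "lq", "lqp")
    n_bootstrap_proc: int = 200
    n_replicates: int = 10
    max_background: int = 5000
    fit_tol: float = 1e-6
    future_deltas: dict = field(default_factory=lambda: {"env1": 1.0, "env2": 1.0})


@dataclass
class PipelineResult:
    spec: SimulationSpec
    settings: PipelineSettings
    stack: RasterStack
    truth: "object"
    occurrences: "object"
    thinned: "object"
    m_mask: np.ndarray
    candidates: list[CandidateResult]
    primary: CandidateResult
    final: FinalModel
    spearman_truth: float
    permutation_importance: pd.Series
    change: "object | None" = None


def run_pipeline(spec: SimulationSpec | None = None,
                 settings: PipelineSettings | None = None,
                 seed: int = 0, with_scenario: bool = True) -> PipelineResult:
    """Run the whole workflow on one synthetic world."""
    if spec is None:
        spec = SimulationSpec(seed=seed)
    if settings is None:
        settings = PipelineSettings()
    rng_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))

    stack = simulate.simulate_stack(spec)
    truth = simulate.true_suitability(stack, spec)
    occs = simulate.sample_occurrences(truth, spec.n_presences, seed=rng_seed + 1)
    eco, routes = simulate.simulate_vectors(spec)

    occs = preprocess.deduplicate(occs)
    thinned = preprocess.thin(occs, settings.thin_km, settings.thin_reps,
                              seed=rng_seed + 2)
    region = preprocess.build_m_region(thinned.retained, eco, settings.buffer_km)
    m_mask = preprocess.rasterize_region(region, stack.transform, stack.shape)
    split_res = preprocess.split(thinned.retained, settings.train_fraction,
                                 seed=rng_seed + 3)

    background = stack.to_table(mask=~m_mask)
    if len(background) > settings.max_background:
        bg_rng = np.random.default_rng(rng_seed + 4)
        idx = np.sort(bg_rng.choice(len(background), settings.max_background,
                                    replace=False))
        background = background.iloc[idx]
    pres_train = extract_values(stack, split_res.train)
    pres_test = extract_values(stack, split_res.test)

    var_sets = build_variable_sets(pres_train, background, seed=rng_seed + 5)
    # reduced default grid keeps the run at minutes scale; Set2's
    # arbitrary half-list carries no meaning on synthetic layers
    sets_used = [s for s in var_sets if s.name != "Set2"]
    candidates = enumerate_candidates(sets_used, settings.rm_grid, settings.class_grid)
    results = run_calibration(candidates, pres_train, pres_test, background,
                              E_percent=settings.E_percent,
                              n_bootstrap=settings.n_bootstrap_proc,
                              seed=rng_seed + 6, fit_tol=settings.fit_tol)
    primary = pick_primary(results)
    final = build_final(primary.spec, stack, thinned.retained, m_mask=m_mask,
                        n_replicates=settings.n_replicates, seed=rng_seed + 7,
                        max_background=settings.max_background,
                        fit_tol=settings.fit_tol)

    rho = suitability_truth_correlation(final, truth, m_mask)
    imp = permutation_importance(final, stack, m_mask, seed=rng_seed + 8)

    change = None
    if with_scenario:
        future = simulate.perturb_future(stack, settings.future_deltas)
        cur_map = final.consensus_map
        fut_model = final.replicates[0]
        # project the consensus via each replicate and take the median
        fut_maps = [r.project(future, m_mask=m_mask) for r in final.replicates]
        fut_vals = np.median([m.raster.values for m in fut_maps], axis=0)
        fut_map = fut_maps[0]
        fut_map.raster.values = fut_vals
        thr = scen.threshold_from_occurrences(cur_map, split_res.train,
                                              settings.E_percent)
        cur_bin = scen.binarize(cur_map, threshold=thr, scenario="current",
                                E_percent=settings.E_percent)
        fut_bin = scen.binarize(fut_map, threshold=thr, scenario="future",
                                E_percent=settings.E_percent)
        change = scen.coverage_change(cur_bin, fut_bin)

    return PipelineResult(spec, settings, stack, truth, occs, thinned, m_mask,
                          results, primary, final, rho, imp, change)


def suitability_truth_correlation(final: FinalModel, truth, m_mask) -> float:
    """Spearman correlation of consensus suitability vs truth inside M."""
    valid = ~final.consensus_map.raster.nodata_mask & m_mask
    a = final.consensus_map.raster.values[valid]
    b = truth.values[valid]
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def permutation_importance(final: FinalModel, stack: RasterStack, m_mask,
                           seed: int = 0) -> pd.Series:
    """Variable importance of the final model by column permutation.

    For each model variable, its column over the prediction cells is
    permuted and importance is 1 − Spearman(permuted map, original
    map): variables whose scrambling scrambles the map most rank first.
    """
    res = final.replicates[0]
    vars_ = final.spec.variable_set.variables
    table = stack.subset(list(vars_)).to_table(mask=~m_mask)
    base = np.median([r.predict(table, kind="logistic") for r in final.replicates],
                     axis=0)
    rng = np.random.default_rng(seed)
    out = {}
    for v in vars_:
        perm = table.copy()
        perm[v] = rng.permutation(perm[v].to_numpy())
        permed = np.median([r.predict(perm, kind="logistic") for r in final.replicates],
                           axis=0)
        rho, _ = stats.spearmanr(base, permed)
        if not np.isfinite(rho):
            rho = 1.0  # permutation changed nothing
        out[v] = 1.0 - float(rho)
    return pd.Series(out).sort_values(ascending=False)
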