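"""Predictor-set construction.

Four ways of choosing the predictor list for candidate models:
fixed literature-derived lists (Sets 1 and 2), jackknife single-variable
contribution ranking with a >90% cumulative cut plus Pearson pruning
(Set 3), and stepwise variance-inflation-factor elimination (Set 4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureConfig
from .model import ConvergenceError, MaxentModel

logger = logging.getLogger(__name__)

#: bioclim layers with known spatial anomalies, excluded up front
ANOMALOUS_BIOCLIM = ("Bio8", "Bio9", "Bio18", "Bio19")

#: default fixed predictor lists for bioclim-named stacks
SET1_BIOCLIM = ("Bio1", "Bio2", "Bio3", "Bio4", "Bio5", "Bio6", "Bio7",
                "Bio10", "Bio11", "Bio12", "Bio13", "Bio14", "Bio15",
                "Bio16", "Bio17")
SET2_BIOCLIM = ("Bio1", "Bio4", "Bio5", "Bio6", "Bio7", "Bio12", "Bio13",
                "Bio14", "Bio15")


@dataclass(frozen=True)
class VariableSet:
    """Named ordered predictor list with its construction rule."""

    name: str
    variables: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("a variable set cannot be empty")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variables in set")


def exclude_anomalous(stack, names=ANOMALOUS_BIOCLIM):
    """Drop known-anomalous bioclim layers if present; others untouched."""
    present = [n for n in names if n in stack]
    if not present:
        return stack
    return stack.drop(present)


def pearson_prune(data: pd.DataFrame, r_threshold: float = 0.8,
                  tiebreak_scores: pd.Series | None = None,
                  name: str = "pearson") -> VariableSet:
    """Iteratively drop one variable of each highly correlated pair.

    While any pair has |r| >= ``r_threshold``, the worst pair is found
    and the member with the lower tiebreak score is dropped (fallback:
    the member with higher mean |r| against all remaining variables).
    Constant variables are dropped first with a warning.
    """
    cols = list(data.columns)
    const = [c for c in cols if data[c].nunique() <= 1]
    if const:
        logger.warning("pearson_prune: dropping constant variable(s) %s", const)
        cols = [c for c in cols if c not in const]
    if len(cols) < 1:
        raise ValueError("no non-constant variables to prune")
    while len(cols) > 1:
        corr = data[cols].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < r_threshold:
            break
        a, b = cols[i], cols[j]
        if tiebreak_scores is not None and a in tiebreak_scores and b in tiebreak_scores:
            drop = a if tiebreak_scores[a] < tiebreak_scores[b] else b
        else:
            mean_r = corr.sum(axis=0) / (len(cols) - 1)
            drop = a if mean_r[i] > mean_r[j] else b
        cols.remove(drop)
    return VariableSet(name, tuple(cols),
                       provenance=f"pairwise Pearson pruning at |r| >= {r_threshold}")


def compute_vif(data: pd.DataFrame) -> pd.Series:
    """Variance inflation factors (with intercept); single column -> 1."""
    cols = list(data.columns)
    if len(cols) == 1:
        return pd.Series([1.0], index=cols)
    X = data.to_numpy(dtype=float)
    out = {}
    for idx, c in enumerate(cols):
        y = X[:, idx]
        others = np.delete(X, idx, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot <= 0:
            out[c] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_prune(data: pd.DataFrame, vif_threshold: float = 10.0,
              name: str = "Set4") -> VariableSet:
    """Drop the largest-VIF variable until max VIF <= threshold."""
    if data.shape[0] <= data.shape[1]:
        raise ValueError("need more samples than variables for VIF")
    cols = list(data.columns)
    while len(cols) > 1:
        vif = compute_vif(data[cols])
        worst = vif.idxmax()
        if vif[worst] <= vif_threshold:
            break
        cols.remove(worst)
    return VariableSet(name, tuple(cols),
                       provenance=f"stepwise VIF elimination at VIF > {vif_threshold}")


def jackknife_contribution(presence: pd.DataFrame, background: pd.DataFrame,
                           config: FeatureConfig | None = None) -> pd.Series:
    """Per-variable contribution from single-variable model gains.

    Each variable is fitted alone; its contribution is its regularized
    training gain, normalized so contributions sum to 100.  A fit
    failure contributes 0 with a warning.
    """
    if config is None:
        config = FeatureConfig(classes=("linear", "quadratic"))
    gains = {}
    for v in presence.columns:
        try:
            res = MaxentModel(presence[[v]], background[[v]], config).fit()
            gains[v] = max(res.gain, 0.0)
        except (ConvergenceError, ValueError) as exc:
            logger.warning("jackknife fit failed for %s: %s", v, exc)
            gains[v] = 0.0
    s = pd.Series(gains)
    total = s.sum()
    if total <= 0:
        # no variable carries signal; spread contributions evenly
        return pd.Series(100.0 / len(s), index=s.index)
    return 100.0 * s / total


def build_set3(scores: pd.Series, data: pd.DataFrame,
               cumulative_pct: float = 90.0, r_threshold: float = 0.8,
               name: str = "Set3") -> VariableSet:
    """Top contributors past the cumulative cut, then Pearson-pruned.

    Variables are taken in decreasing contribution until their
    cumulative contribution exceeds ``cumulative_pct``; correlation
    pruning (contributions as tiebreak) is applied to that prefix.
    """
    ranked = scores.sort_values(ascending=False, kind="stable")
    cum = ranked.cumsum()
    n_keep = int(np.searchsorted(cum.to_numpy(), cumulative_pct, side="right")) + 1
    n_keep = min(n_keep, len(ranked))
    chosen = list(ranked.index[:n_keep])
    pruned = pearson_prune(data[chosen], r_threshold=r_threshold,
                           tiebreak_scores=scores, name=name)
    return VariableSet(name, pruned.variables,
                       provenance=(f"jackknife contributions > {cumulative_pct}% "
                                   f"cumulative, then Pearson pruning"))


def build_variable_sets(presence: pd.DataFrame, background: pd.DataFrame,
                        set1: tuple[str, ...] | None = None,
                        set2: tuple[str, ...] | None = None,
                        seed: int = 0) -> list[VariableSet]:
    """All four predictor sets for a calibration run.

    Sets 1 and 2 default to the full predictor list and its first half
    when no explicit lists are configured (for synthetic stacks whose
    names carry no literature meaning); Set 3 is jackknife+Pearson and
    Set 4 is VIF elimination, both computed from the background sample.
    """
    all_vars = tuple(background.columns)
    if set1 is None:
        set1 = all_vars
    if set2 is None:
        set2 = all_vars[: max(2, len(all_vars) // 2)]
    sets = [
        VariableSet("Set1", tuple(set1), provenance="configured full predictor list"),
        VariableSet("Set2", tuple(set2), provenance="configured literature list"),
    ]
    scores = jackknife_contribution(presence, background)
    sets.append(build_set3(scores, background))
    sets.append(vif_prune(background))
    return sets
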