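"""Candidate-model selection statistics.

Three statistics drive selection: the partial-ROC AUC-ratio bootstrap
test for statistical significance, the omission rate of the test
presences at the least-training-presence threshold, and AICc computed
from the normalized raw scores with parameters counted as nonzero
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MaxentResults


class DegenerateCurveError(ValueError):
    """All suitabilities identical; the ROC curve is undefined."""


@dataclass(frozen=True)
class PartialRocResult:
    mean_auc_ratio: float
    p_value: float
    E_percent: float
    n_bootstrap: int
    bootstrap_fraction: float
    seed: int


@dataclass(frozen=True)
class OmissionResult:
    rate: float
    E_percent: float
    threshold: float


@dataclass(frozen=True)
class AiccResult:
    aicc: float
    k: int
    log_likelihood: float
    m: int

    @property
    def valid(self) -> bool:
        return np.isfinite(self.aicc)


def _auc_ratio(sens: np.ndarray, area: np.ndarray, min_sens: float) -> float:
    """Trapezoidal AUC ratio of the curve restricted to sens >= min_sens.

    ``sens`` and ``area`` must be increasing along the threshold sweep;
    the null area is the trapezoid of the 1:1 line on the same nodes.
    """
    keep = sens >= min_sens
    x = np.concatenate([area[keep], [1.0]])
    y = np.concatenate([sens[keep], [1.0]])
    # interpolate the curve's crossing of the sens = min_sens line so the
    # restricted region starts exactly at the omission limit; without it
    # the discrete curve systematically over-covers the null line
    first = int(np.argmax(keep)) if keep.any() else -1
    if first > 0 and sens[first] > min_sens:
        s0, s1 = sens[first - 1], sens[first]
        a0, a1 = area[first - 1], area[first]
        frac = (min_sens - s0) / (s1 - s0)
        x = np.concatenate([[a0 + frac * (a1 - a0)], x])
        y = np.concatenate([[min_sens], y])
    if x.size < 2:
        x = np.array([1.0, 1.0])
        y = np.array([min_sens, 1.0])
    auc_model = np.trapezoid(y, x)
    auc_null = np.trapezoid(x, x)
    if auc_null <= 0:
        return 0.0
    return float(auc_model / auc_null)


def partial_roc(test_suitability: np.ndarray, background_suitability: np.ndarray,
                E_percent: float = 5.0, n_bootstrap: int = 500,
                bootstrap_fraction: float = 0.5, seed: int = 0) -> PartialRocResult:
    """Partial-ROC significance test (AUC-ratio bootstrap).

    Thresholds sweep the distinct background suitabilities; for each,
    sensitivity is the fraction of test presences at/above threshold
    and "area" the fraction of background at/above.  The curve is
    restricted to sensitivity >= 1 − E/100 and its trapezoidal area is
    divided by the 1:1 null line's area on the same region.  Bootstrap
    resamples of ceil(fraction·n_test) presences (with replacement)
    give the mean ratio and p = fraction of ratios <= 1.
    """
    test = np.asarray(test_suitability, dtype=float)
    bg = np.asarray(background_suitability, dtype=float)
    if test.size < 2 or bg.size < 2:
        raise ValueError("need test presences and background values")
    if np.ptp(bg) == 0 and np.ptp(test) == 0:
        raise DegenerateCurveError("all suitabilities are identical")
    min_sens = 1.0 - E_percent / 100.0

    bg_sorted = np.sort(bg)
    thresholds = np.unique(bg_sorted)[::-1]  # descending
    N = bg.size
    # fraction of background >= threshold, increasing along the sweep
    area = (N - np.searchsorted(bg_sorted, thresholds, side="left")) / N

    rng = np.random.default_rng(seed)
    n_test = test.size
    size = int(np.ceil(bootstrap_fraction * n_test))
    ratios = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        sample = np.sort(test[rng.integers(0, n_test, size)])
        sens = (size - np.searchsorted(sample, thresholds, side="left")) / size
        ratios[b] = _auc_ratio(sens, area, min_sens)
    mean_ratio = float(ratios.mean())
    p = float((ratios <= 1.0).sum() / n_bootstrap)
    return PartialRocResult(mean_ratio, p, E_percent, n_bootstrap,
                            bootstrap_fraction, seed)


def calibration_threshold(train_suitability: np.ndarray, E_percent: float = 5.0) -> float:
    """Least-training-presence threshold at error level E.

    The largest threshold t such that at least (100 − E)% of the
    calibration suitabilities are >= t; E = 0 gives the minimum
    training value.  Candidate thresholds are the observed values.
    """
    vals = np.sort(np.asarray(train_suitability, dtype=float))
    n = vals.size
    if n == 0:
        raise ValueError("no training suitabilities")
    if E_percent <= 0:
        return float(vals[0])
    need = 1.0 - E_percent / 100.0
    best = vals[0]
    for t in np.unique(vals):
        frac_at_or_above = (vals >= t).sum() / n
        if frac_at_or_above >= need:
            best = t
        else:
            break
    return float(best)


def omission_rate(test_suitability: np.ndarray, threshold: float,
                  E_percent: float = 5.0) -> OmissionResult:
    """Fraction of test presences strictly below the threshold."""
    vals = np.asarray(test_suitability, dtype=float)
    if vals.size == 0:
        raise ValueError("no test suitabilities")
    rate = float((vals < threshold).sum() / vals.size)
    return OmissionResult(rate, E_percent, float(threshold))


def aicc(results: MaxentResults) -> AiccResult:
    """AICc from normalized raw scores at the fitting presences.

    lnL = Σ_i log raw(x_i) with raw renormalized over the background;
    k counts nonzero coefficients.  When m − k − 1 <= 0 the criterion
    is undefined and the candidate is flagged invalid (aicc = inf).
    """
    model = results.model
    eta = results.params.to_numpy()
    zp = model._Xp @ eta
    # renormalize over the background cells explicitly
    from scipy.special import logsumexp
    logZ = logsumexp(model._Xb @ eta)
    lnL = float((zp - logZ).sum())
    k = results.k
    m = results.m
    if m - k - 1 <= 0:
        return AiccResult(np.inf, k, lnL, m)
    a = 2.0 * k - 2.0 * lnL + 2.0 * k * (k + 1) / (m - k - 1)
    return AiccResult(float(a), k, lnL, m)


def delta_aicc(results: list[AiccResult]) -> np.ndarray:
    """ΔAICc per candidate; invalid candidates excluded from the minimum."""
    vals = np.array([r.aicc for r in results], dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return np.full(len(results), np.nan)
    return vals - finite.min()
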