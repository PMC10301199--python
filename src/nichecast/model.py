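"""Maximum-entropy presence-background model (Maxent-style).

The model estimates a Gibbs distribution q(x) ∝ exp(η·f(x)) over the
background cells of the calibration region, chosen to maximize the
L1-penalized presence log-likelihood

    ℓ(η) = (1/m) Σ_i η·f(x_i) − log Σ_b exp(η·f(b)) + log N
           − Σ_j β_j |η_j|,       β_j = RM · s_j / √m,

where f are min-max-scaled features, m the presence count, N the
background count, s_j the presence-sample standard deviation of
feature j (floored at 1e-4) and RM the regularization multiplier.
ℓ(0) = 0, so the reported gain ℓ(η̂) is non-negative.

The problem is convex; it is solved deterministically by proximal
gradient descent (FISTA with soft-thresholding and adaptive restart),
followed by an L-BFGS-B polish on the positive/negative split form and
one exact proximal step so that inactive coefficients are hard zeros.

The API follows the model/results convention of statsmodels:
``MaxentModel(presence, background, config).fit()`` returns a
:class:`MaxentResults` carrying the sparse coefficients, normalizer,
entropy, gain and prediction/projection methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .features import FeatureConfig, FeatureMap
from .raster import GridRaster, RasterStack

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Fit did not reach the gradient tolerance within ``max_iter``."""

    def __init__(self, message: str, last_coefficients: np.ndarray,
                 gradient_norm: float):
        super().__init__(message)
        self.last_coefficients = last_coefficients
        self.gradient_norm = gradient_norm


@dataclass
class SuitabilityMap:
    """Logistic suitability on a grid, values in [0, 1]."""

    raster: GridRaster
    kind: str = "logistic"
    model_id: str = ""
    clamped: bool = True


class MaxentModel:
    """Presence-background maximum-entropy model.

    Parameters
    ----------
    presence, background : pandas.DataFrame
        Predictor values at presence records and at background cells
        (same columns).  Background rows should be the calibration
        region sample; features are scaled to its min/max.
    config : FeatureConfig
        Feature classes and regularization multiplier.
    """

    def __init__(self, presence: pd.DataFrame, background: pd.DataFrame,
                 config: FeatureConfig | None = None):
        if config is None:
            config = FeatureConfig()
        if list(presence.columns) != list(background.columns):
            background = background[list(presence.columns)]
        if len(presence) < 5:
            raise ValueError("need at least 5 presence records")
        self.presence = presence.reset_index(drop=True)
        self.background = background.reset_index(drop=True)
        self.config = config
        self.feature_map = FeatureMap.from_background(self.background, config.classes)
        self._Xp = self.feature_map.transform(self.presence, clamp=False)
        self._Xb = self.feature_map.transform(self.background, clamp=False)

    @classmethod
    def from_stack(cls, stack: RasterStack, occs, config: FeatureConfig | None = None,
                   m_mask: np.ndarray | None = None, max_background: int = 10_000,
                   seed: int = 0) -> "MaxentModel":
        """Build from a raster stack and an occurrence set.

        Background = all valid cells inside the (optional) region mask,
        down-sampled uniformly to ``max_background`` when larger.
        ``m_mask`` is True where cells are inside the region.
        """
        from .raster import extract_values
        exclude = None if m_mask is None else ~m_mask
        table = stack.to_table(mask=exclude)
        if len(table) > max_background:
            rng = np.random.default_rng(seed)
            idx = np.sort(rng.choice(len(table), size=max_background, replace=False))
            table = table.iloc[idx]
        pres = extract_values(stack, occs)
        return cls(pres, table, config)

    # ------------------------------------------------------------------
    # objective pieces (negated: we minimize)
    def _smooth_value_grad(self, eta: np.ndarray) -> tuple[float, np.ndarray]:
        """g(η) = −p̄·η + logsumexp(Xb η) − log N and its gradient."""
        pbar = self._Xp.mean(axis=0)
        z = self._Xb @ eta
        lse = logsumexp(z)
        w = np.exp(z - lse)
        g = float(-pbar @ eta + lse - np.log(self._Xb.shape[0]))
        grad = -pbar + self._Xb.T @ w
        return g, grad

    def _betas(self) -> np.ndarray:
        m = self._Xp.shape[0]
        s = self._Xp.std(axis=0, ddof=1) if m > 1 else np.zeros(self._Xp.shape[1])
        s = np.maximum(s, 1e-4)
        return self.config.regularization_multiplier * s / np.sqrt(m)

    def penalized_loglik(self, eta: np.ndarray) -> float:
        """ℓ(η): the penalized gain objective (maximized by fit)."""
        g, _ = self._smooth_value_grad(eta)
        return float(-g - self._betas() @ np.abs(eta))

    # ------------------------------------------------------------------
    def fit(self, tol: float = 1e-7, max_iter: int = 5000) -> "MaxentResults":
        """Solve the convex penalized problem to gradient tolerance ``tol``.

        Raises :class:`ConvergenceError` (carrying the last iterate and
        its generalized-gradient norm) if the tolerance is not reached.
        """
        beta = self._betas()
        J = self._Xb.shape[1]
        eta = np.zeros(J)

        # stage 1: FISTA with backtracking + restart
        L = 1.0
        y = eta.copy()
        t = 1.0
        g_y, grad_y = self._smooth_value_grad(y)
        f_prev = np.inf
        n_fista = min(max_iter, 500)
        for _ in range(n_fista):
            while True:
                cand = _soft_threshold(y - grad_y / L, beta / L)
                step = cand - y
                g_cand, _ = self._smooth_value_grad(cand)
                if g_cand <= g_y + grad_y @ step + 0.5 * L * step @ step + 1e-12:
                    break
                L *= 2.0
            eta_new = cand
            f_new = g_cand + beta @ np.abs(eta_new)
            if f_new > f_prev:  # adaptive restart
                t = 1.0
                y = eta.copy()
                g_y, grad_y = self._smooth_value_grad(y)
                continue
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            y = eta_new + ((t - 1.0) / t_new) * (eta_new - eta)
            eta, t, f_prev = eta_new, t_new, f_new
            g_y, grad_y = self._smooth_value_grad(y)
            if _prox_residual(self, eta, beta, L) < tol:
                return self._results_from(eta)

        # stage 2: polish on the split form (η = η⁺ − η⁻, both ≥ 0);
        # the penalty is linear there and L-BFGS-B is deterministic
        def split_obj(z: np.ndarray):
            p, q = z[:J], z[J:]
            e = p - q
            g, grad = self._smooth_value_grad(e)
            val = g + beta @ (p + q)
            return val, np.concatenate([grad + beta, -grad + beta])

        z0 = np.concatenate([np.maximum(eta, 0), np.maximum(-eta, 0)])
        res = minimize(split_obj, z0, jac=True, method="L-BFGS-B",
                       bounds=[(0, None)] * (2 * J),
                       options={"maxiter": max_iter, "ftol": 1e-15,
                                "gtol": min(tol, 1e-9)})
        eta = res.x[:J] - res.x[J:]

        # stage 3: one exact proximal step for hard zeros
        _, grad = self._smooth_value_grad(eta)
        eta = _soft_threshold(eta - grad / L, beta / L)
        resid = _prox_residual(self, eta, beta, L)
        if resid >= max(tol, 1e-6):
            raise ConvergenceError(
                f"fit did not converge: residual {resid:.3g} after {max_iter} iterations",
                eta, resid)
        return self._results_from(eta)

    def _results_from(self, eta: np.ndarray) -> "MaxentResults":
        eta = np.where(np.abs(eta) < 1e-12, 0.0, eta)
        z = self._Xb @ eta
        logZ = float(logsumexp(z))
        logq = z - logZ
        H = float(-(np.exp(logq) * logq).sum())
        gain = self.penalized_loglik(eta)
        return MaxentResults(self, eta, logZ, H, gain)


def _soft_threshold(x: np.ndarray, thr: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def _prox_residual(model: MaxentModel, eta: np.ndarray, beta: np.ndarray,
                   L: float) -> float:
    _, grad = model._smooth_value_grad(eta)
    mapped = _soft_threshold(eta - grad / L, beta / L)
    return float(np.max(np.abs(L * (eta - mapped))))


class MaxentResults:
    """Fitted maximum-entropy model.

    Attributes
    ----------
    params : pandas.Series
        Sparse coefficient vector η̂ indexed by feature name.
    logZ : float
        log normalizer over the fitting background.
    entropy : float
        Shannon entropy (nats) of the fitted raw distribution.
    gain : float
        Penalized regularized training gain ℓ(η̂) − ℓ(0) (ℓ(0) = 0).
    """

    def __init__(self, model: MaxentModel, eta: np.ndarray, logZ: float,
                 entropy: float, gain: float):
        self.model = model
        self._eta = eta
        self.params = pd.Series(eta, index=model.feature_map.feature_names)
        self.logZ = logZ
        self.entropy = entropy
        self.gain = gain
        self.prevalence = 0.5

    @property
    def k(self) -> int:
        """Parameter count: coefficients with nonzero weight."""
        return int(np.count_nonzero(self._eta))

    @property
    def m(self) -> int:
        return self.model._Xp.shape[0]

    @property
    def n_background(self) -> int:
        return self.model._Xb.shape[0]

    # ------------------------------------------------------------------
    def raw_from_features(self, X: np.ndarray) -> np.ndarray:
        """raw(x) = exp(η·f(x) − logZ); sums to 1 over the fit background."""
        return np.exp(X @ self._eta - self.logZ)

    def logistic_from_features(self, X: np.ndarray) -> np.ndarray:
        """Logistic output: τ e^H raw / (1 + τ e^H raw) with τ = prevalence."""
        t = self.prevalence * np.exp(self.entropy + X @ self._eta - self.logZ)
        return t / (1.0 + t)

    def predict(self, values: pd.DataFrame, kind: str = "logistic",
                clamp: bool = True) -> np.ndarray:
        """Predict raw or logistic output at arbitrary predictor values."""
        X = self.model.feature_map.transform(values, clamp=clamp)
        if kind == "raw":
            return self.raw_from_features(X)
        if kind == "logistic":
            return self.logistic_from_features(X)
        raise ValueError(f"unknown output kind {kind!r}")

    def project(self, scenario: RasterStack, clamp: bool = True,
                m_mask: np.ndarray | None = None) -> SuitabilityMap:
        """Logistic suitability over a scenario stack.

        Features are rebuilt from the scenario values with the STORED
        background scaling; with ``clamp`` on, scaled features are
        truncated to [0, 1] so no feature is extrapolated.
        """
        missing = [v for v in self.model.feature_map.variables if v not in scenario]
        if missing:
            raise KeyError(f"scenario stack is missing model variable(s): {missing}")
        bad = scenario.combined_mask.copy()
        if m_mask is not None:
            bad |= ~m_mask
        table = scenario.to_table(mask=None if m_mask is None else ~m_mask)
        vals = self.predict(table[self.model.feature_map.variables],
                            kind="logistic", clamp=clamp)
        grid = np.zeros(scenario.shape)
        grid.ravel()[table.index.to_numpy()] = vals
        raster = GridRaster(grid, bad, scenario.transform, scenario.crs)
        return SuitabilityMap(raster, kind="logistic",
                              model_id=self.model.config.label, clamped=clamp)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "Maximum-entropy presence-background model",
            "=" * 45,
            f"presences:            {self.m}",
            f"background cells:     {self.n_background}",
            f"feature classes:      {'/'.join(self.model.config.classes)}",
            f"regularization mult.: {self.model.config.regularization_multiplier:g}",
            f"features built:       {len(self.params)}",
            f"nonzero coefficients: {self.k}",
            f"regularized gain:     {self.gain:.4f}",
            f"entropy (nats):       {self.entropy:.4f}",
            f"log normalizer:       {self.logZ:.4f}",
            "-" * 45,
            "nonzero coefficients:",
        ]
        nz = self.params[self.params != 0]
        if nz.empty:
            lines.append("  (none)")
        else:
            for name, val in nz.items():
                lines.append(f"  {name:<24s} {val:+.5f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable model description."""
        fm = self.model.feature_map
        return {
            "feature_names": fm.feature_names,
            "variables": fm.variables,
            "classes": list(self.model.config.classes),
            "regularization_multiplier": self.model.config.regularization_multiplier,
            "scale_min": fm.scale_min.tolist(),
            "scale_max": fm.scale_max.tolist(),
            "coefficients": self._eta.tolist(),
            "logZ": self.logZ,
            "entropy": self.entropy,
            "gain": self.gain,
            "m": self.m,
            "n_background": self.n_background,
        }
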