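"""Feature construction for the maximum-entropy model.

Three feature classes over the raw predictors: linear (the values),
quadratic (their squares) and product (all pairwise products of
distinct predictors).  Every feature is min-max scaled to [0, 1] using
the background sample; constant features are dropped.  Projection onto
new conditions reuses the stored scaling, optionally clamping scaled
values into [0, 1] so the model is never evaluated outside the
calibration range of any feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("linear", "quadratic", "product")
CLASS_ABBREV = {"l": "linear", "q": "quadratic", "p": "product"}
#: canonical enumeration order of the seven class combinations
CLASS_COMBINATIONS = ("l", "q", "p", "lq", "lp", "qp", "lqp")


def parse_classes(spec: str | tuple[str, ...]) -> tuple[str, ...]:
    """'lqp' or ('linear', ...) -> canonical tuple of full class names."""
    if isinstance(spec, str):
        names = [CLASS_ABBREV[ch] for ch in spec]
    else:
        names = [CLASS_ABBREV.get(s, s) for s in spec]
    bad = [n for n in names if n not in FEATURE_CLASSES]
    if bad:
        raise ValueError(f"unknown feature classes: {bad}")
    if not names:
        raise ValueError("feature classes must be non-empty")
    return tuple(n for n in FEATURE_CLASSES if n in names)


def abbreviate_classes(classes: tuple[str, ...]) -> str:
    return "".join(c[0] for c in classes)


@dataclass(frozen=True)
class FeatureConfig:
    """One candidate-model configuration: classes plus L1 multiplier."""

    classes: tuple[str, ...] = ("linear", "quadratic", "product")
    regularization_multiplier: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", parse_classes(self.classes))
        if self.regularization_multiplier < 0:
            raise ValueError("regularization multiplier must be >= 0")

    @property
    def label(self) -> str:
        return f"RM{self.regularization_multiplier:g}_{abbreviate_classes(self.classes)}"


def _raw_features(df: pd.DataFrame, classes: tuple[str, ...]) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    variables = list(df.columns)
    if "linear" in classes:
        for v in variables:
            cols[v] = df[v].to_numpy(dtype=float)
    if "quadratic" in classes:
        for v in variables:
            cols[f"{v}^2"] = df[v].to_numpy(dtype=float) ** 2
    if "product" in classes:
        if len(variables) < 2 and classes == ("product",):
            logger.warning("product features need >= 2 variables; none built")
        for a, b in combinations(variables, 2):
            cols[f"{a}*{b}"] = df[a].to_numpy(dtype=float) * df[b].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


@dataclass
class FeatureMap:
    """Feature recipe plus background min-max scaling."""

    variables: list[str]
    classes: tuple[str, ...]
    feature_names: list[str] = field(default_factory=list)
    scale_min: np.ndarray | None = None
    scale_max: np.ndarray | None = None

    @classmethod
    def from_background(cls, background: pd.DataFrame,
                        classes: tuple[str, ...] | str) -> "FeatureMap":
        classes = parse_classes(classes)
        fm = cls(variables=list(background.columns), classes=classes)
        raw = _raw_features(background, classes)
        if raw.shape[1] == 0:
            raise ValueError("no features could be built from the given classes")
        lo = raw.min(axis=0).to_numpy()
        hi = raw.max(axis=0).to_numpy()
        keep = hi > lo
        n_const = int((~keep).sum())
        if n_const:
            logger.warning("dropping %d constant feature(s)", n_const)
        if not keep.any():
            raise ValueError("all candidate features are constant on the background")
        fm.feature_names = [n for n, k in zip(raw.columns, keep) if k]
        fm.scale_min = lo[keep]
        fm.scale_max = hi[keep]
        return fm

    def transform(self, df: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        """Scaled feature matrix for predictor values ``df``."""
        missing = [v for v in self.variables if v not in df.columns]
        if missing:
            raise KeyError(f"predictor table is missing variables: {missing}")
        raw = _raw_features(df[self.variables], self.classes)
        X = raw[self.feature_names].to_numpy(dtype=float)
        X = (X - self.scale_min) / (self.scale_max - self.scale_min)
        if clamp:
            X = np.clip(X, 0.0, 1.0)
        return X

    def __len__(self) -> int:
        return len(self.feature_names)


def build_features(values: pd.DataFrame,
                   classes: tuple[str, ...] | str) -> tuple[FeatureMap, np.ndarray]:
    """Feature map fitted on ``values`` plus its scaled feature table."""
    fm = FeatureMap.from_background(values, classes)
    return fm, fm.transform(values)
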