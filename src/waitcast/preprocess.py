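"""Leakage-safe preprocessing of the feature table.

Fixed pipeline order: physician-stratified 80/20 split -> square-root
transform of the waiting-time target -> interquartile outlier removal
on the *transformed* target (bounds fitted on train, applied unchanged
to test) -> min-max normalization of the continuous features (bounds
fitted on train; binary flags pass through; test values outside the
training range are not clipped).  Every fitted threshold lives in a
serializable :class:`PreprocessState`, sufficient to transform unseen
data identically — and to de-normalize feature values when narrating a
prediction back to a patient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import BINARY_FEATURES, CONTINUOUS_FEATURES

__all__ = [
    "PreprocessState",
    "split_train_test",
    "transform_target",
    "inverse_transform",
    "fit_outlier_bounds",
    "apply_outlier_filter",
    "fit_minmax",
    "apply_minmax",
    "inverse_minmax",
    "preprocess_pipeline",
]

TARGET = "waiting_minutes"
TARGET_TRANSFORMED = "sqrt_waiting"


@dataclass
class PreprocessState:
    """Fitted thresholds of the preprocessing pipeline."""

    feature_min: dict[str, float] = field(default_factory=dict)
    feature_max: dict[str, float] = field(default_factory=dict)
    outlier_lower: float = float("-inf")
    outlier_upper: float = float("inf")
    target_transform: str = "sqrt"
    split_seed: int | None = None
    split_ratio: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_min": self.feature_min,
                "feature_max": self.feature_max,
                "outlier_lower": self.outlier_lower,
                "outlier_upper": self.outlier_upper,
                "target_transform": self.target_transform,
                "split_seed": self.split_seed,
                "split_ratio": self.split_ratio,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PreprocessState":
        d = json.loads(text)
        return cls(
            feature_min={k: float(v) for k, v in d["feature_min"].items()},
            feature_max={k: float(v) for k, v in d["feature_max"].items()},
            outlier_lower=float(d["outlier_lower"]),
            outlier_upper=float(d["outlier_upper"]),
            target_transform=d.get("target_transform", "sqrt"),
            split_seed=d.get("split_seed"),
            split_ratio=d.get("split_ratio"),
        )


def split_train_test(
    table: pd.DataFrame, ratio: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-physician random split.

    Each physician contributes round(ratio * n) rows to train, so the
    per-physician train share matches the global ratio to within one
    instance.  A physician with fewer than 2 rows goes wholly to train
    with a warning.  Deterministic in ``seed``.
    """
    if not 0.0 < ratio <= 1.0:
        raise ValueError("ratio must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    train_idx: list = []
    test_idx: list = []
    for physician in sorted(table["physician_id"].unique()):
        idx = table.index[table["physician_id"] == physician].to_numpy()
        if len(idx) < 2:
            warnings.warn(
                f"physician {physician!r} has {len(idx)} instance(s); assigning all to train"
            )
            train_idx.extend(idx)
            continue
        perm = rng.permutation(len(idx))
        n_train = int(round(ratio * len(idx)))
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return table.loc[sorted(train_idx)].copy(), table.loc[sorted(test_idx)].copy()


def transform_target(w):
    """Square-root transform of waiting minutes (right-skew reduction)."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("waiting time must be non-negative")
    return np.sqrt(w)


def inverse_transform(v):
    """Back to minutes: the square of the transformed value."""
    return np.square(np.asarray(v, dtype=float))


def fit_outlier_bounds(transformed_targets) -> tuple[float, float]:
    """Tukey fences Q1 - 1.5*IQR, Q3 + 1.5*IQR (linear-interp quartiles)."""
    x = np.asarray(transformed_targets, dtype=float)
    if x.size == 0:
        raise ValueError("cannot fit outlier bounds on an empty training set")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


def apply_outlier_filter(
    table: pd.DataFrame, bounds: tuple[float, float], column: str = TARGET_TRANSFORMED
) -> tuple[pd.DataFrame, int]:
    """Drop rows strictly outside the fences; boundary values are kept."""
    if table.empty:
        return table.copy(), 0
    lower, upper = bounds
    keep = (table[column] >= lower) & (table[column] <= upper)
    return table.loc[keep].copy(), int((~keep).sum())


def fit_minmax(train: pd.DataFrame, columns=None) -> PreprocessState:
    """Record per-feature training min/max for the continuous features."""
    if columns is None:
        columns = [c for c in CONTINUOUS_FEATURES if c in train.columns]
    state = PreprocessState()
    for col in columns:
        state.feature_min[col] = float(train[col].min())
        state.feature_max[col] = float(train[col].max())
    return state


def apply_minmax(table: pd.DataFrame, state: PreprocessState) -> pd.DataFrame:
    """Affine map x -> (x - min) / (max - min); no clipping of test values.

    Binary features ({0,1} flags) pass through untouched.  A feature
    whose training range is degenerate (max == min) maps to 0 with a
    warning.
    """
    out = table.copy()
    for col, lo in state.feature_min.items():
        hi = state.feature_max[col]
        if hi == lo:
            warnings.warn(f"feature {col!r} is constant in training; mapping to 0")
            out[col] = 0.0
        else:
            out[col] = (out[col].astype(float) - lo) / (hi - lo)
    return out


def inverse_minmax(value, feature: str, state: PreprocessState) -> float:
    """De-normalize a scaled value back to its original units."""
    if feature not in state.feature_min:
        if feature in BINARY_FEATURES:
            return float(value)
        raise KeyError(f"no min-max bounds recorded for feature {feature!r}")
    lo = state.feature_min[feature]
    hi = state.feature_max[feature]
    return float(lo + float(value) * (hi - lo))


def preprocess_pipeline(
    features: pd.DataFrame, ratio: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, PreprocessState, dict[str, int]]:
    """Run the full fixed-order pipeline; thresholds fitted on train only.

    Returns (train, test, state, drop_counts).  Both output frames carry
    the normalized features plus ``sqrt_waiting`` (the modelling target)
    alongside the original ``waiting_minutes``.
    """
    train, test = split_train_test(features, ratio=ratio, seed=seed)
    train = train.assign(**{TARGET_TRANSFORMED: transform_target(train[TARGET])})
    test = test.assign(**{TARGET_TRANSFORMED: transform_target(test[TARGET])}) if len(test) else test.assign(**{TARGET_TRANSFORMED: []})
    bounds = fit_outlier_bounds(train[TARGET_TRANSFORMED])
    train, dropped_train = apply_outlier_filter(train, bounds)
    test, dropped_test = apply_outlier_filter(test, bounds)
    state = fit_minmax(train)
    state.outlier_lower, state.outlier_upper = bounds
    state.split_seed = seed
    state.split_ratio = ratio
    train = apply_minmax(train, state)
    test = apply_minmax(test, state)
    drops = {"train": dropped_train, "test": dropped_test}
    return train, test, state, drops
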