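"""Additive (Shapley) attributions and patient-facing narratives.

A prediction ``f(x)`` is decomposed as ``phi0 + sum_i phi_i`` where
``phi_i`` is feature *i*'s Shapley value under the interventional value
function: ``f_x(S)`` is the mean model output over a background sample
with the features in coalition ``S`` replaced by ``x``'s values.  Two
routes compute the same quantity:

* :func:`exact_shapley` — brute-force enumeration of all ``2^M``
  coalitions (the defining sum; tractable for the nine-feature setting);
* :func:`fast_explain` — a closed-form per-leaf pass over a gradient
  -boosted tree ensemble, linear in leaves x background, used for bulk
  explanation and gated against the exact path in tests.

Per-feature attributions live in the model's (square-root) output
space; only the total prediction is converted to minutes when a
narrative is rendered, since a nonlinear inverse transform does not
distribute over the additive terms.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS
from .preprocess import PreprocessState, inverse_minmax, inverse_transform

__all__ = [
    "BackgroundSet",
    "AdditiveExplanation",
    "GlobalImportanceReport",
    "DependenceData",
    "NarrativeExplanation",
    "exact_shapley",
    "fast_explain",
    "global_importance",
    "dependence",
    "narrative",
]

MAX_EXACT_FEATURES = 15
DEFAULT_BACKGROUND_CAP = 500


@dataclass
class BackgroundSet:
    """Reference rows defining the value function's 'feature absent' state."""

    rows: np.ndarray  # (B, M)
    feature_names: Sequence[str]

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        feature_names: Sequence[str] | None = None,
        cap: int = DEFAULT_BACKGROUND_CAP,
        seed: int = 0,
    ) -> "BackgroundSet":
        names = list(feature_names or [c for c in FEATURE_COLUMNS if c in frame.columns])
        rows = frame[names].to_numpy(dtype=float)
        if len(rows) > cap:
            rng = np.random.default_rng(seed)
            rows = rows[rng.choice(len(rows), size=cap, replace=False)]
        if len(rows) == 0:
            raise ValueError("background set must be non-empty")
        return cls(rows=rows, feature_names=names)


@dataclass
class AdditiveExplanation:
    phi0: float
    phi: dict[str, float]
    feature_values: dict[str, float]
    prediction: float
    z: np.ndarray = field(default=None)  # presence indicators, all-ones here

    def __post_init__(self) -> None:
        if self.z is None:
            self.z = np.ones(len(self.phi), dtype=int)

    @property
    def m(self) -> int:
        return len(self.phi)

    @property
    def g(self) -> float:
        """Additive reconstruction phi0 + sum_i phi_i z_i."""
        return self.phi0 + float(np.dot(list(self.phi.values()), self.z))


@dataclass
class GlobalImportanceReport:
    table: pd.DataFrame  # columns: feature, gi; ranked descending
    n: int

    @property
    def ranking(self) -> list[str]:
        return list(self.table["feature"])


@dataclass
class DependenceData:
    feature: str
    interaction: str
    table: pd.DataFrame  # columns: feature_value, phi, interaction_value


def _as_background(background, feature_names) -> BackgroundSet:
    if isinstance(background, BackgroundSet):
        return background
    if isinstance(background, pd.DataFrame):
        return BackgroundSet.from_frame(background, feature_names)
    rows = np.asarray(background, dtype=float)
    if rows.ndim == 1:
        rows = rows[None, :]
    names = list(feature_names or [f"x{i}" for i in range(rows.shape[1])])
    return BackgroundSet(rows=rows, feature_names=names)


def exact_shapley(
    predict: Callable[[np.ndarray], np.ndarray],
    x,
    background,
    feature_names: Sequence[str] | None = None,
) -> AdditiveExplanation:
    """Exact Shapley attribution by full coalition enumeration.

    phi_i = sum over S excluding i of |S|!(M-|S|-1)!/M! times
    (f_x(S + i) - f_x(S)), with f_x(S) the background-substitution
    expectation.  All 2^M coalition evaluations are batched into a
    single predict call.  Limited to M <= 15 features.
    """
    if isinstance(x, pd.Series):
        feature_names = feature_names or list(x.index)
        x = x.to_numpy(dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    bg = _as_background(background, feature_names)
    names = list(bg.feature_names)
    m = x.size
    if m != len(names):
        raise ValueError("x and background disagree on the number of features")
    if m > MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration supports at most {MAX_EXACT_FEATURES} features "
            f"(got {m}); use fast_explain for tree ensembles"
        )
    B = len(bg.rows)
    n_masks = 1 << m
    tiled = np.tile(bg.rows, (n_masks, 1))
    for i in range(m):
        member = (np.arange(n_masks) >> i) & 1  # coalition contains feature i
        rows_mask = np.repeat(member.astype(bool), B)
        tiled[rows_mask, i] = x[i]
    v = np.asarray(predict(tiled), dtype=float).reshape(n_masks, B).mean(axis=1)

    weights = np.array(
        [math.factorial(s) * math.factorial(m - s - 1) / math.factorial(m) for s in range(m)]
    )
    popcount = np.array([bin(mask).count("1") for mask in range(n_masks)])
    phi = np.zeros(m)
    for i in range(m):
        without = np.nonzero(((np.arange(n_masks) >> i) & 1) == 0)[0]
        phi[i] = np.sum(weights[popcount[without]] * (v[without | (1 << i)] - v[without]))
    return AdditiveExplanation(
        phi0=float(v[0]),
        phi={name: float(p) for name, p in zip(names, phi)},
        feature_values={name: float(val) for name, val in zip(names, x)},
        prediction=float(v[-1]),
    )


# --------------------------------------------------------------------------
# closed-form interventional Shapley over tree ensembles

@dataclass
class _Leaf:
    value: float
    features: np.ndarray  # (k,) feature indices appearing on the path
    lower: np.ndarray  # (k,) exclusive lower bounds
    upper: np.ndarray  # (k,) inclusive upper bounds


def _extract_leaves(booster) -> list[_Leaf]:
    """Flatten a LightGBM model dump into per-leaf feature boxes.

    A numeric split sends ``value <= threshold`` left; a leaf is reached
    by ``x`` iff ``lower < x_f <= upper`` for every feature on its path.
    """
    dump = booster.dump_model()
    leaves: list[_Leaf] = []

    def walk(node, box: dict[int, tuple[float, float]]):
        if "leaf_value" in node and "split_feature" not in node:
            feats = np.array(sorted(box), dtype=int)
            leaves.append(
                _Leaf(
                    value=float(node["leaf_value"]),
                    features=feats,
                    lower=np.array([box[f][0] for f in feats]),
                    upper=np.array([box[f][1] for f in feats]),
                )
            )
            return
        f = int(node["split_feature"])
        thr = float(node["threshold"])
        if node.get("decision_type", "<=") != "<=":
            raise ValueError("only numeric '<=' splits are supported")
        lo, hi = box.get(f, (-np.inf, np.inf))
        left_box = dict(box)
        left_box[f] = (lo, min(hi, thr))
        walk(node["left_child"], left_box)
        right_box = dict(box)
        right_box[f] = (max(lo, thr), hi)
        walk(node["right_child"], right_box)

    for tree in dump["tree_info"]:
        walk(tree["tree_structure"], {})
    return leaves


def _shapley_coef_tables(max_pn: int) -> tuple[np.ndarray, np.ndarray]:
    """c_P[p, n] = (p-1)! n! / (p+n)!  and  c_N[p, n] = p! (n-1)! / (p+n)!."""
    size = max_pn + 1
    fact = np.array([math.factorial(i) for i in range(2 * size)], dtype=float)
    c_p = np.zeros((size, size))
    c_n = np.zeros((size, size))
    for p in range(size):
        for n in range(size):
            if p >= 1:
                c_p[p, n] = fact[p - 1] * fact[n] / fact[p + n]
            if n >= 1:
                c_n[p, n] = fact[p] * fact[n - 1] / fact[p + n]
    return c_p, c_n


def fast_explain(
    model,
    rows,
    background,
    feature_names: Sequence[str] | None = None,
) -> list[AdditiveExplanation]:
    """Exact interventional Shapley values through the tree structure.

    For a single background row ``z``, the coalition game of a decision
    tree is a sum over leaves of unanimity-style terms: a leaf fires
    iff every path feature where only ``x`` satisfies the path box is
    present (set P) and every feature where only ``z`` satisfies it is
    absent (set N).  Such a term's Shapley values have the closed form
    value * (p-1)! n! / (p+n)! for members of P and the negated mirror
    for N, so the whole attribution is a linear pass over leaves and
    background rows — no 2^M enumeration.  Averaging over the
    background reproduces :func:`exact_shapley` exactly (gated in
    tests), and the additive identity phi0 + sum phi = f(x) holds row
    by row.

    Falls back to the exact enumeration path (with a warning) for
    models that do not expose a LightGBM booster.
    """
    if isinstance(rows, pd.DataFrame):
        feature_names = feature_names or list(rows.columns)
        rows = rows.to_numpy(dtype=float)
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    bg = _as_background(background, feature_names)
    names = list(bg.feature_names)

    booster = getattr(model, "booster_", model)
    leaves = None
    if hasattr(booster, "dump_model"):
        try:
            leaves = _extract_leaves(booster)
        except ValueError as exc:
            warnings.warn(f"unsupported tree structure ({exc}); falling back to exact enumeration")
    else:
        warnings.warn("model exposes no tree structure; falling back to exact enumeration")
    if leaves is None:
        return [
            exact_shapley(model.predict, row, bg, feature_names=names) for row in rows
        ]
    max_pn = max((len(leaf.features) for leaf in leaves), default=0)
    c_p, c_n = _shapley_coef_tables(max_pn)
    Z = bg.rows
    B = len(Z)

    # leaf membership of the background rows, computed once
    pass_z = [
        (Z[:, leaf.features] > leaf.lower) & (Z[:, leaf.features] <= leaf.upper)
        for leaf in leaves
    ]
    # constant offset (init score) not stored in the leaves: compare the
    # booster's raw score on one background row with its leaf-value sum
    probe = Z[0]
    leaf_sum = 0.0
    for leaf, pz in zip(leaves, pass_z):
        if leaf.features.size == 0 or pz[0].all():
            leaf_sum += leaf.value
    raw_probe = float(np.asarray(booster.predict(probe[None, :], raw_score=True)).ravel()[0])
    offset = raw_probe - leaf_sum

    out: list[AdditiveExplanation] = []
    for r, x in enumerate(rows):
        phi_b = np.zeros((B, len(names)))
        phi0_b = np.zeros(B)
        fx = 0.0
        for leaf, pz in zip(leaves, pass_z):
            feats = leaf.features
            if feats.size == 0:  # stump: constant contribution
                phi0_b += leaf.value
                fx += leaf.value
                continue
            px = (x[feats] > leaf.lower) & (x[feats] <= leaf.upper)
            if px.all():
                fx += leaf.value
            valid = np.all(px[None, :] | pz, axis=1)
            if not valid.any():
                continue
            only_x = px[None, :] & ~pz
            only_z = ~px[None, :] & pz
            p = only_x.sum(axis=1)
            n = only_z.sum(axis=1)
            w_p = np.where(valid & (p > 0), leaf.value * c_p[p, n], 0.0)
            w_n = np.where(valid & (n > 0), -leaf.value * c_n[p, n], 0.0)
            phi0_b[valid & (p == 0)] += leaf.value
            for j, f in enumerate(feats):
                phi_b[:, f] += np.where(only_x[:, j], w_p, 0.0)
                phi_b[:, f] += np.where(only_z[:, j], w_n, 0.0)
        phi = phi_b.mean(axis=0)
        out.append(
            AdditiveExplanation(
                phi0=float(phi0_b.mean() + offset),
                phi={name: float(p) for name, p in zip(names, phi)},
                feature_values={name: float(v) for name, v in zip(names, x)},
                prediction=float(fx + offset),
            )
        )
    return out


def global_importance(explanations: Sequence[AdditiveExplanation]) -> GlobalImportanceReport:
    """Mean absolute attribution per feature, ranked descending.

    GI_i = (1/N) sum_j |phi_i^(j)|; ties rank alphabetically.
    """
    if not explanations:
        raise ValueError("need at least one explanation")
    names = list(explanations[0].phi)
    mat = np.abs(np.array([[e.phi[n] for n in names] for e in explanations]))
    gi = mat.mean(axis=0)
    table = (
        pd.DataFrame({"feature": names, "gi": gi})
        .sort_values(["gi", "feature"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return GlobalImportanceReport(table=table, n=len(explanations))


def dependence(
    explanations: Sequence[AdditiveExplanation],
    feature: str,
    interaction: str = "auto",
    n_bins: int = 8,
) -> DependenceData:
    """Per-instance (feature value, phi, interaction value) triples.

    ``interaction="auto"`` scans the other features and picks the one
    whose values explain the most variance of ``phi_feature`` within
    bins of the feature value (a linear within-bin fit; the candidate
    with the largest total explained sum of squares wins, first feature
    in column order on ties).
    """
    if not explanations:
        raise ValueError("need at least one explanation")
    names = list(explanations[0].phi)
    if feature not in names:
        raise KeyError(f"unknown feature {feature!r}")
    xf = np.array([e.feature_values[feature] for e in explanations])
    phi = np.array([e.phi[feature] for e in explanations])

    if interaction == "auto":
        edges = np.unique(np.quantile(xf, np.linspace(0, 1, n_bins + 1)))
        bins = np.clip(np.searchsorted(edges, xf, side="right") - 1, 0, len(edges) - 2)
        best_name, best_score = None, -1.0
        for cand in names:
            if cand == feature:
                continue
            xc = np.array([e.feature_values[cand] for e in explanations])
            score = 0.0
            for b in np.unique(bins):
                sel = bins == b
                if sel.sum() < 3:
                    continue
                xb, pb = xc[sel], phi[sel]
                if np.ptp(xb) == 0 or np.ptp(pb) == 0:
                    continue
                r = np.corrcoef(xb, pb)[0, 1]
                if np.isfinite(r):
                    score += r * r * float(np.var(pb)) * sel.sum()
            if score > best_score:
                best_name, best_score = cand, score
        interaction = best_name if best_name is not None else next(
            n for n in names if n != feature
        )
    elif interaction not in names:
        raise KeyError(f"unknown interaction feature {interaction!r}")

    xi = np.array([e.feature_values[interaction] for e in explanations])
    return DependenceData(
        feature=feature,
        interaction=interaction,
        table=pd.DataFrame(
            {"feature_value": xf, "phi": phi, "interaction_value": xi}
        ),
    )


# --------------------------------------------------------------------------
# patient-facing narratives

#: Count-valued features are de-normalized to whole patients; durations
#: to minutes at 2 dp; shares stay as 3-dp proportions.
_COUNT_FEATURES = {"Q_L", "P_NP"}
_MINUTE_FEATURES = {"P_ACT"}
_FLAG_PHRASES = {
    "A_S": {1: "an appointment was made", 0: "no appointment was made"},
    "T_S": {
        1: "registration fell in a smooth-flow time zone",
        0: "registration fell in a busy time zone",
    },
}
_VALUE_PHRASES = {
    "Q_L": "{v} patients in the physician's queue",
    "Q_R": "a returning-patient share of {v} in the queue",
    "Q_N": "a newly-visiting-patient share of {v} in the queue",
    "Q_F": "a first-time-patient share of {v} in the queue",
    "Q_D": "a department-first-time share of {v} in the queue",
    "P_ACT": "an average recent consultation of {v} min",
    "P_NP": "{v} patients consulted recently by the physician",
}


@dataclass
class NarrativeExplanation:
    expected_minutes: float
    increasing: list[tuple[str, str]]  # (feature, rendered value)
    decreasing: list[tuple[str, str]]
    denormalized: dict[str, float]
    text: str


def _render(feature: str, denorm: float, raw_value: float) -> tuple[str, str]:
    if feature in _FLAG_PHRASES:
        flag = int(round(raw_value))
        return str(flag), _FLAG_PHRASES[feature][flag]
    if feature in _COUNT_FEATURES:
        rendered = str(int(round(denorm)))
    elif feature in _MINUTE_FEATURES:
        rendered = f"{denorm:.2f}"
    else:
        rendered = f"{denorm:.3f}"
    phrase = _VALUE_PHRASES.get(feature, feature + " of {v}").format(v=rendered)
    if feature in _COUNT_FEATURES and rendered == "1":
        phrase = phrase.replace("patients", "patient")
    return rendered, phrase


def narrative(
    explanation: AdditiveExplanation,
    state: PreprocessState,
    top_k: int = 3,
) -> NarrativeExplanation:
    """Template a patient-facing account of one prediction.

    The total prediction is inverse-transformed to minutes; the top-k
    features by |phi| are cited with their de-normalized values (counts,
    minutes, flags) and grouped into wait-increasing (phi > 0) and
    wait-decreasing (phi < 0) factors.  Attributions themselves are
    described only by direction, since per-feature minutes are not well
    defined under the nonlinear inverse transform.
    """
    pred_sqrt = max(explanation.phi0 + sum(explanation.phi.values()), 0.0)
    minutes = float(inverse_transform(pred_sqrt))
    ranked = sorted(
        explanation.phi.items(), key=lambda kv: (-abs(kv[1]), kv[0])
    )[: int(top_k)]
    increasing: list[tuple[str, str]] = []
    decreasing: list[tuple[str, str]] = []
    denormalized: dict[str, float] = {}
    phrases_up: list[str] = []
    phrases_down: list[str] = []
    for name, phi in ranked:
        if phi == 0.0:
            continue
        raw = explanation.feature_values[name]
        if name in _FLAG_PHRASES:
            denorm = float(int(round(raw)))
        else:
            if name not in state.feature_min:
                raise KeyError(f"no min-max bounds recorded for cited feature {name!r}")
            denorm = inverse_minmax(raw, name, state)
        rendered, phrase = _render(name, denorm, raw)
        denormalized[name] = float(rendered) if name not in _FLAG_PHRASES else denorm
        if phi > 0:
            increasing.append((name, rendered))
            phrases_up.append(phrase)
        else:
            decreasing.append((name, rendered))
            phrases_down.append(phrase)

    sentences = [f"Your waiting time is predicted to be about {round(minutes)} minutes."]
    if phrases_up:
        sentences.append("Increasing the wait: " + "; ".join(phrases_up) + ".")
    if phrases_down:
        sentences.append("Decreasing the wait: " + "; ".join(phrases_down) + ".")
    if not phrases_up and not phrases_down:
        sentences.append("No individual factor moved this prediction away from the baseline.")
    return NarrativeExplanation(
        expected_minutes=minutes,
        increasing=increasing,
        decreasing=decreasing,
        denormalized=denormalized,
        text=" ".join(sentences),
    )
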