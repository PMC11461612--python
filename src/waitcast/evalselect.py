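"""Accuracy and dissatisfaction metrics, DAES, and model selection.

The dissatisfaction-aware asymmetric error score for a tolerance
``gamma`` (minutes) is

    DAES(gamma) = rho(eps > 0) * e(eps > 0) + rho(eps < -gamma) * e(eps < -gamma)

with ``eps = y - yhat`` in minutes, ``rho`` the proportion of instances
in each condition and ``e`` a base metric (RMSE by default) computed
over that condition's subset.  Underestimation (eps > 0) is always
penalized; overestimation only once it exceeds ``gamma`` minutes, the
point at which a patient trusting the forecast might leave the waiting
room and miss their call.  The candidate with the lowest DAES balances
accuracy against underestimation.

Selection runs repeated k-fold cross-validation over a grid of loss
candidates (symmetric squared error, Quad-Quad alphas, LINEX betas);
models are trained on the square-root-transformed target and all
metrics are computed in minutes after inverse transformation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .asymloss import make_objective
from .features import FEATURE_COLUMNS
from .preprocess import TARGET, TARGET_TRANSFORMED, inverse_transform

__all__ = [
    "MetricReport",
    "DAESConfig",
    "Candidate",
    "CVPlan",
    "SelectionResult",
    "compute_metrics",
    "daes",
    "implied_r2",
    "make_lightgbm_learner",
    "default_candidates",
    "cross_validate_select",
    "fit_candidate",
    "predict_minutes",
    "gamma_sweep",
]

logger = logging.getLogger(__name__)

# lightgbm's sklearn wrapper auto-names numpy columns and then warns about
# them on every predict; the message is noise for array-based pipelines
warnings.filterwarnings("ignore", message="X does not have valid feature names")

DEFAULT_LEARNER_PARAMS: dict = {
    "n_estimators": 200,
    "learning_rate": 0.1,
    "num_leaves": 31,
    "min_child_samples": 20,
    "subsample": 1.0,
    "n_jobs": 1,
    "verbose": -1,
}


@dataclass(frozen=True)
class MetricReport:
    rmse: float
    mae: float
    rmsle: float
    r2: float
    rho_under: float  # proportion with eps > 0
    rho_over_gamma: float  # proportion with eps < -gamma
    rmse_under: float  # RMSE over {eps > 0}
    rmse_over: float  # RMSE over {eps < 0}
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "rmse": self.rmse,
            "mae": self.mae,
            "rmsle": self.rmsle,
            "r2": self.r2,
            "rho_under": self.rho_under,
            "rho_over_gamma": self.rho_over_gamma,
            "rmse_under": self.rmse_under,
            "rmse_over": self.rmse_over,
            "n": self.n,
        }


@dataclass(frozen=True)
class DAESConfig:
    gamma: float = 30.0  # minutes
    base_metric: str = "rmse"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.base_metric != "rmse":
            raise ValueError("only RMSE is supported as the DAES base metric")


def _rmse(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x)))) if x.size else 0.0


def compute_metrics(y, yhat, gamma: float = 30.0) -> MetricReport:
    """Accuracy plus under/overestimation breakdown, all in minutes.

    eps = 0 counts as neither under- nor overestimation.  Empty
    conditional subsets yield metric 0 and proportion 0.  RMSLE floors
    predictions at 0 before the log.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0:
        raise ValueError("compute_metrics needs at least one prediction")
    eps = y - yhat
    under = eps > 0
    over = eps < 0
    over_gamma = eps < -gamma
    sse = float(np.sum(np.square(eps)))
    sst = float(np.sum(np.square(y - y.mean())))
    return MetricReport(
        rmse=_rmse(eps),
        mae=float(np.mean(np.abs(eps))),
        rmsle=_rmse(np.log1p(y) - np.log1p(np.maximum(yhat, 0.0))),
        r2=1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf),
        rho_under=float(under.mean()),
        rho_over_gamma=float(over_gamma.mean()),
        rmse_under=_rmse(eps[under]),
        rmse_over=_rmse(eps[over]),
        n=int(y.size),
    )


def daes(y, yhat, config: DAESConfig | float = DAESConfig()) -> float:
    """Dissatisfaction-aware asymmetric error score, in minutes."""
    if not isinstance(config, DAESConfig):
        config = DAESConfig(gamma=float(config))
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0:
        raise ValueError("daes needs at least one prediction")
    eps = y - yhat
    under = eps > 0
    over = eps < -config.gamma
    return float(under.mean() * _rmse(eps[under]) + over.mean() * _rmse(eps[over]))


def implied_r2(rmse: float, target_sd: float) -> float:
    """R^2 implied by an RMSE and the target's standard deviation.

    With SST ~ n * sd^2 this is 1 - (rmse / sd)^2 — a consistency
    identity linking two printed summary numbers.
    """
    return 1.0 - (rmse / target_sd) ** 2


# --------------------------------------------------------------------------
# learner contract and candidates

def make_lightgbm_learner(objective=None, params: Mapping | None = None):
    """Default learner factory: LightGBM behind the objective adapter.

    ``objective`` is an adapter from :func:`waitcast.asymloss.make_objective`
    (or None for the library's built-in squared error).  Any regressor
    exposing fit/predict and accepting such an adapter satisfies the
    contract.
    """
    from lightgbm import LGBMRegressor

    merged = dict(DEFAULT_LEARNER_PARAMS)
    if params:
        merged.update(params)
    return LGBMRegressor(objective=objective or "regression", **merged)


@dataclass(frozen=True)
class Candidate:
    loss_tag: str  # "mse" | "quad_quad" | "linex"
    param: float | None = None  # alpha or beta; None for mse

    @property
    def key(self) -> str:
        return self.loss_tag if self.param is None else f"{self.loss_tag}({self.param:g})"

    @property
    def asymmetry(self) -> float:
        """Distance from the symmetric member of the family (tie-break key)."""
        if self.loss_tag == "quad_quad":
            return abs(self.param - 0.5)
        if self.loss_tag == "linex":
            return abs(self.param)
        return 0.0

    def objective(self):
        if self.loss_tag == "mse":
            return make_objective("mse")
        return make_objective(self.loss_tag, self.param)


def default_candidates(
    alphas: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    betas: Sequence[float] = tuple(round(0.1 * i, 1) for i in range(1, 11)),
    include_mse: bool = True,
) -> list[Candidate]:
    out: list[Candidate] = [Candidate("mse")] if include_mse else []
    out += [Candidate("quad_quad", a) for a in alphas]
    out += [Candidate("linex", b) for b in betas]
    return out


@dataclass
class CVPlan:
    k: int = 5
    n_repeats: int = 5
    seeds: Sequence[int] | None = None  # one per repeat; derived from 0.. if None
    candidates: Sequence[Candidate] = field(default_factory=default_candidates)
    score: str = "daes"  # "daes" | "rmse"
    gamma: float = 30.0
    learner_params: Mapping | None = None
    #: optional random search over learner hyperparameters: a mapping
    #: name -> list of values, sampled ``search_budget`` times (budget 1
    #: keeps the defaults / first sample deterministic by search_seed).
    search_space: Mapping[str, Sequence] | None = None
    search_budget: int = 1
    search_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if not self.candidates:
            raise ValueError("candidate grid must be non-empty")
        if self.seeds is None:
            self.seeds = list(range(self.n_repeats))
        if len(self.seeds) != self.n_repeats:
            raise ValueError("need exactly one seed per repeat")


@dataclass
class SelectionResult:
    grid: pd.DataFrame  # one row per candidate: averaged metrics + score
    best: Candidate
    fold_predictions: dict[str, list[tuple[np.ndarray, np.ndarray]]]
    plan: CVPlan

    @property
    def best_row(self) -> pd.Series:
        return self.grid.loc[self.grid["candidate"] == self.best.key].iloc[0]


def predict_minutes(model, X) -> np.ndarray:
    """Raw (sqrt-space) predictions floored at 0, then squared to minutes."""
    raw = np.asarray(model.predict(X), dtype=float)
    return inverse_transform(np.maximum(raw, 0.0))


def _sample_param_sets(plan: CVPlan) -> list[dict]:
    if not plan.search_space or plan.search_budget <= 1:
        base = dict(plan.learner_params or {})
        if plan.search_space:
            rng = np.random.default_rng(plan.search_seed)
            base.update(
                {k: v[rng.integers(len(v))] for k, v in sorted(plan.search_space.items())}
            )
        return [base]
    rng = np.random.default_rng(plan.search_seed)
    names = sorted(plan.search_space)
    sets = []
    for _ in range(plan.search_budget):
        s = dict(plan.learner_params or {})
        s.update({k: plan.search_space[k][rng.integers(len(plan.search_space[k]))] for k in names})
        sets.append(s)
    return sets


def _cv_folds(n: int, plan: CVPlan):
    for seed in plan.seeds:
        kf = KFold(n_splits=plan.k, shuffle=True, random_state=int(seed))
        yield from kf.split(np.arange(n))


def cross_validate_select(
    train: pd.DataFrame,
    plan: CVPlan,
    learner_factory: Callable = make_lightgbm_learner,
) -> SelectionResult:
    """Repeated k-fold selection over the loss-candidate grid.

    For every candidate (and hyperparameter sample, when a search space
    is configured), models are trained on the sqrt target over k folds
    x n_repeats; fold predictions are inverse-transformed to minutes
    before any metric.  Metrics are averaged over folds.  The winner
    minimizes the configured score (DAES(gamma) or RMSE); exact score
    ties go to the candidate closest to its family's symmetric member.
    """
    X = train[FEATURE_COLUMNS].to_numpy(dtype=float)
    y_t = train[TARGET_TRANSFORMED].to_numpy(dtype=float)
    y_min = train[TARGET].to_numpy(dtype=float)

    param_sets = _sample_param_sets(plan)
    rows = []
    fold_preds: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for cand in plan.candidates:
        best_for_cand = None
        for pi, pset in enumerate(param_sets):
            preds: list[tuple[np.ndarray, np.ndarray]] = []
            try:
                for tr_idx, va_idx in _cv_folds(len(train), plan):
                    model = learner_factory(cand.objective(), pset)
                    model.fit(X[tr_idx], y_t[tr_idx])
                    yhat = predict_minutes(model, X[va_idx])
                    preds.append((y_min[va_idx], yhat))
            except Exception:  # pragma: no cover - learner failure path
                logger.exception("candidate %s failed; excluded", cand.key)
                continue
            reports = [compute_metrics(yv, yh, plan.gamma) for yv, yh in preds]
            mean = {
                k: float(np.mean([r.as_dict()[k] for r in reports]))
                for k in reports[0].as_dict()
            }
            mean["daes"] = float(
                np.mean([daes(yv, yh, plan.gamma) for yv, yh in preds])
            )
            pooled = (
                np.concatenate([yv for yv, _ in preds]),
                np.concatenate([yh for _, yh in preds]),
            )
            mean["rho_under_pooled"] = float((pooled[0] - pooled[1] > 0).mean())
            score = mean["daes"] if plan.score == "daes" else mean["rmse"]
            entry = (score, pi, mean, preds, pset)
            if best_for_cand is None or entry[0] < best_for_cand[0]:
                best_for_cand = entry
        if best_for_cand is None:
            continue
        score, _pi, mean, preds, pset = best_for_cand
        fold_preds[cand.key] = preds
        rows.append(
            {
                "candidate": cand.key,
                "loss": cand.loss_tag,
                "param": cand.param,
                "asymmetry": cand.asymmetry,
                "score": score,
                **mean,
                "learner_params": pset,
            }
        )
    if not rows:
        raise RuntimeError("every candidate failed during cross-validation")
    grid = pd.DataFrame(rows)
    order = grid.sort_values(["score", "asymmetry", "candidate"], kind="mergesort")
    best_row = order.iloc[0]
    best = next(c for c in plan.candidates if c.key == best_row["candidate"])
    return SelectionResult(grid=grid, best=best, fold_predictions=fold_preds, plan=plan)


def fit_candidate(
    train: pd.DataFrame,
    candidate: Candidate,
    learner_params: Mapping | None = None,
    learner_factory: Callable = make_lightgbm_learner,
):
    """Fit one candidate on the full training table (sqrt target)."""
    model = learner_factory(candidate.objective(), dict(learner_params or {}))
    model.fit(
        train[FEATURE_COLUMNS].to_numpy(dtype=float),
        train[TARGET_TRANSFORMED].to_numpy(dtype=float),
    )
    return model


DEFAULT_OVER_THRESHOLDS = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)


def gamma_sweep(
    train: pd.DataFrame,
    test: pd.DataFrame,
    gammas: Sequence[float],
    plan: CVPlan,
    learner_factory: Callable = make_lightgbm_learner,
    over_thresholds: Sequence[float] = DEFAULT_OVER_THRESHOLDS,
) -> pd.DataFrame:
    """Best-model-per-gamma evaluation on the held-out test split.

    Fold predictions per candidate are computed once; DAES(gamma) is
    then re-scored from them for each gamma (the predictions do not
    depend on gamma), the per-gamma winner is refit on the full train
    table and evaluated on test.  Rows report the selected candidate,
    test RMSE, rho(eps>0), conditional RMSEs and rho(eps < -g) for each
    threshold g.  A symmetric baseline row (the symmetric candidate in
    the grid, fit once) is reported per gamma for contrast; it is
    invariant to gamma by construction.
    """
    base = cross_validate_select(train, plan, learner_factory)
    X_test = test[FEATURE_COLUMNS].to_numpy(dtype=float)
    y_test = test[TARGET].to_numpy(dtype=float)

    by_key = {c.key: c for c in plan.candidates}
    symmetric = min(plan.candidates, key=lambda c: (c.asymmetry, c.key))
    fitted: dict[str, object] = {}

    def evaluate(cand: Candidate) -> dict:
        if cand.key not in fitted:
            params = base.grid.loc[
                base.grid["candidate"] == cand.key, "learner_params"
            ].iloc[0]
            fitted[cand.key] = fit_candidate(train, cand, params, learner_factory)
        yhat = predict_minutes(fitted[cand.key], X_test)
        rep = compute_metrics(y_test, yhat)
        eps = y_test - yhat
        row = {
            "rmse": rep.rmse,
            "rho_under": rep.rho_under,
            "rmse_under": rep.rmse_under,
            "rmse_over": rep.rmse_over,
        }
        for g in over_thresholds:
            row[f"rho_over_{g:g}"] = float((eps < -g).mean())
        return row

    rows = []
    for gamma in gammas:
        scored = []
        for key, preds in base.fold_predictions.items():
            score = float(np.mean([daes(yv, yh, gamma) for yv, yh in preds]))
            scored.append((score, by_key[key].asymmetry, key))
        scored.sort()
        winner = by_key[scored[0][2]]
        rows.append(
            {
                "gamma": gamma,
                "selected": winner.key,
                "selected_loss": winner.loss_tag,
                "selected_param": winner.param,
                "selected_asymmetry": winner.asymmetry,
                "cv_score": scored[0][0],
                **evaluate(winner),
            }
        )
        rows.append(
            {
                "gamma": gamma,
                "selected": f"baseline:{symmetric.key}",
                "selected_loss": symmetric.loss_tag,
                "selected_param": symmetric.param,
                "selected_asymmetry": symmetric.asymmetry,
                "cv_score": float(
                    np.mean(
                        [daes(yv, yh, gamma) for yv, yh in base.fold_predictions[symmetric.key]]
                    )
                ),
                **evaluate(symmetric),
            }
        )
    return pd.DataFrame(rows)
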