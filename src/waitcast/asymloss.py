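"""Asymmetric training losses with analytic derivatives.

Both losses act on the signed error ``eps = y - yhat`` (positive means
underestimation, the direction that drives patient dissatisfaction) and
are smooth enough for second-order gradient boosting:

* Quad-Quad: ``L(eps) = 2 * [alpha + (1 - 2*alpha) * 1{eps < 0}] * eps**2``
  — quadratic on both sides with side-dependent coefficient.  alpha =
  0.5 is the symmetric case (identically the squared error); alpha >
  0.5 penalizes underestimation more.
* LINEX: ``L(eps) = (2 / beta**2) * (exp(beta*eps) - beta*eps - 1)`` —
  exponential on one side, linear on the other; beta -> 0 recovers the
  squared error.

Derivatives are with respect to the *prediction* (d eps / d yhat = -1),
the convention a boosting library's custom objective consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "QuadQuadParams",
    "LinexParams",
    "LossEval",
    "quad_quad_loss",
    "linex_loss",
    "loss_gradients",
    "make_objective",
    "CURVATURE_FLOOR",
    "LINEX_EXPONENT_CAP",
]

#: Hessian floor keeping second-order boosting steps finite even in the
#: degenerate alpha = 1.0 limit where one side loses all curvature.
CURVATURE_FLOOR = 1e-6

#: |beta * eps| cap; beyond it the exponential is continued linearly so
#: the loss stays finite and convex instead of overflowing.
LINEX_EXPONENT_CAP = 30.0


@dataclass(frozen=True)
class QuadQuadParams:
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]; 1.0 is the degenerate limit")

    @property
    def degenerate(self) -> bool:
        return self.alpha >= 1.0


@dataclass(frozen=True)
class LinexParams:
    beta: float

    def __post_init__(self) -> None:
        if self.beta == 0.0:
            raise ValueError("beta must be nonzero (beta -> 0 is the squared error)")


@dataclass(frozen=True)
class LossEval:
    """Loss value with first and second derivatives w.r.t. the prediction."""

    loss: np.ndarray
    d1: np.ndarray
    d2: np.ndarray


def _side_coef(eps: np.ndarray, alpha: float) -> np.ndarray:
    # eps = 0 takes the underestimation coefficient alpha: loss and d1
    # are continuous there, only d2 jumps, so hessians are deterministic.
    return np.where(eps < 0.0, 1.0 - alpha, alpha)


def quad_quad_loss(eps, params: QuadQuadParams) -> np.ndarray:
    eps = np.asarray(eps, dtype=float)
    return 2.0 * _side_coef(eps, params.alpha) * np.square(eps)


def _linex_exp_terms(eps: np.ndarray, beta: float):
    """exp(beta*eps) with linear continuation of the loss beyond the cap."""
    u = beta * eps
    uc = np.clip(u, -LINEX_EXPONENT_CAP, LINEX_EXPONENT_CAP)
    e = np.exp(uc)
    # first-order continuation: exp(u) ~ exp(cap) * (1 + (u - cap)) for u > cap
    over = u - uc
    return e, over


def linex_loss(eps, params: LinexParams) -> np.ndarray:
    eps = np.asarray(eps, dtype=float)
    beta = params.beta
    e, over = _linex_exp_terms(eps, beta)
    core = e * (1.0 + over) - beta * eps - 1.0
    return (2.0 / beta**2) * core


def loss_gradients(loss_tag: str, y, yhat, params) -> LossEval:
    """Analytic (loss, dL/dyhat, d2L/dyhat2) for one loss family.

    Quad-Quad: d1 = -4*c*eps, d2 = 4*c with c = alpha on eps >= 0 and
    1 - alpha on eps < 0.  LINEX: d1 = -(2/beta)*(exp(beta*eps) - 1),
    d2 = 2*exp(beta*eps).  d2 is floored at ``CURVATURE_FLOOR``.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    eps = y - yhat
    if loss_tag == "quad_quad":
        if not isinstance(params, QuadQuadParams):
            params = QuadQuadParams(float(params))
        c = _side_coef(eps, params.alpha)
        loss = 2.0 * c * np.square(eps)
        d1 = -4.0 * c * eps
        d2 = 4.0 * c * np.ones_like(eps)
    elif loss_tag == "linex":
        if not isinstance(params, LinexParams):
            params = LinexParams(float(params))
        beta = params.beta
        e, over = _linex_exp_terms(eps, beta)
        loss = (2.0 / beta**2) * (e * (1.0 + over) - beta * eps - 1.0)
        # beyond the cap the loss continues linearly: slope exp(+-cap) - 1,
        # curvature 0 (then floored)
        d1 = -(2.0 / beta) * (e - 1.0)
        d2 = np.where(over == 0.0, 2.0 * e, 0.0)
    elif loss_tag in ("mse", "squared_error"):
        loss = np.square(eps)
        d1 = -2.0 * eps
        d2 = 2.0 * np.ones_like(eps)
    else:
        raise ValueError(f"unknown loss_tag {loss_tag!r}")
    return LossEval(loss=loss, d1=d1, d2=np.maximum(d2, CURVATURE_FLOOR))


def make_objective(loss_tag: str, params=None) -> Callable:
    """Objective adapter: (y_true, y_pred) -> (grad, hess) per instance.

    This is the signature gradient-boosting learners with custom
    objectives (e.g. LightGBM's sklearn API) consume; the gradients are
    w.r.t. the raw prediction.
    """

    def objective(y_true, y_pred):
        ev = loss_gradients(loss_tag, y_true, y_pred, params)
        return ev.d1, ev.d2

    objective.loss_tag = loss_tag
    objective.params = params
    return objective
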