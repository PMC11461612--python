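"""Metrics, DAES, and cross-validated selection mechanics."""

import numpy as np
import pandas as pd
import pytest

from waitcast import evalselect as ev
from waitcast import preprocess as pp


class TestComputeMetrics:
    def test_perfect_predictions(self):
        rep = ev.compute_metrics([10, 20, 30], [10, 20, 30])
        assert rep.rmse == rep.mae == rep.rmsle == 0
        assert rep.r2 == 1.0 and rep.rho_under == 0.0

    def test_hand_example(self):
        rep = ev.compute_metrics([10, 20], [15, 15])
        assert rep.rmse == pytest.approx(5.0)
        assert rep.mae == pytest.approx(5.0)
        assert rep.rho_under == 0.5
        assert rep.rmse_under == pytest.approx(5.0)
        assert rep.rmse_over == pytest.approx(5.0)

    def test_implied_r2_consistency(self):
        """Printed test RMSE and target sd must reproduce the printed R^2."""
        assert round(ev.implied_r2(14.975, 23.001), 3) == 0.576

    def test_duplication_invariance(self):
        y = np.array([5.0, 30.0, 70.0, 12.0])
        yhat = np.array([9.0, 25.0, 80.0, 12.0])
        a = ev.compute_metrics(y, yhat)
        b = ev.compute_metrics(np.tile(y, 3), np.tile(yhat, 3))
        for k, v in a.as_dict().items():
            if k != "n":
                assert v == pytest.approx(b.as_dict()[k])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ev.compute_metrics([], [])


class TestDAES:
    def test_hand_evaluated_score(self):
        """errors {+3,+4,-50,-10}, gamma=30: 0.5*sqrt(12.5) + 0.25*50."""
        y = np.array([3.0, 4.0, -50.0, -10.0])
        yhat = np.zeros(4)
        expected = 0.5 * np.sqrt(12.5) + 0.25 * 50.0
        assert ev.daes(y, yhat, 30.0) == pytest.approx(expected)
        assert expected == pytest.approx(14.2678, abs=1e-4)

    def test_all_small_overestimates_score_zero(self):
        y = np.zeros(4)
        yhat = np.array([1.0, 5.0, 10.0, 29.0])  # eps in (-gamma, 0]
        assert ev.daes(y, yhat, 30.0) == 0.0

    def test_large_gamma_leaves_underestimation_term(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 60, 50)
        yhat = rng.uniform(0, 60, 50)
        eps = y - yhat
        under_term = (eps > 0).mean() * np.sqrt(np.mean(eps[eps > 0] ** 2))
        assert ev.daes(y, yhat, 1e9) == pytest.approx(under_term)

    def test_under_term_closed_form_oracle(self):
        """rho * RMSE over {eps>0} equals sqrt(sum eps^2 * count) / n."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.uniform(0, 100, 40)
            yhat = rng.uniform(0, 100, 40)
            eps = y - yhat
            pos = eps[eps > 0]
            oracle = np.sqrt(np.sum(pos**2) * pos.size) / eps.size
            measured = ev.daes(y, yhat, 1e9)
            assert measured == pytest.approx(oracle)

    def test_nonincreasing_in_gamma(self):
        rng = np.random.default_rng(4)
        gammas = [1.0, 5.0, 10.0, 20.0, 40.0, 80.0]
        for _ in range(100):
            y = rng.uniform(0, 120, 30)
            yhat = rng.uniform(0, 120, 30)
            scores = [ev.daes(y, yhat, g) for g in gammas]
            assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            ev.DAESConfig(gamma=-1.0)


def tiny_train(n=120, seed=0):
    rng = np.random.default_rng(seed)
    q = rng.uniform(0, 1, n)
    wait = 60 * q + rng.normal(0, 5, n) + 20
    wait = np.clip(wait, 0.1, None)
    frame = pd.DataFrame({c: rng.uniform(0, 1, n) for c in ev.FEATURE_COLUMNS})
    frame["Q_L"] = q
    frame[pp.TARGET] = wait
    frame[pp.TARGET_TRANSFORMED] = np.sqrt(wait)
    return frame


class MeanLearner:
    """Objective-blind constant predictor (for tie-break mechanics)."""

    def fit(self, X, y):
        self.mu = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.mu)


def mean_factory(objective, params):
    return MeanLearner()


class TestSelection:
    def test_deterministic_given_seeds(self):
        plan = lambda: ev.CVPlan(
            k=3, n_repeats=2, seeds=[7, 8],
            candidates=[ev.Candidate("mse"), ev.Candidate("quad_quad", 0.8)],
            learner_params={"n_estimators": 30},
        )
        a = ev.cross_validate_select(tiny_train(), plan())
        b = ev.cross_validate_select(tiny_train(), plan())
        assert a.best.key == b.best.key
        pd.testing.assert_frame_equal(
            a.grid.drop(columns="learner_params"), b.grid.drop(columns="learner_params")
        )

    def test_symmetric_rmse_selection_is_plain_accuracy_selection(self):
        plan = ev.CVPlan(
            k=3, n_repeats=1,
            candidates=[ev.Candidate("mse"), ev.Candidate("quad_quad", 0.5)],
            score="rmse", learner_params={"n_estimators": 30},
        )
        result = ev.cross_validate_select(tiny_train(), plan)
        assert result.best_row["score"] == result.grid["rmse"].min()

    def test_score_tie_goes_to_smaller_asymmetry(self):
        plan = ev.CVPlan(
            k=2, n_repeats=1,
            candidates=[ev.Candidate("quad_quad", 0.7), ev.Candidate("quad_quad", 0.6)],
        )
        result = ev.cross_validate_select(tiny_train(), plan, learner_factory=mean_factory)
        # identical predictions -> identical scores -> least-asymmetric wins
        assert result.grid["score"].nunique() == 1
        assert result.best.param == 0.6

    def test_predictions_reported_in_minutes(self):
        plan = ev.CVPlan(
            k=3, n_repeats=1, candidates=[ev.Candidate("mse")],
            learner_params={"n_estimators": 30},
        )
        result = ev.cross_validate_select(tiny_train(), plan)
        y, yhat = result.fold_predictions["mse"][0]
        assert y.max() > 10  # minute scale, not sqrt scale
        assert (yhat >= 0).all()


@pytest.fixture(scope="module")
def sweep():
    train = tiny_train(300, seed=1)
    test = tiny_train(80, seed=2)
    plan = ev.CVPlan(
        k=3, n_repeats=1,
        candidates=[ev.Candidate("quad_quad", a) for a in (0.5, 0.8)],
        learner_params={"n_estimators": 40},
    )
    return ev.gamma_sweep(train, test, [10.0, 30.0, 60.0], plan)


class TestGammaSweep:
    def test_baseline_rows_invariant_to_gamma(self, sweep):
        base = sweep[sweep["selected"].str.startswith("baseline:")]
        metric_cols = [c for c in base.columns if c.startswith(("rmse", "rho"))]
        assert base[metric_cols].round(12).drop_duplicates().shape[0] == 1

    def test_thresholds_beyond_error_range_give_zero_rho(self, sweep):
        # rho(eps < -g) is non-increasing in g and hits 0 once g exceeds
        # the largest overestimation error
        cols = [c for c in sweep.columns if c.startswith("rho_over_")]
        vals = sweep[cols].to_numpy()
        assert (np.diff(vals, axis=1) <= 1e-12).all()

    def test_selected_candidates_come_from_the_grid(self, sweep):
        chosen = set(sweep.loc[~sweep["selected"].str.startswith("baseline:"), "selected"])
        assert chosen <= {"quad_quad(0.5)", "quad_quad(0.8)"}
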