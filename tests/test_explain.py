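"""Shapley attributions: axioms, oracle equivalence, narratives."""

import itertools
import math
import re

import numpy as np
import pandas as pd
import pytest

from waitcast import explain as ex
from waitcast import preprocess as pp


def perm_shapley(predict, x, background):
    """Independent permutation-form oracle: average marginal contribution
    over all M! feature orderings."""
    m = len(x)
    phi = np.zeros(m)
    for order in itertools.permutations(range(m)):
        current = np.array(background, dtype=float)
        prev = float(np.mean(predict(current)))
        for i in order:
            current[:, i] = x[i]
            value = float(np.mean(predict(current)))
            phi[i] += value - prev
            prev = value
    return phi / math.factorial(m)


class TestExactShapley:
    def test_additive_model_closed_form(self):
        a, b = 3.0, -2.0
        f = lambda X: a * X[:, 0] + b * X[:, 1]
        rng = np.random.default_rng(0)
        background = rng.normal(size=(40, 2))
        x = np.array([1.5, -0.5])
        e = ex.exact_shapley(f, x, background)
        assert e.phi["x0"] == pytest.approx(a * (x[0] - background[:, 0].mean()))
        assert e.phi["x1"] == pytest.approx(b * (x[1] - background[:, 1].mean()))

    def test_constant_model_all_zero(self):
        f = lambda X: np.full(len(X), 7.5)
        e = ex.exact_shapley(f, [1.0, 2.0, 3.0], np.zeros((5, 3)))
        assert all(v == 0 for v in e.phi.values())
        assert e.phi0 == 7.5

    def test_matches_permutation_oracle_exhaustively(self):
        rng = np.random.default_rng(1)
        f = lambda X: X[:, 0] * X[:, 1] - np.maximum(X[:, 2], 0) + 0.3 * X[:, 3] ** 2
        background = rng.normal(size=(6, 4))
        for _ in range(5):
            x = rng.normal(size=4)
            e = ex.exact_shapley(f, x, background)
            oracle = perm_shapley(f, x, background)
            assert np.allclose(list(e.phi.values()), oracle, atol=1e-10)

    def test_local_accuracy_any_model(self):
        rng = np.random.default_rng(2)
        f = lambda X: np.sin(X[:, 0]) * X[:, 1] + np.exp(0.1 * X[:, 2])
        x = rng.normal(size=3)
        e = ex.exact_shapley(f, x, rng.normal(size=(20, 3)))
        assert e.phi0 + sum(e.phi.values()) == pytest.approx(f(x[None, :])[0], abs=1e-8)
        assert e.g == pytest.approx(e.prediction, abs=1e-8)

    def test_symmetry_of_exchangeable_features(self):
        f = lambda X: X[:, 0] + X[:, 1]
        background = np.array([[0.0, 0.0], [1.0, 1.0], [0.5, 0.5]])
        e = ex.exact_shapley(f, [2.0, 2.0], background)
        assert e.phi["x0"] == pytest.approx(e.phi["x1"])

    def test_missingness_ignored_feature_gets_zero(self):
        f = lambda X: 2.0 * X[:, 0] - X[:, 1]
        rng = np.random.default_rng(3)
        e = ex.exact_shapley(f, rng.normal(size=3), rng.normal(size=(15, 3)))
        assert e.phi["x2"] == pytest.approx(0.0, abs=1e-12)

    def test_feature_count_limit(self):
        f = lambda X: X.sum(axis=1)
        with pytest.raises(ValueError, match="at most"):
            ex.exact_shapley(f, np.zeros(16), np.zeros((2, 16)))


@pytest.fixture(scope="module")
def small_tree_model():
    from lightgbm import LGBMRegressor

    rng = np.random.default_rng(7)
    X = rng.normal(size=(500, 5))
    y = X[:, 0] * X[:, 1] + np.where(X[:, 2] > 0, 2.0, -1.0) + rng.normal(0, 0.1, 500)
    model = LGBMRegressor(n_estimators=25, num_leaves=7, verbose=-1, n_jobs=1).fit(X, y)
    return model, X


class TestFastExplain:
    def test_matches_exact_path(self, small_tree_model):
        model, X = small_tree_model
        background = X[:25]
        rows = X[:8]
        fast = ex.fast_explain(model, rows, background)
        for row, f_exp in zip(rows, fast):
            e_exp = ex.exact_shapley(model.predict, row, background)
            for name in e_exp.phi:
                assert f_exp.phi[name] == pytest.approx(e_exp.phi[name], abs=1e-6)
            assert f_exp.phi0 == pytest.approx(e_exp.phi0, abs=1e-6)

    def test_local_accuracy_bulk(self, small_tree_model):
        model, X = small_tree_model
        rng = np.random.default_rng(11)
        rows = rng.normal(size=(1000, 5))
        exps = ex.fast_explain(model, rows, X[:40])
        preds = model.predict(rows)
        for e, p in zip(exps, preds):
            assert e.phi0 + sum(e.phi.values()) == pytest.approx(p, abs=1e-8)

    def test_identical_rows_identical_explanations(self, small_tree_model):
        model, X = small_tree_model
        rows = np.vstack([X[0], X[0]])
        a, b = ex.fast_explain(model, rows, X[:20])
        assert a.phi == b.phi and a.phi0 == b.phi0

    def test_fallback_without_tree_access(self):
        class Linear:
            def predict(self, X):
                return X[:, 0] * 2.0

        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning, match="falling back"):
            exps = ex.fast_explain(Linear(), rng.normal(size=(2, 3)), rng.normal(size=(6, 3)))
        assert len(exps) == 2


class TestGlobalImportance:
    def make(self, phi_rows):
        return [
            ex.AdditiveExplanation(
                phi0=0.0,
                phi={f"f{j}": v for j, v in enumerate(row)},
                feature_values={f"f{j}": 0.0 for j in range(len(row))},
                prediction=sum(row),
            )
            for row in phi_rows
        ]

    def test_single_instance(self):
        report = ex.global_importance(self.make([[0.5, -2.0]]))
        assert dict(zip(report.table["feature"], report.table["gi"])) == {"f0": 0.5, "f1": 2.0}

    def test_sign_cancellation_guard(self):
        report = ex.global_importance(self.make([[1.0], [-1.0]]))
        assert report.table["gi"].iloc[0] == 1.0

    def test_hand_matrix(self):
        report = ex.global_importance(self.make([[1.0, -4.0], [3.0, 0.0], [2.0, 2.0]]))
        gi = dict(zip(report.table["feature"], report.table["gi"]))
        assert gi == {"f0": 2.0, "f1": 2.0}
        assert report.ranking == ["f0", "f1"]  # tie broken alphabetically


class TestDependence:
    def planted(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        a, b, c = rng.uniform(-1, 1, (3, n))
        exps = [
            ex.AdditiveExplanation(
                phi0=0.0,
                phi={"a": a[i] * c[i], "b": 0.0, "c": 0.0},
                feature_values={"a": a[i], "b": b[i], "c": c[i]},
                prediction=a[i] * c[i],
            )
            for i in range(n)
        ]
        return exps

    def test_auto_recovers_planted_interaction(self):
        data = ex.dependence(self.planted(), "a", "auto")
        assert data.interaction == "c"
        assert len(data.table) == 300

    def test_constant_phi_falls_back_to_first_feature(self):
        exps = self.planted()
        for e in exps:
            e.phi["a"] = 0.0
        data = ex.dependence(exps, "a", "auto")
        assert data.interaction == "b"  # first non-self feature in order

    def test_explicit_interaction_bypasses_auto(self):
        data = ex.dependence(self.planted(), "a", "b")
        assert data.interaction == "b"

    def test_unknown_feature_rejected(self):
        with pytest.raises(KeyError):
            ex.dependence(self.planted(), "zzz")


class TestNarrative:
    def state(self):
        return pp.PreprocessState(
            feature_min={"Q_L": 0.0, "P_ACT": 0.0, "P_NP": 0.0},
            feature_max={"Q_L": 27.0, "P_ACT": 14.90, "P_NP": 19.0},
        )

    def explanation(self):
        return ex.AdditiveExplanation(
            phi0=6.5,
            phi={"Q_L": 0.9, "P_NP": -0.7, "P_ACT": 1.11, "T_S": 0.0},
            feature_values={"Q_L": 0.296, "P_NP": 0.368, "P_ACT": 0.435, "T_S": 0.0},
            prediction=7.81,
        )

    def test_denormalized_citations_match_printed_values(self):
        n = ex.narrative(self.explanation(), self.state(), top_k=3)
        cited = dict(n.increasing + n.decreasing)
        assert cited["Q_L"] == "8"  # 0.296 * 27 patients
        assert cited["P_ACT"] == "6.48"  # 0.435 * 14.90 minutes
        assert cited["P_NP"] == "7"  # 0.368 * 19 patients
        assert n.expected_minutes == pytest.approx(61.0, abs=0.01)
        assert "about 61 minutes" in n.text

    def test_every_number_in_text_reparses(self):
        n = ex.narrative(self.explanation(), self.state(), top_k=3)
        numbers = set(re.findall(r"\d+(?:\.\d+)?", n.text))
        for _, rendered in n.increasing + n.decreasing:
            assert rendered in numbers

    def test_zero_attributions_baseline_only(self):
        e = ex.AdditiveExplanation(
            phi0=5.0, phi={"Q_L": 0.0, "P_NP": 0.0},
            feature_values={"Q_L": 0.1, "P_NP": 0.2}, prediction=5.0,
        )
        n = ex.narrative(e, self.state())
        assert n.increasing == [] and n.decreasing == []
        assert "about 25 minutes" in n.text

    def test_missing_bounds_raise(self):
        e = ex.AdditiveExplanation(
            phi0=5.0, phi={"Q_N": 1.0}, feature_values={"Q_N": 0.5}, prediction=6.0
        )
        with pytest.raises(KeyError):
            ex.narrative(e, self.state())
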