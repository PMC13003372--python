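import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.tree import DecisionTreeRegressor

from ewsbench.contribution import (
    encode_features,
    fit_outcome_model,
    shap_contributions,
    stratum_contrast,
)
from ewsbench.errors import ConfigurationError, FitError
from ewsbench.treeshap import shap_values, tree_expected_value, tree_shap_single
from ewsbench.synthetic import CohortConfig, generate_cohort

from .helpers import oracle_tree_shap


class TestTreeShap:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for depth in (1, 2, 3):
            for rep in range(8):
                X = rng.normal(size=(50, 4))
                y = rng.normal(size=50)
                tree = DecisionTreeRegressor(max_depth=depth, random_state=rep)
                tree.fit(X, y)
                for _ in range(3):
                    x = rng.normal(size=4)
                    got = tree_shap_single(tree, x, 4)
                    want = oracle_tree_shap(tree, x, 4)
                    np.testing.assert_allclose(got, want, atol=1e-10)

    def test_stump_single_feature(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 3))
        y = (X[:, 1] > 0).astype(float)
        tree = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        phi = tree_shap_single(tree, np.array([0.0, 2.0, 0.0]), 3)
        assert phi[0] == 0.0 and phi[2] == 0.0
        assert phi[1] != 0.0

    def test_additivity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(1500, 5))
        y = ((X[:, 0] + 0.5 * X[:, 1] + rng.normal(size=1500)) > 0).astype(int)
        model = GradientBoostingClassifier(n_estimators=40, max_depth=3,
                                           init="zero", random_state=0).fit(X, y)
        phi, base = shap_values(model, X[:200])
        margin = model.decision_function(X[:200])
        np.testing.assert_allclose(phi.sum(axis=1) + base, margin, atol=1e-6)

    def test_requires_zero_init(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 2))
        y = (X[:, 0] > 0).astype(int)
        model = GradientBoostingClassifier(n_estimators=5, random_state=0).fit(X, y)
        with pytest.raises(ConfigurationError):
            shap_values(model, X)

    def test_expected_value_is_cover_weighted_mean(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 3))
        y = rng.normal(size=200)
        tree = DecisionTreeRegressor(max_depth=3, random_state=0).fit(X, y)
        assert tree_expected_value(tree) == pytest.approx(np.mean(tree.predict(X)), abs=1e-9)


class TestFitOutcomeModel:
    def test_single_signal_feature_dominates(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(2000, 4)), columns=list("abcd"))
        y = (X["c"] > 0.5).astype(int)
        model = fit_outcome_model(X, y, {"n_estimators": 40}, seed=0)
        res = shap_contributions(model, X)
        assert res.normalized["c"] == 1.0
        assert res.normalized.drop("c").max() < 0.2

    def test_pure_noise_near_chance(self):
        from ewsbench.discrimination import auroc

        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(3000, 5)))
        X.columns = [f"f{i}" for i in range(5)]
        y = rng.integers(0, 2, 3000)
        model = fit_outcome_model(X.iloc[:2000], y[:2000],
                                  {"n_estimators": 40}, seed=0)
        held = model.decision_function(X.iloc[2000:].to_numpy())
        r = auroc(held, y[2000:])
        assert abs(r.auroc - 0.5) < 0.06

    def test_single_class_raises(self):
        X = pd.DataFrame(np.random.default_rng(7).normal(size=(50, 3)))
        with pytest.raises(FitError):
            fit_outcome_model(X, np.zeros(50))

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("abc"))
        y = (X["a"] > 0).astype(int)
        m1 = fit_outcome_model(X, y, {"n_estimators": 20}, seed=3)
        m2 = fit_outcome_model(X, y, {"n_estimators": 20}, seed=3)
        np.testing.assert_array_equal(m1.decision_function(X.to_numpy()),
                                      m2.decision_function(X.to_numpy()))

    def test_ensemble_dominance_on_cohort(self, default_cohort, default_scores):
        from ewsbench.discrimination import auroc

        df = default_cohort
        y = df["outcome24h"].astype(int).to_numpy()
        half = len(df) // 2
        X = encode_features(df)
        model = fit_outcome_model(X.iloc[:half], y[:half],
                                  {"n_estimators": 100}, seed=0)
        held = model.decision_function(X.iloc[half:].to_numpy())
        model_auc = auroc(held, y[half:]).auroc
        best_single = max(auroc(default_scores[name].iloc[half:].to_numpy(),
                                y[half:]).auroc
                          for name in default_scores.columns)
        assert model_auc >= best_single - 0.02


class TestShapContributions:
    def test_constant_outcome_model_all_zero(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=list("abc"))
        y = np.r_[np.ones(150), np.zeros(150)].astype(int)
        # shuffle so y is independent of X, trees cannot split usefully
        model = fit_outcome_model(X, y, {"n_estimators": 5, "max_depth": 1}, seed=0)
        res = shap_contributions(model, X)
        assert (res.mean_abs_shap < 0.2).all()

    def test_normalized_max_is_one(self, default_cohort):
        sub = default_cohort.iloc[:4000]
        X = encode_features(sub)
        y = sub["outcome24h"].astype(int)
        model = fit_outcome_model(X, y, {"n_estimators": 30}, seed=1)
        res = shap_contributions(model, X.iloc[:500])
        assert res.normalized.max() == 1.0
        assert ((res.normalized >= 0) & (res.normalized <= 1)).all()

    def test_feature_mismatch(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        y = (X["a"] > 0).astype(int)
        model = fit_outcome_model(X, y, {"n_estimators": 5}, seed=0)
        with pytest.raises(ConfigurationError, match="feature"):
            shap_values(model, X.to_numpy()[:, :2])


class TestStratumContrast:
    def test_age_cut_out_of_range(self, default_cohort):
        with pytest.raises(ConfigurationError):
            stratum_contrast(default_cohort.iloc[:200], age_cut=200, B=10)

    def test_stratum_without_events(self):
        df = generate_cohort(CohortConfig(n=400, seed=1)).records.copy()
        df["outcome24h"] = df["age"] >= 87  # younger stratum has no events
        with pytest.raises(FitError):
            stratum_contrast(df, age_cut=87, B=10)

    def test_report_shape_and_determinism(self):
        df = generate_cohort(CohortConfig(n=6000, seed=2, prevalence=0.1)).records
        kwargs = dict(age_cut=87, B=100, seed=5,
                      hyperparams={"n_estimators": 25}, max_shap_samples=300)
        r1 = stratum_contrast(df, **kwargs)
        r2 = stratum_contrast(df, **kwargs)
        pd.testing.assert_series_equal(r1.shap_difference, r2.shap_difference)
        pd.testing.assert_series_equal(r1.p_boot, r2.p_boot)
        assert r1.younger.normalized.max() == 1.0
        assert r1.older.normalized.max() == 1.0
        assert (r1.p_boot.between(0, 1)).all()

    def test_constructed_interaction_recovered(self):
        """When oxygen dependence matters far more for the older stratum, its
        normalised contribution difference must be positive and significant."""
        rng = np.random.default_rng(11)
        n = 20_000
        base = generate_cohort(CohortConfig(n=n, seed=3, severity_shift=0.0)).records.copy()
        old = (base["age"] >= 87).to_numpy()
        o2 = base["on_oxygen"].astype(bool).to_numpy()
        logits = -3.0 + 0.4 * o2 + 3.0 * (o2 & old)
        base["outcome24h"] = rng.random(n) < 1 / (1 + np.exp(-logits))
        rep = stratum_contrast(base, age_cut=87, B=400, seed=7,
                               hyperparams={"n_estimators": 60},
                               max_shap_samples=800)
        assert rep.shap_difference["on_oxygen"] > 0
        assert rep.p_boot["on_oxygen"] < 0.05
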