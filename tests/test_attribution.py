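import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.tree import DecisionTreeRegressor

from knockoffml.attribution import (
    attribute,
    exhaustive_attribute,
    feature_importance,
    importance_for_knockoff_analysis,
    leverage_scores,
    slev_subsample,
    slev_subsample_size,
)
from knockoffml.knockoffs import generate_knockoffs
from knockoffml.learners import fit_single


class TestSubsampleSize:
    @pytest.mark.parametrize(
        "n, expected",
        [
            (10_000, 1984),  # floor(10 * 10000^(1/3) * ln 10000)
            (1_000, 690),  # floor(10 * 10 * ln 1000) = floor(690.77)
            (2, 2),  # capped at n
        ],
    )
    def test_values(self, n, expected):
        assert slev_subsample_size(n) == expected


class TestLeverageScores:
    def test_symmetric_rows_give_uniform_probabilities(self):
        X = np.tile([[1.0], [-1.0]], (10, 1))  # all rows have equal leverage
        ls = leverage_scores(X)
        np.testing.assert_allclose(ls.probabilities, 1 / 20)

    def test_default_rank_for_88_features(self, rng):
        X = rng.standard_normal((200, 88))
        ls = leverage_scores(X)
        assert ls.rank == 20  # ceil(sqrt(88 ln 88)) = ceil(19.85)

    def test_proper_distribution_with_floor(self, rng):
        for n, p in [(30, 3), (100, 10), (57, 5)]:
            X = rng.standard_normal((n, p))
            ls = leverage_scores(X)
            assert ls.probabilities.sum() == pytest.approx(1.0)
            assert ls.probabilities.min() >= 0.5 / n - 1e-12
            assert np.all((ls.leverages >= 0) & (ls.leverages <= 1 + 1e-12))

    def test_rank_reduced_for_degenerate_design(self, rng):
        X = np.ones((40, 6)) * rng.standard_normal((40, 1))  # rank ~2 with 1s
        with pytest.warns(UserWarning, match="rank"):
            ls = leverage_scores(X)
        assert ls.rank <= 2


class TestSlevSubsample:
    def test_full_draw_returns_all_indices(self, rng):
        X = rng.standard_normal((25, 2))
        ls = leverage_scores(X)
        idx = slev_subsample(ls, seed=0, k=25)
        assert np.array_equal(idx, np.arange(25))

    def test_concentrated_probability_dominates(self, rng):
        X = np.vstack([np.full((1, 2), 50.0), rng.standard_normal((40, 2)) * 0.01])
        ls = leverage_scores(X)
        hits = sum(0 in slev_subsample(ls, seed=s, k=1) for s in range(200))
        # the high-leverage row has pi ~= 0.26 (half leverage share of the
        # rank-2 basis plus the uniform floor); uniform would give ~5 hits
        assert hits > 25

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((50, 3))
        ls = leverage_scores(X)
        a = slev_subsample(ls, seed=5)
        b = slev_subsample(ls, seed=5)
        assert np.array_equal(a, b)


class TestAttribute:
    def test_constant_model(self, rng):
        X = rng.standard_normal((50, 3))
        model = DecisionTreeRegressor(max_depth=1).fit(X, np.full(50, 7.0))
        att = attribute(model, X)
        np.testing.assert_allclose(att.values.to_numpy(), 0.0, atol=1e-12)
        assert att.base_value == pytest.approx(7.0)

    def test_stump_attributes_to_split_feature_only(self, rng):
        X = rng.standard_normal((200, 4))
        y = np.where(X[:, 1] > 0, 2.0, -1.0)
        model = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        att = attribute(model, X[:20])
        oracle = exhaustive_attribute(model, X[:20])
        np.testing.assert_allclose(
            att.values.to_numpy(), oracle.values.to_numpy(), atol=1e-10
        )
        others = [c for i, c in enumerate(att.values.columns) if i != 1]
        np.testing.assert_allclose(att.values[others].to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(
            att.values.iloc[:, 1] + att.base_value, model.predict(X[:20])
        )

    @pytest.mark.parametrize(
        "factory, raw",
        [
            (
                lambda: RandomForestRegressor(
                    n_estimators=12, max_depth=3, random_state=0
                ),
                lambda m, X: m.predict(X),
            ),
            (
                lambda: GradientBoostingRegressor(
                    n_estimators=20, max_depth=2, random_state=0
                ),
                lambda m, X: m.predict(X),
            ),
            (
                lambda: GradientBoostingClassifier(
                    n_estimators=20, max_depth=2, random_state=0
                ),
                lambda m, X: m.decision_function(X),
            ),
            (
                lambda: RandomForestClassifier(
                    n_estimators=10, max_depth=3, random_state=0
                ),
                lambda m, X: m.predict_proba(X)[:, 1],
            ),
        ],
    )
    def test_path_algorithm_matches_exhaustive_enumeration(
        self, rng, factory, raw
    ):
        p = 7
        X = rng.standard_normal((300, p))
        target = X[:, 0] + X[:, 1] * X[:, 2] + 0.3 * rng.standard_normal(300)
        model = factory()
        if hasattr(model, "predict_proba"):
            model.fit(X, (target > 0).astype(int))
        else:
            model.fit(X, target)
        rows = X[:15]
        att = attribute(model, rows)
        oracle = exhaustive_attribute(model, rows)
        np.testing.assert_allclose(
            att.values.to_numpy(), oracle.values.to_numpy(), atol=1e-9
        )
        # local accuracy against the model's raw output
        np.testing.assert_allclose(
            att.predictions(), raw(model, rows), rtol=1e-6, atol=1e-9
        )

    @pytest.mark.parametrize("algorithm", ["lightgbm", "xgboost"])
    def test_boosters_satisfy_local_accuracy(self, rng, algorithm):
        X = pd.DataFrame(
            rng.standard_normal((400, 6)), columns=[f"f{i}" for i in range(6)]
        )
        y = (X["f0"] + X["f1"] ** 2 + 0.3 * rng.standard_normal(400) > 0).astype(int)
        model = fit_single(algorithm, X, y, "dichotomous", seed=0, n_estimators=30)
        att = attribute(model, X.iloc[:50])
        from scipy.special import logit

        margins = logit(model.predict(X.iloc[:50]))
        np.testing.assert_allclose(att.predictions(), margins, rtol=1e-5, atol=1e-5)


class TestFeatureImportance:
    def test_mean_absolute_attribution(self):
        from knockoffml.attribution import AttributionMatrix

        att = AttributionMatrix(
            values=pd.DataFrame({"a": [1.0, -1.0], "b": [0.0, 0.0]}),
            base_value=0.0,
            model_id="toy",
            output_space="response",
        )
        fi = feature_importance(att)
        assert fi["a"] == 1.0 and fi["b"] == 0.0


class TestKnockoffImportances:
    def test_shape_contract(self, rng):
        X = rng.standard_normal((300, 5))
        ks = generate_knockoffs(X, M=3, seed=0)
        y = (X[:, 0] + 0.5 * rng.standard_normal(300) > 0).astype(int)
        model = fit_single(
            "lightgbm", ks.augmented(), y, "dichotomous", seed=1, n_estimators=30
        )
        iv = importance_for_knockoff_analysis(model, ks, seed=2)
        assert iv.M == 3
        assert len(iv.original) == 5
        assert iv.knockoffs.shape == (3, 5)
        assert (iv.original >= 0).all()
        assert (iv.knockoffs.to_numpy() >= 0).all()

    def test_dominant_risk_feature_beats_its_knockoffs(self, rng):
        wins = 0
        for s in range(8):
            r = np.random.default_rng(s)
            X = r.standard_normal((500, 6))
            y = (2.0 * X[:, 0] + r.standard_normal(500) > 0).astype(int)
            ks = generate_knockoffs(X, M=3, seed=s)
            model = fit_single(
                "lightgbm",
                ks.augmented(),
                y,
                "dichotomous",
                seed=s,
                n_estimators=50,
            )
            iv = importance_for_knockoff_analysis(model, ks, seed=s, subsample=False)
            if iv.original.iloc[0] > iv.knockoffs.iloc[:, 0].max():
                wins += 1
        assert wins >= 7

    def test_slev_importance_tracks_full_sample_importance(self):
        # guards the subsampling approximation on the full-scale design
        from scipy.stats import spearmanr

        from knockoffml.sim_data import simulate_dataset
        from knockoffml.studies import linear_dichotomous

        ds = simulate_dataset(linear_dichotomous())
        ks = generate_knockoffs(ds.X, M=1, seed=0)
        model = fit_single(
            "lightgbm",
            ks.augmented(),
            ds.y,
            "dichotomous",
            seed=1,
            n_estimators=80,
            num_leaves=31,
            max_bin=63,
        )
        sub = importance_for_knockoff_analysis(model, ks, seed=2, subsample=True)
        full = importance_for_knockoff_analysis(model, ks, seed=2, subsample=False)
        rho = spearmanr(sub.original, full.original).statistic
        assert rho >= 0.9
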