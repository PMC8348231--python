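import numpy as np
import pandas as pd
import pytest

from solvar import (
    LAYER1_FEATURES,
    LAYER2_FEATURES,
    fit_binary,
    fit_single_multiclass,
    fit_two_layer,
    planted_signal_matrix,
    predict_two_layer,
    rfe_select,
)
from solvar.learner import (
    N_FEATURES_PER_LAYER,
    N_FEATURES_SINGLE,
    load_model,
    predict_single,
    save_model,
)

FAST = {"min_child_samples": 5}


def _separable_binary(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat(["neg", "pos"], n // 2)
    X = pd.DataFrame({
        "f1": rng.normal(size=n) + 8 * (y == "pos"),
        "f2": rng.normal(size=n),
    })
    return X, y


class TestFitBinary:
    def test_separable_training_accuracy(self):
        X, y = _separable_binary()
        m = fit_binary(X, y, FAST, seed=0, positive_class="pos")
        assert (m.predict_label(X) == y).mean() == 1.0

    def test_same_seed_identical_predictions(self):
        X, y = _separable_binary()
        s1 = fit_binary(X, y, FAST, seed=7).predict_score(X)
        s2 = fit_binary(X, y, FAST, seed=7).predict_score(X)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_rejected(self):
        X, _ = _separable_binary()
        with pytest.raises(ValueError, match="single class"):
            fit_binary(X, np.repeat("pos", len(X)), FAST)

    def test_duplicate_feature_names_rejected(self):
        X, y = _separable_binary()
        X2 = pd.concat([X, X[["f1"]]], axis=1)
        with pytest.raises(ValueError, match="collision"):
            fit_binary(X2, y, FAST)

    def test_feature_mismatch_on_predict(self):
        X, y = _separable_binary()
        m = fit_binary(X, y, FAST)
        with pytest.raises(ValueError, match="mismatch"):
            m.predict_score(X.rename(columns={"f1": "other"}))

    def test_exposes_importances(self):
        X, y = _separable_binary()
        imp = fit_binary(X, y, FAST).feature_importance()
        assert list(imp.index) == ["f1", "f2"] and imp["f1"] > imp["f2"]


class TestRFE:
    def test_identity_when_target_is_feature_count(self):
        X, y = planted_signal_matrix(n=100, seed=0)
        r = rfe_select(X, y, target_k=X.shape[1], seed=0, num_rounds=10)
        assert r.selected == list(X.columns) and r.elimination_order == []

    def test_order_is_permutation(self):
        X, y = planted_signal_matrix(n=200, n_noise=10, seed=1)
        r = rfe_select(X, y, target_k=3, seed=1, num_rounds=20)
        assert sorted(r.full_ranking) == sorted(X.columns)
        assert len(r.selected) == 3

    def test_target_exceeding_features_rejected(self):
        X, y = planted_signal_matrix(n=100, n_noise=5, seed=0)
        with pytest.raises(ValueError):
            rfe_select(X, y, target_k=10, seed=0)

    def test_step_sizes_agree_on_top_feature(self):
        X, y = planted_signal_matrix(n=300, n_noise=20, seed=2)
        r1 = rfe_select(X, y, target_k=1, step=1, seed=2, num_rounds=30)
        r5 = rfe_select(X, y, target_k=1, step=5, seed=2, num_rounds=30)
        assert r1.selected == r5.selected == ["informative"]

    def test_agrees_with_sklearn_rfe_oracle(self):
        """Cross-check the elimination loop against scikit-learn's RFE."""
        from lightgbm import LGBMClassifier
        from sklearn.feature_selection import RFE

        X, y = planted_signal_matrix(n=300, n_noise=20, seed=3)
        ours = rfe_select(X, y, target_k=1, step=1, seed=3, num_rounds=30)
        est = LGBMClassifier(n_estimators=30, random_state=3, n_jobs=1,
                             deterministic=True, force_row_wise=True,
                             importance_type="gain", verbose=-1)
        sk = RFE(est, n_features_to_select=1, step=1).fit(X, y)
        assert list(X.columns[sk.support_]) == ours.selected


@pytest.fixture(scope="module")
def fitted(small_matrix):
    X, y = small_matrix
    return X, y, fit_two_layer(X, y, params=FAST, seed=0)


class TestTwoLayer:

    def test_layer_roles_and_positive_classes(self, fitted):
        _, _, m = fitted
        assert m.layer1.positive_class == "decrease"
        assert m.layer2.positive_class == "increase"
        assert m.layer2.negative_class == "no_effect"

    def test_default_budget_constants(self):
        assert N_FEATURES_PER_LAYER == 20 and N_FEATURES_SINGLE == 30
        assert len(LAYER1_FEATURES) == len(LAYER2_FEATURES) == 20

    def test_routing_rule(self, fitted):
        X, _, m = fitted
        pred = predict_two_layer(m, X)
        dec = pred["score_decrease"] >= m.layer1.decision_threshold
        assert (pred.loc[dec, "predicted"] == "decrease").all()
        inc = ~dec & (pred["score_increase"] >= m.layer2.decision_threshold)
        assert (pred.loc[inc, "predicted"] == "increase").all()
        assert (pred.loc[~dec & ~inc, "predicted"] == "no_effect").all()

    def test_decrease_calls_invariant_to_layer2(self, fitted, small_matrix):
        X, y, m = fitted
        pred = predict_two_layer(m, X)
        # refit layer2 on shuffled labels: decrease calls must not move
        rng = np.random.default_rng(0)
        mask = y != "decrease"
        y2 = rng.permutation(y[mask])
        from solvar.learner import TwoLayerModel
        alt2 = fit_binary(X.loc[mask], y2, FAST, seed=9, positive_class="increase")
        alt = TwoLayerModel(layer1=m.layer1, layer2=alt2)
        pred_alt = predict_two_layer(alt, X)
        dec = pred["predicted"] == "decrease"
        assert (pred_alt.loc[dec, "predicted"] == "decrease").all()

    def test_layer2_trained_only_on_not_decreasing(self, fitted):
        _, y, m = fitted
        n_expected = int((y != "decrease").sum())
        assert m.layer2.n_training_samples == n_expected

    def test_empty_class_rejected(self, small_matrix):
        X, y = small_matrix
        y2 = np.where(y == "increase", "no_effect", y)
        with pytest.raises(ValueError, match="empty class"):
            fit_two_layer(X, y2, params=FAST)

    def test_layer_feature_subsets(self, small_matrix):
        X, y = small_matrix
        m = fit_two_layer(X, y, LAYER1_FEATURES, LAYER2_FEATURES, FAST, seed=0)
        assert m.layer1.feature_names == LAYER1_FEATURES
        assert m.layer2.feature_names == LAYER2_FEATURES
        pred = predict_two_layer(m, X[sorted(set(LAYER1_FEATURES) | set(LAYER2_FEATURES))])
        assert set(pred["predicted"]) <= {"decrease", "no_effect", "increase"}


class TestSingleMulticlass:
    def _three_clusters(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat(["decrease", "no_effect", "increase"], n // 3)
        centers = {"decrease": (0, 0), "no_effect": (10, 0), "increase": (0, 10)}
        X = pd.DataFrame(
            [rng.normal(size=2) + centers[c] for c in y], columns=["u", "v"])
        return X, y

    def test_separable_training_accuracy(self):
        X, y = self._three_clusters()
        m = fit_single_multiclass(X, y, params=FAST, seed=0)
        assert (predict_single(m, X)["predicted"] == y).mean() == 1.0

    def test_same_seed_reproducible(self):
        X, y = self._three_clusters()
        p1 = predict_single(fit_single_multiclass(X, y, params=FAST, seed=4), X)
        p2 = predict_single(fit_single_multiclass(X, y, params=FAST, seed=4), X)
        pd.testing.assert_frame_equal(p1, p2)


class TestPersistence:
    def test_two_layer_roundtrip(self, small_matrix, tmp_path):
        X, y = small_matrix
        m = fit_two_layer(X, y, params=FAST, seed=0)
        save_model(m, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        pd.testing.assert_frame_equal(predict_two_layer(m, X), predict_two_layer(back, X))
        assert (tmp_path / "bundle" / "meta.json").exists()

    def test_single_roundtrip(self, small_matrix, tmp_path):
        X, y = small_matrix
        m = fit_single_multiclass(X, y, params=FAST, seed=0)
        save_model(m, tmp_path / "single")
        back = load_model(tmp_path / "single")
        pd.testing.assert_frame_equal(predict_single(m, X), predict_single(back, X))
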