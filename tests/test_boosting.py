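"""Boosted stumps: split search against brute force, algorithm behavior,
feature importance, and cross-validated evaluation."""

import numpy as np
import pytest

from phonovib.boosting import (AdaBoostStumps, BoostConfig,
                               LogitBoostStumps, RUSBoostStumps,
                               crossval_evaluate, feature_importance,
                               fit_stump, make_estimator, predict_scores,
                               roc_auc, train, StumpEnsemble)


def brute_force_stump_error(X, y_pm, w):
    """Exhaustive weighted-misclassification optimum over all features and
    midpoints (independent oracle)."""
    best = 0.5 * (w.sum() - abs(np.sum(w * y_pm)))
    for f in range(X.shape[1]):
        xs = np.unique(X[:, f])
        for lo, hi in zip(xs[:-1], xs[1:]):
            thr = 0.5 * (lo + hi)
            left = X[:, f] <= thr
            for lv in (-1, 1):
                err = np.sum(w[left & (y_pm != lv)]) + \
                    np.sum(w[~left & (y_pm != -lv)])
                best = min(best, err)
    return best


class TestFitStump:
    def test_perfect_split_at_midpoint(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        st = fit_stump(X, y)
        assert st.threshold == 1.5
        assert st.left == -1.0 and st.right == 1.0
        assert st.gain > 0

    def test_matches_brute_force_optimum(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            X = rng.normal(size=(20, 3))
            y = np.where(rng.uniform(size=20) > 0.5, 1.0, -1.0)
            w = rng.uniform(0.1, 1.0, 20)
            st = fit_stump(X, y, w)
            pred = st.predict(X)
            err = float(np.sum(w[pred != y]))
            assert err == pytest.approx(brute_force_stump_error(X, y, w),
                                        abs=1e-10)

    def test_random_labels_give_near_zero_gain(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        y = np.where(rng.uniform(size=200) > 0.5, 1.0, -1.0)
        st = fit_stump(X, y)
        root = 0.5 * (200 - abs(y.sum()))
        assert st.gain / root < 0.15

    def test_duplicated_feature_ties_to_lower_index(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        st = fit_stump(X, y)
        assert st.feature == 0

    def test_constant_features_give_degenerate_stump(self):
        st = fit_stump(np.ones((10, 2)), np.array([-1.0, 1.0] * 5))
        assert st.gain == 0.0
        assert st.left == st.right

    def test_invalid_weights_rejected(self):
        X = np.zeros((4, 1))
        y = np.array([-1.0, 1.0, -1.0, 1.0])
        with pytest.raises(ValueError):
            fit_stump(X, y, np.zeros(4))


@pytest.fixture
def separable():
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(-3, 0.5, (40, 1)),
                   rng.normal(3, 0.5, (40, 1))])
    y = np.array([0] * 40 + [1] * 40)
    return X, y


class TestTraining:
    @pytest.mark.parametrize("cls", [AdaBoostStumps, LogitBoostStumps,
                                     RUSBoostStumps])
    def test_separable_data_learned_within_fifty_stumps(self, cls,
                                                        separable):
        X, y = separable
        est = cls(n_stumps=50, learning_rate=0.1, seed=0).fit(X, y)
        assert np.mean(est.predict(X) == y) == 1.0

    def test_logitboost_training_loss_never_increases(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 6))
        y = (X[:, 0] + 0.8 * rng.normal(size=100) > 0).astype(int)
        est = LogitBoostStumps(n_stumps=150, seed=0).fit(X, y)
        F = np.zeros(100)
        losses = []
        for st in est.ensemble_.stumps:
            F += st.predict(X)
            p = np.clip(1 / (1 + np.exp(-2 * F)), 1e-10, 1 - 1e-10)
            losses.append(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        assert np.all(np.diff(losses) <= 1e-12)

    def test_fixed_seed_reproduces_ensemble(self, separable):
        X, y = separable
        for cls in (AdaBoostStumps, RUSBoostStumps):
            a = cls(n_stumps=30, seed=3).fit(X, y)
            b = cls(n_stumps=30, seed=3).fit(X, y)
            assert a.ensemble_.to_json() == b.ensemble_.to_json()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            AdaBoostStumps().fit(np.zeros((5, 2)), np.zeros(5))

    def test_uniform_prior_balances_class_weight(self):
        est = AdaBoostStumps()
        y_pm = np.array([1.0] * 10 + [-1.0] * 90)
        w = est._prior_weights(y_pm)
        assert np.sum(w[y_pm > 0]) == pytest.approx(0.5)
        assert np.sum(w[y_pm < 0]) == pytest.approx(0.5)

    def test_ensemble_json_round_trip(self, separable):
        X, y = separable
        ens = train(X, y, BoostConfig(algorithm="LogitBoost", n_stumps=10))
        back = StumpEnsemble.from_json(ens.to_json())
        assert np.array_equal(back.decision_function(X),
                              ens.decision_function(X))


class TestPrediction:
    def test_empty_ensemble_scores_zero_default_class(self):
        ens = StumpEnsemble(stumps=[], algorithm="LogitBoost", n_features=2,
                            classes=(0, 1),
                            config=BoostConfig(n_stumps=1))
        scores, labels = predict_scores(ens, np.zeros((3, 2)))
        assert np.all(scores == 0)
        assert np.all(labels == 0)

    def test_one_stump_two_score_levels(self, separable):
        X, y = separable
        ens = train(X, y, BoostConfig(algorithm="AdaBoost", n_stumps=1))
        scores, _ = predict_scores(ens, X)
        assert len(np.unique(scores)) == 2

    def test_separable_scores_perfectly_ordered(self, separable):
        X, y = separable
        ens = train(X, y, BoostConfig(algorithm="LogitBoost", n_stumps=30))
        scores, _ = predict_scores(ens, X)
        assert scores[y == 1].min() > scores[y == 0].max()

    def test_dimension_mismatch_rejected(self, separable):
        X, y = separable
        ens = train(X, y, BoostConfig(n_stumps=5))
        with pytest.raises(ValueError):
            ens.decision_function(np.zeros((3, 4)))


class TestFeatureImportance:
    def test_single_informative_feature_takes_all_mass(self, separable):
        X, y = separable
        X3 = np.hstack([X, np.zeros((80, 2))])
        est = LogitBoostStumps(n_stumps=50, seed=0).fit(X3, y)
        fi = feature_importance(est)
        assert fi.normalized[0] == 1.0
        assert fi.normalized[1] == fi.normalized[2] == 0.0

    def test_random_features_rated_unimportant(self):
        # Disjoint class supports on the informative feature: the ensemble
        # separates immediately and must leave the random columns unused.
        rng = np.random.default_rng(4)
        X = np.vstack([rng.uniform(0, 1, (60, 1)),
                       rng.uniform(2, 3, (60, 1))])
        X = np.hstack([X, rng.normal(size=(120, 1)),
                       rng.uniform(size=(120, 1))])
        y = np.array([0] * 60 + [1] * 60)
        for cls in (AdaBoostStumps, LogitBoostStumps):
            est = cls(n_stumps=300, seed=0).fit(X, y)
            fi = feature_importance(est).normalized
            assert np.max(fi[1:]) < 0.1

    def test_duplicate_columns_share_single_column_importance(self,
                                                              separable):
        X, y = separable
        single = LogitBoostStumps(n_stumps=40, seed=0).fit(X, y)
        dup = LogitBoostStumps(n_stumps=40, seed=0).fit(
            np.hstack([X, X]), y)
        raw_single = feature_importance(single).raw[0]
        raw_dup = feature_importance(dup).raw
        assert raw_dup.sum() == pytest.approx(raw_single, rel=1e-9)


class TestCrossValidation:
    def test_separable_data_perfect_metrics(self, separable):
        X, y = separable
        cfg = BoostConfig(algorithm="LogitBoost", n_stumps=30)
        perf = crossval_evaluate(X, y, cfg, k=5, repeats=2, seed=0)
        assert perf.auc_mean == pytest.approx(1.0)
        assert perf.acc_mean == pytest.approx(1.0, abs=0.01)

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 4))
        y = rng.integers(0, 2, 200)
        cfg = BoostConfig(algorithm="LogitBoost", n_stumps=50)
        perf = crossval_evaluate(X, y, cfg, k=5, repeats=5, seed=1)
        assert perf.auc_mean == pytest.approx(0.5, abs=0.05)

    def test_same_seed_reproduces_summary(self, separable):
        X, y = separable
        cfg = BoostConfig(algorithm="RUSBoost", n_stumps=20)
        a = crossval_evaluate(X, y, cfg, k=5, repeats=2, seed=3)
        b = crossval_evaluate(X, y, cfg, k=5, repeats=2, seed=3)
        assert a == b

    def test_class_smaller_than_k_rejected(self):
        X = np.zeros((12, 1))
        y = np.array([0] * 9 + [1] * 3)
        with pytest.raises(ValueError, match="smaller k"):
            crossval_evaluate(X, y, BoostConfig(n_stumps=5), k=5, repeats=1)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        y = np.where(rng.uniform(size=50) > 0.5, 1.0, -1.0)
        s = rng.normal(size=50)
        assert roc_auc(y, s) == pytest.approx(roc_auc(y, np.exp(s)))
        assert roc_auc(y, s) == pytest.approx(roc_auc(y, 5 * s - 3))

    def test_rusboost_close_to_adaboost_on_balanced_classes(self):
        rng = np.random.default_rng(13)
        diffs = []
        for seed in range(20):
            X = np.vstack([rng.normal(0, 1, (40, 2)),
                           rng.normal(1.5, 1, (40, 2))])
            y = np.array([0] * 40 + [1] * 40)
            Xt = np.vstack([rng.normal(0, 1, (100, 2)),
                            rng.normal(1.5, 1, (100, 2))])
            yt = np.array([-1.0] * 100 + [1.0] * 100)
            sa = AdaBoostStumps(n_stumps=30, seed=seed).fit(X, y)
            sr = RUSBoostStumps(n_stumps=30, seed=seed).fit(X, y)
            diffs.append(roc_auc(yt, sa.decision_function(Xt))
                         - roc_auc(yt, sr.decision_function(Xt)))
        assert abs(np.mean(diffs)) < 0.05

    def test_estimator_params_round_trip(self):
        est = LogitBoostStumps(n_stumps=10)
        est.set_params(learning_rate=0.5, seed=4)
        assert est.get_params()["learning_rate"] == 0.5
        with pytest.raises(ValueError):
            est.set_params(bogus=1)
        with pytest.raises(ValueError):
            make_estimator(BoostConfig(algorithm="GradientBoost"))
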