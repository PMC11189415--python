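import numpy as np
import pandas as pd
import pytest

from anxrpt import classifier as clf
from anxrpt.classifier import (
    ClassBalanceError,
    ClassifierRun,
    RandomForest,
    evaluate,
    gini_importance,
    label_anxiety,
    permutation_null,
    proximity_mds,
    split_train_test,
)


def _two_gaussians(n=300, sep=6.0, p_pos=0.5, seed=0, n_features=5):
    rng = np.random.default_rng(seed)
    y = np.where(rng.random(n) < p_pos, "higher", "lower")
    X = rng.standard_normal((n, n_features))
    X[y == "higher", 0] += sep
    return X, y


class TestLabeling:
    def test_threshold_is_inclusive_for_higher(self):
        scores = pd.Series([34, 35, 36, 20, 80])
        labels, pct = label_anxiety(scores, 35)
        assert labels.tolist() == ["lower", "higher", "higher", "lower", "higher"]
        assert pct["higher"] == pytest.approx(60.0)

    def test_threshold_outside_range_rejected(self):
        with pytest.raises(ValueError):
            label_anxiety(pd.Series([30, 40]), 81)

    def test_degenerate_split_raises(self):
        with pytest.raises(ClassBalanceError):
            label_anxiety(pd.Series([20, 20, 20]), 35)


class TestForest:
    def test_brf_every_tree_is_class_balanced(self):
        X, y = _two_gaussians(n=200, p_pos=0.2, seed=1)
        model = RandomForest("brf", n_trees=60, vars_per_split=3, seed=2).fit(X, y)
        minority = min((y == "higher").sum(), (y == "lower").sum())
        for counts in model.bootstrap_class_counts_:
            assert counts["higher"] == counts["lower"] == minority

    def test_rf_bootstrap_draws_n_samples(self):
        X, y = _two_gaussians(n=150, seed=3)
        model = RandomForest("rf", n_trees=20, seed=4).fit(X, y)
        for counts in model.bootstrap_class_counts_:
            assert sum(counts.values()) == 150

    def test_separable_data_high_oob(self):
        X, y = _two_gaussians(n=500, sep=6.0, seed=5)
        model = RandomForest("rf", n_trees=100, seed=6).fit(X, y)
        assert model.oob_accuracy_ > 95.0

    def test_shuffled_labels_oob_near_majority_rate(self):
        rng = np.random.default_rng(7)
        X, y = _two_gaussians(n=600, sep=5.0, p_pos=0.25, seed=7)
        y_shuffled = rng.permutation(y)
        model = RandomForest("rf", n_trees=200, seed=8).fit(X, y_shuffled)
        majority_rate = 100.0 * max(np.mean(y_shuffled == "higher"),
                                    np.mean(y_shuffled == "lower"))
        assert abs(model.oob_accuracy_ - majority_rate) < 3.0

    def test_single_class_training_raises(self):
        X = np.random.default_rng(0).standard_normal((30, 3))
        with pytest.raises(ClassBalanceError):
            RandomForest("rf", 10, 3, 0).fit(X, ["lower"] * 30)

    def test_same_seed_reproduces_metrics(self):
        X, y = _two_gaussians(n=200, sep=2.0, seed=9)
        m1 = RandomForest("brf", 50, 3, 11).fit(X, y)
        m2 = RandomForest("brf", 50, 3, 11).fit(X, y)
        assert m1.oob_accuracy_ == m2.oob_accuracy_
        assert np.array_equal(m1.vote_fractions(X), m2.vote_fractions(X))


class _StubModel:
    """Minimal duck-typed forest for metric-formula checks."""

    classes_ = np.array(["higher", "lower"])

    def __init__(self, frac_higher):
        self._f = np.asarray(frac_higher, dtype=float)

    def vote_fractions(self, X):
        return np.column_stack([self._f, 1.0 - self._f])


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array(["higher"] * 3 + ["lower"] * 5)
        model = _StubModel([1, 1, 1, 0, 0, 0, 0, 0])
        rep = evaluate(model, np.zeros((8, 1)), y)
        assert rep.accuracy == 100.0
        assert rep.sensitivity == 100.0 and rep.specificity == 100.0
        assert rep.auc_roc == 1.0 and rep.balanced_accuracy == 100.0

    def test_all_predicted_lower_on_imbalanced_set(self):
        y = np.array(["higher"] * 12 + ["lower"] * 88)
        model = _StubModel([0.2] * 100)
        rep = evaluate(model, np.zeros((100, 1)), y)
        assert rep.sensitivity == 0.0 and rep.specificity == 100.0
        assert rep.balanced_accuracy == 50.0

    def test_missing_class_reports_none(self):
        y = np.array(["lower"] * 10)
        rep = evaluate(_StubModel([0.1] * 10), np.zeros((10, 1)), y)
        assert rep.sensitivity is None and rep.auc_roc is None

    def test_random_votes_auc_near_half(self):
        rng = np.random.default_rng(12)
        aucs = []
        for _ in range(100):
            y = np.where(rng.random(200) < 0.5, "higher", "lower")
            rep = evaluate(_StubModel(rng.random(200)), np.zeros((200, 1)), y)
            aucs.append(rep.auc_roc)
        assert 0.48 < np.mean(aucs) < 0.52


class TestPermutationNull:
    def test_small_null_auc_near_chance_and_reproducible(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.standard_normal((200, 8)))
        scores = pd.Series(rng.integers(20, 81, 200).astype(float))
        run = ClassifierRun(threshold=45, mode="brf", seed=3, n_trees=40)
        rep1 = permutation_null(X, scores, run, n_iter=8)
        rep2 = permutation_null(X, scores, run, n_iter=8)
        assert 0.38 < rep1.auc_roc < 0.62
        assert rep1.auc_roc == rep2.auc_roc

    def test_invalid_iterations(self):
        with pytest.raises(ValueError):
            permutation_null(pd.DataFrame(np.zeros((10, 2))),
                             pd.Series([30.0] * 5 + [50.0] * 5),
                             ClassifierRun(), n_iter=0)


class TestImportance:
    def test_shares_sum_to_one(self):
        X, y = _two_gaussians(n=200, sep=2.0, seed=14, n_features=6)
        model = RandomForest("rf", 50, 3, 15).fit(X, y)
        rep = gini_importance(model, [f"f{i}" for i in range(6)],
                              judgment_vars=["f0"])
        assert rep.shares.sum() == pytest.approx(1.0, abs=1e-9)
        assert sum(rep.group_sums.values()) == pytest.approx(1.0, abs=1e-9)

    def test_informative_feature_dominates(self):
        X, y = _two_gaussians(n=300, sep=3.0, seed=16, n_features=10)
        model = RandomForest("rf", 80, 3, 17).fit(X, y)
        rep = gini_importance(model, [f"f{i}" for i in range(10)],
                              judgment_vars=["f0"])
        assert rep.shares.idxmax() == "f0"
        assert rep.group_sums["judgment"] == pytest.approx(rep.shares["f0"])


class TestProximity:
    def test_matrix_properties_and_duplicates(self):
        X, y = _two_gaussians(n=60, sep=4.0, seed=18)
        X[1] = X[0]  # plant a duplicate pair
        model = RandomForest("rf", 40, 3, 19).fit(X, y)
        P = model.proximity(X)
        assert np.allclose(P, P.T)
        assert np.allclose(np.diag(P), 1.0)
        assert P[0, 1] == pytest.approx(1.0)
        assert P.min() >= 0.0 and P.max() <= 1.0

    def test_mds_separates_planted_clusters(self):
        X, y = _two_gaussians(n=80, sep=8.0, seed=20)
        model = RandomForest("rf", 60, 3, 21).fit(X, y)
        coords = proximity_mds(model, X)
        hi, lo = coords[y == "higher"], coords[y == "lower"]
        within = (np.linalg.norm(hi - hi.mean(0), axis=1).mean()
                  + np.linalg.norm(lo - lo.mean(0), axis=1).mean()) / 2
        between = np.linalg.norm(hi.mean(0) - lo.mean(0))
        assert between > within

    def test_too_few_samples(self):
        X, y = _two_gaussians(n=30, seed=22)
        model = RandomForest("rf", 10, 3, 23).fit(X, y)
        with pytest.raises(ValueError):
            proximity_mds(model, X[:2])


class TestSplit:
    def test_split_fractions_and_disjointness(self):
        idx = pd.Index([f"p{i}" for i in range(100)])
        train, test = split_train_test(idx, 0.7, 5)
        assert len(train) == 70 and len(test) == 30
        assert not set(train) & set(test)

    def test_brf_beats_rf_sensitivity_under_imbalance(self, analysis_cohort):
        """With ~10% positive class the balanced forest finds more positives."""
        from anxrpt.pipeline_io import predictor_columns

        feats = analysis_cohort[predictor_columns()]
        scores = analysis_cohort["stai_s"]
        thr = float(scores.quantile(0.9))
        sens = {}
        for mode in ("rf", "brf"):
            run = ClassifierRun(threshold=thr, mode=mode, seed=29, n_trees=150)
            _, rep, _, _ = clf.classify_cohort(feats, scores, run)
            sens[mode] = rep.sensitivity
        assert sens["brf"] > sens["rf"]
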