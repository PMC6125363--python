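"""Split, filter, enumeration, SMOTE, metrics, repeated CV, ranking."""

import numpy as np
import pandas as pd
import pytest

import prognosig as pg
from prognosig import srm
from prognosig.errors import (
    ParameterError,
    SchemaError,
    SmoteError,
    StratificationError,
    UndefinedAUCError,
)

from _oracles import auc_pairwise, brute_force_u
from conftest import PLANTED_TRIO, feature_table_from, planted_effects


def _labels(n0: int, nplus: int) -> np.ndarray:
    return np.array(["N0"] * n0 + ["N+"] * nplus)


class TestStratifiedHoldout:
    def test_per_class_rounding_on_study_cohort(self):
        train, test = pg.stratified_holdout(_labels(14, 26), 0.2, seed=0)
        y = _labels(14, 26)
        assert (y[test] == "N0").sum() == 3  # round(0.2 * 14)
        assert (y[test] == "N+").sum() == 5  # round(0.2 * 26)
        assert len(np.intersect1d(train, test)) == 0
        assert len(train) + len(test) == 40

    def test_balanced_half_split(self):
        train, test = pg.stratified_holdout(_labels(10, 10), 0.5, seed=1)
        y = _labels(10, 10)
        assert (y[test] == "N0").sum() == 5
        assert (y[test] == "N+").sum() == 5

    def test_deterministic_given_seed(self):
        a = pg.stratified_holdout(_labels(14, 26), 0.2, seed=3)
        b = pg.stratified_holdout(_labels(14, 26), 0.2, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_tiny_class_rejected(self):
        with pytest.raises(StratificationError):
            pg.stratified_holdout(_labels(1, 10), 0.2, seed=0)


class TestMwFilter:
    def test_separated_feature_retained(self):
        y = _labels(5, 5)
        X = pd.DataFrame(
            {"sep": np.r_[np.zeros(5), np.ones(5)], "flat": np.ones(10)}
        )
        assert pg.mw_filter(X, y, alpha=0.10) == ["sep"]

    def test_null_retention_tracks_alpha(self):
        """Permuted labels retain roughly alpha of features."""
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 500)), columns=[f"f{i}" for i in range(500)])
        y = rng.permutation(_labels(14, 26))
        rate = len(pg.mw_filter(X, y, alpha=0.10)) / 500
        assert 0.05 < rate < 0.15


class TestEnumerateSignatures:
    @pytest.mark.parametrize("n,count", [(1, 1), (6, 63), (10, 1023)])
    def test_counts(self, n, count):
        sigs = pg.enumerate_signatures([f"f{i}" for i in range(n)])
        assert len(sigs) == count
        assert len(set(sigs)) == count

    def test_deterministic_order_by_size_then_lex(self):
        sigs = pg.enumerate_signatures(["b", "a", "c"])
        assert sigs == [
            ("a",), ("b",), ("c",),
            ("a", "b"), ("a", "c"), ("b", "c"),
            ("a", "b", "c"),
        ]

    def test_refuses_combinatorial_explosion(self):
        with pytest.raises(ParameterError):
            pg.enumerate_signatures([f"f{i}" for i in range(21)])


class TestSmote:
    def test_balances_study_imbalance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = _labels(14, 26)
        X_aug, y_aug, mask = pg.smote(X, y, k=5, seed=2)
        assert np.bincount(y_aug).tolist() == [26, 26]
        assert mask.sum() == 12
        assert np.array_equal(X_aug[:40], X)  # originals untouched, first

    def test_synthetic_points_lie_on_minority_segments(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        y = _labels(10, 20)
        X_aug, y_aug, mask = pg.smote(X, y, k=3, seed=4)
        minority = X[:10]
        for p in X_aug[mask]:
            on_segment = False
            for i in range(10):
                for j in range(10):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    denom = float(d @ d)
                    if denom == 0:
                        continue
                    u = float((p - minority[i]) @ d) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(
                        minority[i] + u * d, p, atol=1e-9
                    ):
                        on_segment = True
            assert on_segment

    def test_one_synthetic_between_two_points(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 5.0], [6.0, 6.0], [7.0, 7.0]])
        y = np.array([0, 0, 1, 1, 1])
        X_aug, _y, mask = pg.smote(X, y, k=1, seed=5)
        (p,) = X_aug[mask]
        assert 0.0 <= p[0] <= 1.0 and p[0] == pytest.approx(p[1])

    def test_already_balanced_unchanged(self):
        X = np.arange(8.0).reshape(4, 2)
        y = np.array([0, 0, 1, 1])
        X_aug, y_aug, mask = pg.smote(X, y, seed=0)
        assert np.array_equal(X_aug, X) and mask.sum() == 0

    def test_k_reduced_with_warning_and_singleton_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.array([0] * 3 + [1] * 7)
        with pytest.warns(UserWarning, match="reduced"):
            pg.smote(X, y, k=5, seed=1)
        y_bad = np.array([0] + [1] * 9)
        with pytest.raises(SmoteError):
            pg.smote(X, y_bad, k=5, seed=1)


class TestRocAuc:
    def test_perfect_and_all_tied(self):
        y = _labels(3, 3)
        assert pg.roc_auc(y, [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]) == pytest.approx(1.0)
        assert pg.roc_auc(y, [0.5] * 6) == pytest.approx(0.5)

    def test_matches_pairwise_oracle_and_u_statistic(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n0, n1 = rng.integers(2, 12, size=2)
            y = np.r_[np.zeros(n0, int), np.ones(n1, int)]
            s = np.round(rng.normal(size=n0 + n1), 1)  # coarse: force ties
            auc = pg.roc_auc(y, s)
            assert auc == pytest.approx(auc_pairwise(y, s))
            assert auc == pytest.approx(brute_force_u(s[y == 1], s[y == 0]) / (n0 * n1))

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedAUCError):
            pg.roc_auc(np.ones(4, int), [0.1, 0.2, 0.3, 0.4])


class TestBinaryMetrics:
    def test_perfect_classifier(self):
        y = _labels(2, 3)
        m = pg.binary_metrics(y, [0.1, 0.2, 0.9, 0.8, 0.7])
        assert all(m[k] == 1.0 for k in ("accuracy", "f1", "sensitivity", "specificity", "precision"))

    def test_all_positive_predictor_on_study_prevalence(self):
        y = _labels(14, 26)
        m = pg.binary_metrics(y, np.ones(40))
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0
        assert m["accuracy"] == pytest.approx(26 / 40)

    def test_no_predicted_positives_flagged(self):
        m = pg.binary_metrics(_labels(2, 2), np.zeros(4))
        assert m["precision"] == 0.0 and not m["precision_defined"]

    def test_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        s = rng.random(50)
        m = pg.binary_metrics(y, s)
        pred = (s >= 0.5).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        assert m["accuracy"] == pytest.approx((pred == y).mean())
        assert m["precision"] == pytest.approx(tp / (tp + fp))
        assert m["f1"] == pytest.approx(2 * tp / (2 * tp + fp + fn))


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(8)
    y = _labels(14, 26)
    X = pd.DataFrame(
        {
            "signal": np.r_[rng.normal(0, 0.2, 14), rng.normal(3, 0.2, 26)],
            "noise": rng.normal(size=40),
        }
    )
    return X, y


class TestRepeatedCv:
    def test_separable_signature_saturates_auc(self, separable):
        X, y = separable
        cfg = pg.CVConfig(repetitions=5, folds=10, base_seed=0)
        res = pg.repeated_cv(X, y, ("signal",), pg.make_classifiers()["naive_bayes"], cfg)
        assert res.means["roc_auc"] >= 0.99
        assert res.metrics.shape == (5, 6)

    def test_deterministic_given_config(self, separable):
        X, y = separable
        cfg = pg.CVConfig(repetitions=3, folds=5, base_seed=4, balance="smote")
        clf = pg.make_classifiers()["naive_bayes"]
        a = pg.repeated_cv(X, y, ("signal", "noise"), clf, cfg)
        b = pg.repeated_cv(X, y, ("signal", "noise"), clf, cfg)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)

    def test_folds_reduced_for_tiny_class(self, separable):
        X, y = separable
        cfg = pg.CVConfig(repetitions=2, folds=10, base_seed=0)
        with pytest.warns(UserWarning, match="folds reduced"):
            pg.repeated_cv(
                X.iloc[:20], y[:20][::-1], ("signal",), pg.make_classifiers()["naive_bayes"], cfg
            )

    def test_missing_feature_rejected(self, separable):
        X, y = separable
        cfg = pg.CVConfig(repetitions=1, folds=5, base_seed=0)
        with pytest.raises(SchemaError):
            pg.repeated_cv(X, y, ("absent",), pg.make_classifiers()["naive_bayes"], cfg)

    def test_smote_never_hurts_minority_sensitivity_on_average(self):
        """Balanced training folds recover minority (N0) recall on average."""
        eff = planted_effects(-0.7)
        clf = pg.make_classifiers()["naive_bayes"]
        diffs = []
        for seed in range(10):
            cohort = pg.gen_srm_cohort(
                pg.SrmSimConfig(seed=500 + seed, group_effect_log2=eff, noise_cv=0.3)
            )
            X, y = feature_table_from(cohort)
            plain = pg.repeated_cv(
                X, y, PLANTED_TRIO, clf, pg.CVConfig(repetitions=5, folds=10, base_seed=seed)
            ).means["specificity"]
            balanced = pg.repeated_cv(
                X, y, PLANTED_TRIO, clf,
                pg.CVConfig(repetitions=5, folds=10, balance="smote", base_seed=seed),
            ).means["specificity"]
            diffs.append(balanced - plain)
        assert np.mean(diffs) >= 0.0


class TestRankSignatures:
    @staticmethod
    def _result(sig, acc, auc):
        metrics = pd.DataFrame(
            {
                "accuracy": [acc],
                "roc_auc": [auc],
                "f1": [0.5],
                "sensitivity": [0.5],
                "specificity": [0.5],
                "precision": [0.5],
            }
        )
        return pg.SignatureResult(
            signature=tuple(sig), metrics=metrics, classifier="test", config=pg.CVConfig()
        )

    def test_equal_auc_prefers_smaller_signature(self):
        two = self._result(("a", "b"), 0.8, 0.9)
        three = self._result(("a", "b", "c"), 0.8, 0.9)
        assert pg.rank_signatures([three, two])[0] is two

    def test_accuracy_floor_excludes(self):
        low = self._result(("a",), 0.73, 0.99)
        high = self._result(("b",), 0.74, 0.70)
        ranked = pg.rank_signatures([low, high], accuracy_floor=0.74)
        assert [r.signature for r in ranked] == [("b",)]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(9)
        results = [
            self._result(
                tuple(f"f{j}" for j in range(rng.integers(1, 4))),
                rng.uniform(0.5, 1),
                round(rng.uniform(0.5, 1), 2),
            )
            for _ in range(30)
        ]
        ranked = pg.rank_signatures(results)
        expected = sorted(
            results, key=lambda r: (-r.means["roc_auc"], len(r.signature), r.signature)
        )
        assert [r.signature for r in ranked] == [r.signature for r in expected]


class TestClassifierSweep:
    def test_strong_classifier_outranks_random_guesser(self):
        rng = np.random.default_rng(10)
        y = _labels(10, 10)
        X = pd.DataFrame({"f": np.r_[rng.normal(0, 0.3, 10), rng.normal(3, 0.3, 10)]})

        class _Guess:
            classes_ = np.array([0, 1])
            def __init__(self, seed):
                self.rng = np.random.default_rng(seed)
            def fit(self, X, y):
                return self
            def predict_proba(self, X):
                p = self.rng.random(len(X))
                return np.c_[1 - p, p]

        specs = [
            pg.ClassifierSpec("coin_flip", _Guess),
            pg.make_classifiers()["logistic_regression"],
        ]
        cfg = pg.CVConfig(repetitions=3, folds=5, base_seed=0)
        report = pg.classifier_sweep(X, y, [("f",)], specs, cfg)
        assert report.loc[0, "classifier"] == "logistic_regression"


class TestHoldoutValidate:
    def test_overlapping_patients_rejected(self, planted_features):
        X, y = planted_features
        cfg = pg.CVConfig(base_seed=0)
        with pytest.raises(ParameterError):
            pg.holdout_validate(
                X, y, X.iloc[:5], y[:5], PLANTED_TRIO, pg.make_classifiers()["naive_bayes"], cfg
            )

    def test_separable_planted_data_validates(self, planted_features):
        X, y = planted_features
        cfg = pg.CVConfig(base_seed=1)
        train, test = pg.stratified_holdout(y, 0.2, seed=1)
        res = pg.holdout_validate(
            X.iloc[train], y[train], X.iloc[test], y[test],
            PLANTED_TRIO, pg.make_classifiers()["naive_bayes"], cfg,
        )
        assert res["roc_auc"] >= 0.8

    def test_missing_test_feature_rejected(self, planted_features):
        X, y = planted_features
        train, test = pg.stratified_holdout(y, 0.2, seed=1)
        with pytest.raises(SchemaError):
            pg.holdout_validate(
                X.iloc[train], y[train], X.iloc[test].drop(columns=[PLANTED_TRIO[0]]),
                y[test], PLANTED_TRIO, pg.make_classifiers()["naive_bayes"],
                pg.CVConfig(base_seed=0),
            )


def test_signature_search_end_to_end(planted_features):
    """Filter -> enumerate -> CV -> rank -> holdout on the planted cohort."""
    X, y = planted_features
    cfg = pg.CVConfig(repetitions=5, folds=10, base_seed=11)
    report = pg.signature_search(X, y, cfg, clf=pg.make_classifiers()["naive_bayes"])
    assert set(report.retained_features) >= set(PLANTED_TRIO)
    assert len(report.results) == 2 ** len(report.retained_features) - 1
    assert set(report.best.signature) <= set(report.retained_features)
    assert report.best.means["roc_auc"] > 0.8
    # the untouched test set stayed out of training
    assert len(np.intersect1d(report.train_index, report.test_index)) == 0
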