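import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from cardiotrait import (
    ALL_FEATURES,
    bin_scores,
    clopper_pearson,
    evaluate,
    feature_importance,
    run_trait_classification,
    select_features,
    stratified_split,
    train_rf,
)
from cardiotrait.exceptions import (
    DegenerateLabelsError,
    NotFittedError,
    ParameterError,
)
from cardiotrait.features import CLINICAL_FEATURES


class TestBinScores:
    @pytest.mark.parametrize("score,expected", [
        (1.00, 1), (1.50, 1), (1.51, 2), (2.50, 2), (2.51, 3),
        (3.50, 3), (3.505, 4), (4.50, 4), (4.51, 5), (5.00, 5),
    ])
    def test_boundaries(self, score, expected):
        assert bin_scores(score) == expected

    def test_vectorised(self):
        out = bin_scores([1.2, 2.0, 3.0, 4.0, 4.9])
        np.testing.assert_array_equal(out, [1, 2, 3, 4, 5])

    @pytest.mark.parametrize("bad", [0.9, 5.1, np.nan])
    def test_domain_error(self, bad):
        with pytest.raises(ParameterError):
            bin_scores(bad)


class TestSelectFeatures:
    @pytest.fixture()
    def table(self, rng):
        return pd.DataFrame(rng.normal(size=(6, 62)), columns=list(ALL_FEATURES))

    def test_column_counts(self, table):
        assert select_features(table, "all62").shape[1] == 62
        assert select_features(table, "no_hrv_index").shape[1] == 61
        assert select_features(table, "clinical34").shape[1] == 34

    def test_hrv_index_excluded(self, table):
        assert "HRV_index" not in select_features(table, "no_hrv_index").columns
        assert "HRV_index" not in select_features(table, "clinical34").columns

    def test_clinical_set_excludes_peak_distances_and_pairs(self, table):
        cols = set(select_features(table, "clinical34").columns)
        assert cols == set(CLINICAL_FEATURES)
        assert not cols & {"PR_min", "ST_max", "QRS_sd", "PRa_mean", "QSa_sd"}
        assert {"Ek_mean", "Ek_sd"} <= cols

    def test_unknown_mode(self, table):
        with pytest.raises(ParameterError):
            select_features(table, "everything")


class TestStratifiedSplit:
    def _data(self, rng, counts):
        labels = np.repeat(np.arange(1, len(counts) + 1), counts)
        idx = pd.Index([f"S{i}" for i in range(len(labels))])
        X = pd.DataFrame(rng.normal(size=(len(labels), 3)), index=idx)
        return X, pd.Series(labels, index=idx)

    def test_disjoint_and_covering(self, rng):
        X, y = self._data(rng, [20, 30, 20])
        tr_X, tr_y, te_X, te_y = stratified_split(X, y, seed=0)
        assert set(tr_X.index).isdisjoint(te_X.index)
        assert set(tr_X.index) | set(te_X.index) == set(X.index)

    def test_per_class_share(self, rng):
        X, y = self._data(rng, [20, 30, 20])
        tr_X, tr_y, te_X, te_y = stratified_split(X, y, seed=1)
        for cat, n_c in [(1, 20), (2, 30), (3, 20)]:
            n_train = (tr_y == cat).sum()
            assert abs(n_train - 0.75 * n_c) <= 1

    def test_70_subjects_test_size(self, rng):
        X, y = self._data(rng, [14, 14, 14, 14, 14])
        *_, te_y = stratified_split(X, y, seed=2)
        assert len(te_y) in {16, 17, 18}

    def test_deterministic(self, rng):
        X, y = self._data(rng, [10, 12])
        a = stratified_split(X, y, seed=5)
        b = stratified_split(X, y, seed=5)
        assert list(a[0].index) == list(b[0].index)
        assert list(a[2].index) == list(b[2].index)

    def test_singleton_category_goes_to_train(self, rng):
        X, y = self._data(rng, [1, 10])
        tr_X, tr_y, te_X, te_y = stratified_split(X, y, seed=0)
        assert (tr_y == 1).sum() == 1
        assert (te_y == 1).sum() == 0


class TestClopperPearson:
    def test_matches_brute_force_binomial_inversion(self):
        """CP bounds agree with direct bisection on the binomial CDF."""
        def invert(k, n, target, upper):
            lo, hi = 0.0, 1.0
            for _ in range(200):
                mid = (lo + hi) / 2
                if upper:
                    tail = binom.cdf(k, n, mid)      # P(X <= k)
                    lo, hi = (lo, mid) if tail < target else (mid, hi)
                else:
                    tail = binom.sf(k - 1, n, mid)   # P(X >= k)
                    lo, hi = (mid, hi) if tail < target else (lo, mid)
            return (lo + hi) / 2

        for n in range(1, 31):
            for k in range(n + 1):
                lo, hi = clopper_pearson(k, n)
                expect_lo = 0.0 if k == 0 else invert(k, n, 0.025, upper=False)
                expect_hi = 1.0 if k == n else invert(k, n, 0.025, upper=True)
                assert lo == pytest.approx(expect_lo, abs=1e-9)
                assert hi == pytest.approx(expect_hi, abs=1e-9)

    @pytest.mark.parametrize("k,n,acc,lo,hi", [
        (13, 16, 81.3, 54.4, 96.0),
        (12, 16, 75.0, 47.6, 92.7),
        (11, 15, 73.3, 44.9, 92.2),
        (7, 16, 43.8, 19.8, 70.1),
        (5, 16, 31.3, 11.0, 58.7),
        (8, 17, 47.1, 23.0, 72.2),
        (12, 17, 70.6, 44.0, 89.7),
    ])
    def test_published_interval_pairs(self, k, n, acc, lo, hi):
        """The exact binomial CI reproduces the reference printed intervals."""
        got_lo, got_hi = clopper_pearson(k, n)
        assert round(100 * k / n + 1e-9, 1) == acc
        assert round(100 * got_lo, 1) == lo
        assert round(100 * got_hi, 1) == hi

    def test_zero_successes_boundary(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi < 0.35

    def test_invalid_counts(self):
        with pytest.raises(ParameterError):
            clopper_pearson(5, 4)


class _FixedModel:
    """Predicts a pre-recorded label sequence (for CI arithmetic tests)."""

    def __init__(self, outputs):
        self.outputs = np.asarray(outputs)

    def predict(self, X):
        return self.outputs[:len(X)]


class TestEvaluate:
    def test_13_of_16(self):
        y = np.array([1] * 16)
        pred = np.array([1] * 13 + [2] * 3)
        acc, (lo, hi) = evaluate(_FixedModel(pred), np.zeros((16, 2)), y)
        assert acc == 81.3
        assert (lo, hi) == (54.4, 96.0)

    def test_all_wrong(self):
        y = np.array([1] * 10)
        acc, (lo, hi) = evaluate(_FixedModel(np.full(10, 2)), np.zeros((10, 2)), y)
        assert acc == 0.0
        assert lo == 0.0

    def test_empty_test_set(self):
        with pytest.raises(ParameterError):
            evaluate(_FixedModel([1]), np.zeros((0, 2)), np.array([]))


def _planted_table(rng, n=80, p=10, rho_feature=0):
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"f{i}" for i in range(p)],
                     index=[f"S{i}" for i in range(n)])
    score = np.clip(3.0 + 0.8 * X.iloc[:, rho_feature] + 0.3 * rng.normal(size=n),
                    1.0, 5.0)
    y = pd.Series(bin_scores(score), index=X.index)
    return X, y


class TestTrainRf:
    def test_deterministic(self, rng):
        X, y = _planted_table(rng)
        a = train_rf(X, y, cv_folds=3, ntree_grid=(50, 100), seed=4)
        b = train_rf(X, y, cv_folds=3, ntree_grid=(50, 100), seed=4)
        assert a[1:] == b[1:]

    def test_single_class_rejected(self, rng):
        X, _ = _planted_table(rng)
        with pytest.raises(DegenerateLabelsError):
            train_rf(X, pd.Series(2, index=X.index), ntree_grid=(20,))

    def test_recovers_planted_signal(self, rng):
        X, y = _planted_table(rng, n=120)
        model, cv_acc, ntree, mtry = train_rf(
            X, y, cv_folds=5, ntree_grid=(200,), seed=0)
        majority = 100 * y.value_counts().max() / len(y)
        assert cv_acc > majority
        ranked = feature_importance(model, X.columns)
        assert ranked[0][0] == "f0"


class TestFeatureImportance:
    def test_normalised_to_100(self, rng):
        X, y = _planted_table(rng)
        model, *_ = train_rf(X, y, cv_folds=3, ntree_grid=(50,), seed=0)
        ranked = feature_importance(model, X.columns)
        values = [v for _, v in ranked]
        assert values[0] == pytest.approx(100.0)
        assert all(0 <= v <= 100 for v in values)
        assert values == sorted(values, reverse=True)

    def test_untrained_model_rejected(self):
        with pytest.raises(NotFittedError):
            feature_importance(object(), ["a"])


class TestRunTraitClassification:
    def test_report_invariants(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 62)), columns=list(ALL_FEATURES),
                         index=[f"S{i}" for i in range(60)])
        raw = np.clip(3.3 + 0.9 * X["RTa_mean"].to_numpy()
                      + 0.3 * rng.normal(size=60), 1, 5)
        traits = pd.DataFrame({"Extraversion": raw}, index=X.index)
        report = run_trait_classification(
            X, traits, "Extraversion", feature_set="all62", seed=0,
            cv_folds=5, ntree_grid=(100,), mtry_grid=(8,))
        assert 0 <= report.cv_mean_accuracy <= 100
        assert report.ci95[0] <= report.test_accuracy <= report.ci95[1]
        assert report.importances[0][1] == pytest.approx(100.0)
        assert report.n_test + report.n_train == 60

    def test_missing_trait_scores_excluded(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 62)), columns=list(ALL_FEATURES),
                         index=[f"S{i}" for i in range(30)])
        raw = rng.uniform(1.4, 4.8, size=30)
        raw[:5] = np.nan
        traits = pd.DataFrame({"Openness": raw}, index=X.index)
        report = run_trait_classification(
            X, traits, "Openness", feature_set="clinical34", seed=1,
            cv_folds=3, ntree_grid=(50,), mtry_grid=(5,))
        assert report.n_test + report.n_train == 25

    def test_unknown_trait(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 62)), columns=list(ALL_FEATURES))
        with pytest.raises(ParameterError):
            run_trait_classification(X, pd.DataFrame(index=X.index), "Grit")
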