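"""Modelling harness: normalisation, ADASYN, trees, CV, metrics, comparison."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from xerpred.model import (
    AdasynSettings,
    ModelSpec,
    TreeHyper,
    adasyn,
    auc_rank,
    compare_models,
    compute_metrics,
    model_catalog,
    run_catalog,
    stratified_cv,
    train_tree,
    zscore_fit_apply,
)
from xerpred.synthetic import CohortConfig, generate_cohort


class TestZscore:
    def test_train_standardised_to_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(3, 2, 50), "b": rng.uniform(0, 9, 50)})
        tz, ez, dropped = zscore_fit_apply(df, df)
        assert not dropped
        np.testing.assert_allclose(tz.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(tz.std(ddof=0), 1.0, atol=1e-12)
        pd.testing.assert_frame_equal(tz, ez)

    def test_constant_feature_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            tz, _, dropped = zscore_fit_apply(df, df)
        assert dropped == ["c"] and list(tz.columns) == ["a"]

    def test_affine_invariance_of_standardised_output(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=30)})
        shifted = df * 7.0 + 11.0
        tz1, _, _ = zscore_fit_apply(df, df)
        tz2, _, _ = zscore_fit_apply(shifted, shifted)
        np.testing.assert_allclose(tz1.to_numpy(), tz2.to_numpy(), atol=1e-10)

    def test_statistics_from_train_only(self):
        train = pd.DataFrame({"a": [0.0, 2.0]})
        ev = pd.DataFrame({"a": [4.0]})
        _, ez, _ = zscore_fit_apply(train, ev)
        assert ez["a"].iloc[0] == pytest.approx(3.0)  # (4-1)/1


class TestAdasyn:
    def _clusters(self, n_maj=40, n_min=20, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (n_maj, 2)), rng.normal(2.5, 1, (n_min, 2))])
        y = np.array([0] * n_maj + [1] * n_min)
        return X, y

    def test_balanced_input_unchanged(self):
        X, y = self._clusters(20, 20)
        Xa, ya = adasyn(X, y, rng=0)
        assert len(ya) == 40

    def test_exact_synthetic_count(self):
        X, y = self._clusters(40, 20)
        Xa, ya = adasyn(X, y, target_ratio=1.0, rng=0)
        assert int(np.sum(ya == 1)) == 40
        assert len(ya) - len(y) == 20

    def test_synthetic_points_on_minority_segments(self):
        X, y = self._clusters(60, 25, seed=3)
        Xa, ya = adasyn(X, y, rng=7)
        Xmin = X[y == 1]
        for xs in Xa[len(X):]:
            # distance to the closest minority-minority segment is ~0
            d_best = np.inf
            for i in range(len(Xmin)):
                for j in range(len(Xmin)):
                    if i == j:
                        continue
                    u = Xmin[j] - Xmin[i]
                    t = np.clip(np.dot(xs - Xmin[i], u) / (u @ u), 0, 1)
                    d_best = min(d_best, np.linalg.norm(xs - (Xmin[i] + t * u)))
            assert d_best < 1e-9

    def test_minority_too_small_errors(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.array([0] * 9 + [1])
        with pytest.raises(ValueError, match="skip"):
            adasyn(X, y)

    def test_deterministic_under_seed(self):
        X, y = self._clusters()
        X1, _ = adasyn(X, y, rng=5)
        X2, _ = adasyn(X, y, rng=5)
        np.testing.assert_array_equal(X1, X2)


def _gini(labels):
    if len(labels) == 0:
        return 0.0
    p = np.mean(labels)
    return 2 * p * (1 - p)


def brute_force_best_split_impurity(X, y):
    """Exhaustive axis-aligned split search minimising weighted Gini."""
    best = _gini(y)
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        for thr in (vals[:-1] + vals[1:]) / 2:
            left, right = y[X[:, j] <= thr], y[X[:, j] > thr]
            imp = (len(left) * _gini(left) + len(right) * _gini(right)) / len(y)
            best = min(best, imp)
    return best


class TestTree:
    def test_separable_1d_perfect_training_accuracy(self):
        X = np.linspace(0, 1, 20).reshape(-1, 1)
        y = (X.ravel() > 0.5).astype(int)
        tree = train_tree(X, y, TreeHyper(max_depth=1, min_leaf=1))
        assert np.mean(tree.predict(X) == y) == 1.0

    def test_xor_needs_depth_two(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 5, dtype=float)
        y = np.array([0, 1, 1, 0] * 5)
        deep = train_tree(X, y, TreeHyper(max_depth=2, min_leaf=1))
        shallow = train_tree(X, y, TreeHyper(max_depth=1, min_leaf=1))
        assert np.mean(deep.predict(X) == y) == 1.0
        assert np.mean(shallow.predict(X) == y) <= 0.75

    def test_depth_one_matches_exhaustive_split_oracle(self):
        """The fitted stump's split achieves the exhaustive-search minimum
        of the weighted Gini impurity."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            X = rng.normal(size=(18, 2))
            y = rng.integers(0, 2, 18)
            if np.unique(y).size < 2:
                continue
            tree = train_tree(X, y, TreeHyper(max_depth=1, min_leaf=1))
            feat = tree.tree_.feature[0]
            if feat < 0:  # no impurity-reducing split exists
                assert brute_force_best_split_impurity(X, y) == pytest.approx(_gini(y))
                continue
            thr = tree.tree_.threshold[0]
            left, right = y[X[:, feat] <= thr], y[X[:, feat] > thr]
            achieved = (len(left) * _gini(left) + len(right) * _gini(right)) / len(y)
            assert achieved == pytest.approx(
                brute_force_best_split_impurity(X, y), abs=1e-12
            )

    def test_single_class_constant_model(self):
        X = np.zeros((5, 1))
        with pytest.warns(UserWarning, match="single-class"):
            model = train_tree(X, np.ones(5, dtype=int))
        assert np.all(model.predict_proba_pos(X) == 1.0)


class TestAucAndMetrics:
    def test_rank_auc_equals_sklearn_on_random_scores(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = rng.integers(10, 200)
            y = rng.integers(0, 2, n)
            if np.unique(y).size < 2:
                continue
            s = rng.normal(size=n)
            assert auc_rank(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-10)

    def test_perfect_scores_saturate_metrics(self):
        preds = pd.DataFrame(
            {
                "patient_id": range(20),
                "fold": 0,
                "score": [0.9] * 10 + [0.1] * 10,
                "predicted": [1] * 10 + [0] * 10,
                "true": [1] * 10 + [0] * 10,
            }
        )
        rep = compute_metrics(preds, n_boot=0)
        assert rep.auc == 1.0
        assert rep.accuracy == rep.sensitivity == rep.specificity == 100.0
        assert rep.ppv == rep.npv == 100.0

    def test_wilson_ci_contains_point_estimate(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 100)
        s = rng.uniform(size=100)
        preds = pd.DataFrame(
            {"patient_id": range(100), "fold": 0, "score": s,
             "predicted": (s >= 0.5).astype(int), "true": y}
        )
        rep = compute_metrics(preds, n_boot=200, seed=1)
        lo, hi = rep.ci_95["accuracy"]
        assert lo <= rep.accuracy <= hi
        assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]

    def test_single_class_truth_errors(self):
        preds = pd.DataFrame(
            {"patient_id": range(4), "fold": 0, "score": [0.1] * 4,
             "predicted": [0] * 4, "true": [0] * 4}
        )
        with pytest.raises(ValueError, match="single class"):
            compute_metrics(preds, n_boot=0)


@pytest.fixture(scope="module")
def cohort():
    table, _ = generate_cohort(CohortConfig(n_patients=150, seed=21))
    return table.set_index("patient_id")


class TestStratifiedCV:
    def test_deterministic_under_seed(self, cohort):
        spec = model_catalog()[8]
        r1 = stratified_cv(cohort, spec, seed=3, n_boot=0)
        r2 = stratified_cv(cohort, spec, seed=3, n_boot=0)
        pd.testing.assert_frame_equal(r1.predictions, r2.predictions)
        assert r1.auc == r2.auc

    def test_separable_label_is_learned(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"V65_pct": rng.uniform(0, 20, 100)})
        df["XQ_Int_mid"] = rng.uniform(0, 100, 100)
        df["XER_12"] = (df["V65_pct"] > 10).astype(int)
        rep = stratified_cv(df, model_catalog()[8], seed=0, n_boot=0)
        assert rep.auc > 0.95
        assert rep.accuracy > 90.0

    def test_no_test_fold_leakage(self, cohort):
        """A fold's fitted model depends only on its training rows:
        perturbing a held-out row leaves the scores of its fold-mates
        (scored by the same fold model) unchanged."""
        spec = model_catalog()[8]
        base = stratified_cv(cohort, spec, seed=5, n_boot=0)
        target = cohort.index[0]
        mutated = cohort.copy()
        mutated.loc[target, "V65_pct"] *= 1.5
        rep = stratified_cv(mutated, spec, seed=5, n_boot=0)
        a = base.predictions.set_index("patient_id")
        b = rep.predictions.set_index("patient_id")
        fold = a.loc[target, "fold"]
        mates = a.index[(a["fold"] == fold) & (a.index != target)]
        np.testing.assert_allclose(
            a.loc[mates, "score"].to_numpy(),
            b.loc[mates, "score"].to_numpy(),
            atol=1e-12,
        )

    def test_small_class_errors(self):
        df = pd.DataFrame(
            {"V65_pct": np.arange(10.0), "XQ_Int_mid": np.arange(10.0),
             "XER_12": [1] + [0] * 9}
        )
        with pytest.raises(ValueError, match="stratified"):
            stratified_cv(df, model_catalog()[8], seed=0, n_boot=0)


class TestCompareAndCatalog:
    def test_identical_predictions_p_one(self, cohort):
        spec = model_catalog()[8]
        r = stratified_cv(cohort, spec, seed=1, n_boot=0)
        assert compare_models(r, r).p_value == 1.0

    def test_symmetry(self, cohort):
        r8 = stratified_cv(cohort, model_catalog()[8], seed=1, n_boot=0)
        r3 = stratified_cv(cohort, model_catalog()[3], seed=1, n_boot=0)
        assert compare_models(r8, r3).p_value == compare_models(r3, r8).p_value

    def test_mismatched_patients_error(self, cohort):
        r = stratified_cv(cohort, model_catalog()[8], seed=1, n_boot=0)
        other = stratified_cv(cohort.iloc[:-1], model_catalog()[8], seed=1, n_boot=0)
        with pytest.raises(ValueError, match="patient sets"):
            compare_models(r, other)

    def test_catalog_feature_subsets(self):
        cat = model_catalog()
        assert len(cat) == 16
        assert set(cat[8].features) == {"V65_pct", "XQ_Int_mid"}
        assert set(cat[3].features) == {"ve_P25", "V65_pct"}
        assert set(cat[16].features) == {
            "ve_P25", "Ktrans_P10", "Dmean_Gy", "V65_pct",
            "Dmean_SMG_Gy", "XQ_Int_mid",
        }
        assert all(cat[i].stage == "baseline" for i in range(1, 8))
        assert all(cat[i].stage == "in_treatment" for i in range(8, 17))

    def test_catalog_screening_excludes_low_auc(self, cohort):
        reports, retained = run_catalog(cohort, seed=2, n_boot=0)
        assert set(reports) == set(range(1, 17))
        for i in retained:
            assert reports[i].auc > 0.6
        for i in set(reports) - set(retained):
            assert reports[i].auc <= 0.6
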