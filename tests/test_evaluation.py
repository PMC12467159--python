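import numpy as np
import pytest

from octatex.evaluation import (
    ClassifierSpec,
    EvaluationConfig,
    auc,
    cross_validate,
    full_classifier_grid,
    knn_grid,
    metric_panel,
    nested_cv,
    run_grid,
    stratified_kfold,
    svm_grid,
)
from octatex.features import FeatureMatrix


def brute_force_auc(scores, labels):
    """Exhaustive pair-counting oracle: ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_feature_matrix(n_per_class=30, F=10, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    D = np.vstack([
        rng.normal(0.0, 1.0, size=(n_per_class, F)),
        rng.normal(shift, 1.0, size=(n_per_class, F)),
    ])
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    eyes = tuple(f"e{i}" for i in range(2 * n_per_class))
    return FeatureMatrix(D=D, eye_ids=eyes, labels=labels, layers=("deep",), fingerprint="rand")


class TestStratifiedKfold:
    def test_balanced_30_30(self):
        y = np.array([1] * 30 + [0] * 30)
        folds = stratified_kfold(y, K=10, seed=42)
        for f in folds:
            assert len(f) == 6
            assert y[f].sum() == 3

    def test_imbalanced_33_23(self):
        # frozen from the dealing rule: 33 positives split 4/4/4/3...,
        # 23 negatives split 3/3/3/2..., balanced so folds are size 5-6
        y = np.array([1] * 33 + [0] * 23)
        folds = stratified_kfold(y, K=10, seed=42)
        sizes = sorted(len(f) for f in folds)
        assert set(sizes) <= {5, 6}
        for f in folds:
            assert int(y[f].sum()) in (3, 4)

    def test_partition(self):
        y = np.array([0, 1] * 20)
        folds = stratified_kfold(y, K=10, seed=3)
        flat = np.concatenate(folds)
        assert len(flat) == len(set(flat.tolist())) == 40

    def test_class_proportion_within_one(self):
        y = np.array([1] * 21 + [0] * 34)
        folds = stratified_kfold(y, K=10, seed=1)
        global_frac = 21 / 55
        for f in folds:
            assert abs(y[f].sum() - global_frac * len(f)) <= 1.0

    def test_small_class_rejected(self):
        y = np.array([1] * 5 + [0] * 30)
        with pytest.raises(ValueError):
            stratified_kfold(y, K=10, seed=0)

    def test_deterministic(self):
        y = np.array([0, 1] * 15)
        a = stratified_kfold(y, K=10, seed=9)
        b = stratified_kfold(y, K=10, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_toy_four_points_matches_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_random_scores_match_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 20))
            labels = np.r_[np.ones(n // 2, dtype=int), np.zeros(n - n // 2, dtype=int)]
            scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)  # force ties
            assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestMetricPanel:
    def test_perfect_predictions(self):
        labels = np.array([0, 0, 1, 1])
        p = metric_panel(labels, [0.1, 0.2, 0.8, 0.9], labels)
        for m in ("accuracy", "sensitivity", "specificity", "precision", "auc"):
            assert p[m] == 1.0

    def test_all_positive_on_balanced(self):
        labels = np.array([0, 0, 1, 1])
        p = metric_panel(np.ones(4, dtype=int), [0.6, 0.7, 0.8, 0.9], labels)
        assert p["sensitivity"] == 1.0
        assert p["specificity"] == 0.0
        assert p["accuracy"] == 0.5

    def test_hand_confusion_matrix(self):
        # TP=3, FP=1, TN=4, FN=2
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        preds = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0])
        p = metric_panel(preds, np.linspace(0, 1, 10)[::-1], labels)
        assert p["sensitivity"] == pytest.approx(0.6)
        assert p["specificity"] == pytest.approx(0.8)
        assert p["precision"] == pytest.approx(0.75)
        assert p["accuracy"] == pytest.approx(0.7)

    def test_zero_denominator_flagged(self):
        labels = np.array([0, 0, 1, 1])
        p = metric_panel(np.zeros(4, dtype=int), [0.1, 0.2, 0.3, 0.4], labels)
        assert p["precision"] == 0.0
        assert "precision" in p["degenerate"]


class TestGrids:
    def test_knn_grid_size(self):
        assert len(knn_grid()) == 5 * 3

    def test_svm_grid_size(self):
        # linear: 6; rbf: 6*6; poly: 6*6*8
        assert len(svm_grid()) == 6 + 36 + 288

    def test_full_grid_size(self):
        assert len(full_classifier_grid()) == 15 + 330


class TestCrossValidateAndRunGrid:
    def test_separable_data_perfect_auc(self):
        fm = random_feature_matrix(shift=8.0, seed=42)
        config = EvaluationConfig(seed=42, mode="reduced", classifiers=tuple(knn_grid()))
        report = run_grid(config, fm)
        assert report.best["mean_auc"] == 1.0
        assert report.best["std_auc"] == 0.0

    def test_determinism(self):
        fm = random_feature_matrix(shift=0.5, seed=7)
        config = EvaluationConfig(seed=42, mode="reduced", classifiers=tuple(knn_grid()[:3]))
        r1 = run_grid(config, fm)
        r2 = run_grid(config, fm)
        for e1, e2 in zip(r1.entries, r2.entries):
            assert e1 == e2

    def test_whole_vs_reduced_only_differ_by_transform(self):
        fm = random_feature_matrix(shift=1.0, seed=3)
        spec = ClassifierSpec("knn", (("k", 5), ("metric", "euclidean")))
        folds = stratified_kfold(fm.labels, K=10, seed=42)
        whole = cross_validate(fm.D, fm.labels, spec, folds, mode="whole")
        reduced = cross_validate(fm.D, fm.labels, spec, folds, mode="reduced")
        assert len(whole) == len(reduced) == 10
        assert set(whole[0]) == set(reduced[0])

    def test_fold_auc_matches_pair_ranking_oracle(self):
        fm = random_feature_matrix(shift=1.0, seed=5)
        spec = ClassifierSpec("svm", (("C", 1), ("kernel", "linear")))
        folds = stratified_kfold(fm.labels, K=10, seed=42)
        from sklearn.svm import SVC

        all_idx = np.arange(fm.n_eyes)
        for f, panel in zip(folds, cross_validate(fm.D, fm.labels, spec, folds)):
            train = np.setdiff1d(all_idx, f)
            clf = SVC(C=1, kernel="linear").fit(fm.D[train], fm.labels[train])
            scores = clf.decision_function(fm.D[f])
            assert panel["auc"] == pytest.approx(brute_force_auc(scores, fm.labels[f]))

    def test_no_leakage_from_test_rows(self):
        # a fold's transform and classifier are functions of its training
        # rows alone: perturbing the held-out rows must reproduce exactly the
        # panel obtained by fitting on train and scoring the perturbed rows
        from octatex.dimreduce import fit_reducer, transform
        from sklearn.neighbors import KNeighborsClassifier

        fm = random_feature_matrix(shift=1.0, seed=11)
        spec = ClassifierSpec("knn", (("k", 3), ("metric", "euclidean")))
        folds = stratified_kfold(fm.labels, K=10, seed=42)
        test0 = folds[0]
        train0 = np.setdiff1d(np.arange(fm.n_eyes), test0)
        D2 = fm.D.copy()
        D2[test0] += 3.0
        pipeline_panel = cross_validate(D2, fm.labels, spec, [test0], mode="reduced")[0]

        # independent recomputation from training rows of the *unperturbed*
        # matrix (identical to D2 on train): same transform, same model
        model = fit_reducer(fm.D[train0])
        clf = KNeighborsClassifier(n_neighbors=3, metric="euclidean", algorithm="brute")
        clf.fit(transform(fm.D[train0], model), fm.labels[train0])
        Z_test = transform(D2[test0], model)
        preds = clf.predict(Z_test)
        scores = clf.predict_proba(Z_test)[:, list(clf.classes_).index(1)]
        expected = metric_panel(preds, scores, fm.labels[test0])
        assert pipeline_panel == expected

    def test_label_permutation_null_auc(self):
        # mean AUC of a fixed config over label permutations concentrates at 0.5
        fm = random_feature_matrix(shift=1.0, seed=2)
        spec = ClassifierSpec("knn", (("k", 5), ("metric", "euclidean")))
        rng = np.random.default_rng(0)
        means = []
        for _ in range(200):
            y = rng.permutation(fm.labels)
            folds = stratified_kfold(y, K=10, seed=42)
            panels = cross_validate(fm.D, y, spec, folds)
            means.append(np.mean([p["auc"] for p in panels]))
        assert abs(np.mean(means) - 0.5) < 0.03

    def test_best_tie_break_prefers_smaller_std_then_order(self):
        from octatex.evaluation import EvaluationReport

        rep = EvaluationReport()
        mk = lambda a, s: [dict(auc=a, accuracy=1, sensitivity=1, specificity=1, precision=1)
                           for a in np.full(3, a) + np.array([-s, 0, s])]
        rep.add("d", ClassifierSpec("knn", (("k", 1), ("metric", "euclidean"))), mk(0.9, 0.1))
        rep.add("d", ClassifierSpec("knn", (("k", 3), ("metric", "euclidean"))), mk(0.9, 0.0))
        rep.add("d", ClassifierSpec("knn", (("k", 5), ("metric", "euclidean"))), mk(0.9, 0.0))
        assert rep.best["classifier"] == "knn(k=3,metric=euclidean)"


class TestNestedCv:
    def test_separable_data_still_perfect(self):
        fm = random_feature_matrix(n_per_class=15, shift=8.0, seed=1)
        panels = nested_cv(fm.D, fm.labels, knn_grid()[:6], K=5, seed=42, mode="reduced")
        assert np.mean([p["auc"] for p in panels]) == 1.0

    def test_null_data_near_chance(self):
        # nested selection removes the optimism of best-of-grid reporting
        fm = random_feature_matrix(n_per_class=30, shift=0.0, seed=4)
        panels = nested_cv(fm.D, fm.labels, knn_grid(), K=10, seed=42)
        assert 0.25 <= np.mean([p["auc"] for p in panels]) <= 0.75
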