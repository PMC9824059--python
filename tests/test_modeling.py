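"""Classifier protocol building blocks: SMOTE, scaling, AUC, LOSO, leakage."""

import numpy as np
import pytest

from gaitsurface import (
    InvalidConfigError,
    ModelSpec,
    SurfaceClassifier,
    UndefinedMetricError,
    auc,
    loso_partitions,
    run_loso_evaluation,
    smote_balance,
    standardize,
)
from gaitsurface.modeling import cv_auc, default_estimator

from conftest import planted_matrix


# ---------------------------------------------------------------------------
# partitions


def test_loso_partitions_cover_each_row_once(ankle_features):
    parts = loso_partitions(ankle_features)
    assert len(parts) == len(ankle_features.subjects)
    all_test = np.concatenate([test for _, test, _ in parts])
    assert sorted(all_test) == list(range(ankle_features.n))
    sids = np.asarray(ankle_features.subject_ids)
    for train, test, subject in parts:
        assert set(sids[test]) == {subject}
        assert subject not in set(sids[train])


def test_loso_single_subject_rejected(ankle_features):
    single = ankle_features.subset(
        rows=np.flatnonzero(
            np.asarray(ankle_features.subject_ids)
            == ankle_features.subjects[0]
        )
    )
    with pytest.raises(InvalidConfigError):
        loso_partitions(single)


# ---------------------------------------------------------------------------
# standardization


def test_standardize_closed_form():
    train = np.array([[1.0], [2.0], [3.0]])
    scaled, _, _ = standardize(train)
    assert scaled.ravel() == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)


def test_standardize_constant_column_and_test_mean():
    train = np.column_stack([np.array([1.0, 2.0, 3.0]), np.full(3, 7.0)])
    test = np.array([[2.0, 7.0]])
    train_s, test_s, _ = standardize(train, test)
    assert np.all(train_s[:, 1] == 0.0)
    assert test_s[0, 0] == pytest.approx(0.0)  # equals the train mean


# ---------------------------------------------------------------------------
# SMOTE


def _two_cluster_data(n_maj=650, n_min=350, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            rng.normal(0.0, 1.0, size=(n_maj, 5)),
            rng.normal(3.0, 1.0, size=(n_min, 5)),
        ]
    )
    y = np.array([0] * n_maj + [1] * n_min)
    return X, y


def test_smote_balances_65_35_to_50_50():
    X, y = _two_cluster_data()
    X2, y2 = smote_balance(X, y, seed=0)
    counts = np.bincount(y2)
    assert counts[0] == counts[1] == 650
    # originals preserved, in order
    assert np.array_equal(X2[: len(X)], X)


def test_smote_balanced_input_unchanged():
    X, y = _two_cluster_data(n_maj=100, n_min=100)
    X2, y2 = smote_balance(X, y, seed=0)
    assert np.array_equal(X2, X) and np.array_equal(y2, y)


def test_smote_synthetic_rows_are_convex_combinations():
    X, y = _two_cluster_data(n_maj=30, n_min=10, seed=1)
    X2, y2 = smote_balance(X, y, k_neighbors=5, seed=1)
    minority = X[y == 1]
    synthetic = X2[len(X):]
    assert len(synthetic) == 20
    for s in synthetic:
        found = False
        for i in range(len(minority)):
            for j in range(len(minority)):
                if i == j:
                    continue
                seg = minority[j] - minority[i]
                denom = float(seg @ seg)
                if denom == 0:
                    continue
                u = float((s - minority[i]) @ seg) / denom
                if -1e-9 <= u <= 1 + 1e-9 and np.allclose(
                    s, minority[i] + u * seg, atol=1e-9
                ):
                    found = True
                    break
            if found:
                break
        assert found, "synthetic sample off every minority segment"


def test_smote_small_minority_reduces_k_with_warning():
    X, y = _two_cluster_data(n_maj=20, n_min=4, seed=2)
    with pytest.warns(UserWarning, match="reducing k_neighbors"):
        X2, y2 = smote_balance(X, y, k_neighbors=5, seed=2)
    assert np.bincount(y2)[0] == np.bincount(y2)[1]


def test_smote_minority_of_one_rejected():
    X, y = _two_cluster_data(n_maj=10, n_min=1, seed=3)
    with pytest.raises(InvalidConfigError):
        smote_balance(X, y, seed=3)


# ---------------------------------------------------------------------------
# AUC


def test_auc_hand_counted_cases():
    assert auc([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2]) == 1.0
    assert auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5
    # hand count of concordant (positive, negative) pairs:
    # (0.8, 0.7) yes, (0.8, 0.2) yes, (0.3, 0.7) no, (0.3, 0.2) yes -> 3/4
    assert auc([1, 0, 1, 0], [0.8, 0.7, 0.3, 0.2]) == 0.75


def test_auc_one_class_undefined():
    with pytest.raises(UndefinedMetricError):
        auc([1, 1, 1], [0.1, 0.2, 0.3])


def test_auc_monotone_transform_invariant():
    rng = np.random.default_rng(5)
    y = (rng.random(50) < 0.4).astype(int)
    s = rng.normal(size=50)
    base = auc(y, s)
    assert auc(y, np.exp(s)) == pytest.approx(base)
    assert auc(y, 3.0 * s + 2.0) == pytest.approx(base)


# ---------------------------------------------------------------------------
# classifier + search


def _separable_matrix(n=120, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = np.column_stack([y * 4.0 + rng.normal(0, 0.2, n), rng.normal(size=n)])
    return X, y


def test_svm_separable_training_auc_is_one():
    X, y = _separable_matrix()
    clf = SurfaceClassifier(model="SVM", n_search_iterations=3, random_state=0)
    clf.fit(X, y)
    assert auc(y, clf.decision_scores(X)) == 1.0


def test_search_is_deterministic():
    X, y = _separable_matrix(seed=1)
    a = SurfaceClassifier(model="RF", n_search_iterations=4, random_state=7)
    b = SurfaceClassifier(model="RF", n_search_iterations=4, random_state=7)
    a.fit(X, y)
    b.fit(X, y)
    assert a.best_params_ == b.best_params_
    assert a.best_cv_auc_ == b.best_cv_auc_


def test_single_class_training_rejected():
    X = np.random.default_rng(0).normal(size=(30, 3))
    clf = SurfaceClassifier(model="LR", n_search_iterations=2)
    with pytest.raises(InvalidConfigError):
        clf.fit(X, np.zeros(30, dtype=int))


def test_permuted_labels_score_at_chance():
    """CV AUC under label permutation sits near 0.5 (median of 5 draws)."""
    rng = np.random.default_rng(9)
    X = rng.normal(size=(200, 10))
    scores = {"SVM": [], "RF": []}
    for rep in range(5):
        y = rng.permutation(np.array([1] * 70 + [0] * 130))
        for name in scores:
            scores[name].append(
                cv_auc(
                    X,
                    y,
                    lambda fs, n=name: default_estimator(n, seed=fs),
                    folds=5,
                    repeats=1,
                    seed=rep,
                )
            )
    for name, vals in scores.items():
        assert 0.4 <= float(np.median(vals)) <= 0.6, (name, vals)


# ---------------------------------------------------------------------------
# LOSO evaluation


def test_loso_report_bookkeeping():
    fm, _ = planted_matrix(n=160, effect=2.0, seed=3)
    spec = ModelSpec(name="LR", n_search_iterations=3, seed=0)
    report = run_loso_evaluation(fm, spec)
    values = np.array(list(report.per_subject_auc.values()))
    assert report.mean_auc == pytest.approx(values.mean())
    assert report.sd_auc == pytest.approx(values.std(ddof=1))
    assert set(report.predictions["subject_id"]) == set(fm.subjects)
    assert len(report.predictions) == fm.n


def test_loso_strong_signal_high_auc():
    fm, _ = planted_matrix(n=160, effect=2.0, seed=4)
    spec = ModelSpec(name="LR", n_search_iterations=3, seed=0)
    report = run_loso_evaluation(fm, spec)
    assert report.mean_auc > 0.9


def test_no_leakage_from_test_subject():
    """Corrupting the held-out subject's labels or features leaves the
    trained fold model unchanged."""
    fm, _ = planted_matrix(n=120, effect=1.0, seed=6)
    parts = loso_partitions(fm)
    train, test, subject = parts[0]
    X = fm.X.to_numpy(dtype=float)
    y = np.asarray(fm.y).copy()

    clf = SurfaceClassifier(model="LR", n_search_iterations=3, random_state=1)
    clf.fit(X[train], y[train])
    probs_before = clf.decision_scores(X[test])
    scaler_mean = clf.scaler_.mean_.copy()

    # corrupt the held-out subject's labels and features
    y[test] = 1 - y[test]
    X2 = X.copy()
    X2[test] += 100.0

    clf2 = SurfaceClassifier(model="LR", n_search_iterations=3, random_state=1)
    clf2.fit(X2[train], y[train])
    assert np.array_equal(clf2.scaler_.mean_, scaler_mean)
    assert np.allclose(clf2.decision_scores(X[test]), probs_before)
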