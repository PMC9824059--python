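"""Classifier training and evaluation protocols.

Five classifiers (SVM with RBF kernel, random forest, logistic regression,
AdaBoost, gradient-boosted trees) are trained on standardized, SMOTE-balanced
stride features and compared by AUC under a leave-one-subject-out (LOSO)
protocol: each subject in turn is the test set, hyperparameters are re-tuned
on the remaining subjects by randomized search with stratified five-fold CV,
and the per-subject test AUCs are averaged.

Pipeline order inside every fold is standardize -> SMOTE -> fit, so the
nearest-neighbour geometry SMOTE relies on is not dominated by feature scale,
and neither the scaler nor the oversampler ever sees test data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint, uniform
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterSampler, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .errors import InvalidConfigError, UndefinedMetricError
from .features import FeatureMatrix

MODEL_NAMES = ("SVM", "RF", "LR", "ADA", "XGB")

SMOTE_K_NEIGHBORS = 5
DEFAULT_SEARCH_ITERATIONS = 20
DEFAULT_CV_FOLDS = 5


def default_estimator(name: str, seed: int = 0):
    """An unfitted classifier with fast, sensible default hyperparameters."""
    if name == "SVM":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed,
                                      n_jobs=1)
    if name == "LR":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "ADA":
        return AdaBoostClassifier(n_estimators=50, random_state=seed)
    if name == "XGB":
        return XGBClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.3,
            eval_metric="logloss", verbosity=0, n_jobs=1, random_state=seed,
        )
    raise InvalidConfigError(f"unknown model name {name!r}")


def default_search_space(name: str) -> dict:
    """Randomized-search distributions per classifier.

    The searched hyperparameters follow the usual choices for each model
    (SVM: RBF cost and kernel coefficient; RF: trees, depth, split/leaf
    minima, features per split; XGB: depth, learning rate, trees, row and
    per-tree/per-node column subsampling); ranges are package defaults.
    """
    if name == "SVM":
        return {"C": loguniform(1e-1, 1e2), "gamma": loguniform(1e-3, 1e1)}
    if name == "RF":
        return {
            "n_estimators": randint(50, 301),
            "max_depth": [None, 3, 5, 10, 20],
            "min_samples_split": randint(2, 11),
            "max_features": ["sqrt", "log2", 0.5, 1.0],
            "min_samples_leaf": randint(1, 5),
        }
    if name == "LR":
        return {"C": loguniform(1e-3, 1e2)}
    if name == "ADA":
        return {"n_estimators": randint(25, 201),
                "learning_rate": loguniform(0.01, 2.0)}
    if name == "XGB":
        return {
            "max_depth": randint(2, 9),
            "learning_rate": loguniform(0.01, 0.5),
            "n_estimators": randint(50, 301),
            "subsample": uniform(0.5, 0.5),
            "colsample_bytree": uniform(0.5, 0.5),
            "colsample_bynode": uniform(0.5, 0.5),
        }
    raise InvalidConfigError(f"unknown model name {name!r}")


@dataclass
class ModelSpec:
    """A classifier plus its hyperparameter search configuration."""

    name: str
    search_space: dict | None = None
    n_search_iterations: int = DEFAULT_SEARCH_ITERATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise InvalidConfigError(f"unknown model name {self.name!r}")
        if self.search_space is None:
            self.search_space = default_search_space(self.name)
        if not self.search_space:
            raise InvalidConfigError("search space must be non-empty")


def default_model_specs(seed: int = 0) -> list[ModelSpec]:
    return [ModelSpec(name=n, seed=seed) for n in MODEL_NAMES]


# ---------------------------------------------------------------------------
# protocol building blocks


def loso_partitions(
    data: FeatureMatrix,
) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """(train_rows, test_rows, held_out_subject) per subject.

    Test sets are disjoint and jointly cover every row exactly once.
    """
    subjects = data.subjects
    if len(subjects) < 2:
        raise InvalidConfigError("LOSO needs at least 2 subjects")
    sids = np.asarray(data.subject_ids)
    partitions = []
    for subject in subjects:
        test = np.flatnonzero(sids == subject)
        train = np.flatnonzero(sids != subject)
        partitions.append((train, test, subject))
    return partitions


def standardize(
    train_X: np.ndarray, other_X: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, StandardScaler]:
    """Zero-mean / unit-variance scaling fitted on the training rows only.

    Constant columns map to 0 (no division error).
    """
    scaler = StandardScaler()
    train_s = scaler.fit_transform(np.asarray(train_X, dtype=float))
    other_s = None
    if other_X is not None:
        other_s = scaler.transform(np.asarray(other_X, dtype=float))
    return train_s, other_s, scaler


def smote_balance(
    train_X: np.ndarray,
    train_y: np.ndarray,
    k_neighbors: int = SMOTE_K_NEIGHBORS,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class to a 50:50 ratio (SMOTE).

    Each synthetic sample lies on the segment between a minority sample and
    one of its k nearest minority neighbours.  Original rows are preserved
    and come first in the output.  Training data only — never balance a test
    set.
    """
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise InvalidConfigError("SMOTE requires exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X, y
    if n_min < 2:
        raise InvalidConfigError("minority class needs at least 2 members")
    if n_min <= k_neighbors:
        warnings.warn(
            f"minority class has {n_min} members; reducing k_neighbors "
            f"from {k_neighbors} to {n_min - 1}",
            stacklevel=2,
        )
        k_neighbors = n_min - 1

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    neighbors = nn.kneighbors(X_min, return_distance=False)[:, 1:]

    n_new = int(n_maj - n_min)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_neighbors, size=n_new)
    gaps = rng.random(n_new)
    partners = neighbors[base, pick]
    synthetic = X_min[base] + gaps[:, None] * (X_min[partners] - X_min[base])

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney U / n1*n0, ties counting one half)."""
    y = np.asarray(y_true)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError(
            "AUC is undefined when only one class is present"
        )
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _score_samples(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


# ---------------------------------------------------------------------------
# the tunable classifier


class SurfaceClassifier(BaseEstimator, ClassifierMixin):
    """Surface classifier with fold-safe preprocessing and randomized search.

    ``fit`` runs a randomized hyperparameter search scored by stratified
    five-fold CV AUC; inside every fold the scaler and SMOTE are fitted on
    the fold's training part only.  The best configuration is refitted on the
    full (standardized, balanced) training data.

    Parameters
    ----------
    model : one of "SVM", "RF", "LR", "ADA", "XGB"
    search_space : randomized-search distributions; defaults per model
    n_search_iterations : sampled configurations (1 disables tuning beyond
        a single draw)
    cv_folds : folds of the inner stratified CV
    smote : whether to SMOTE-balance training folds
    random_state : master seed; the search, CV shuffling, SMOTE and the
        estimator are all derived from it
    """

    def __init__(
        self,
        model: str = "SVM",
        search_space: dict | None = None,
        n_search_iterations: int = DEFAULT_SEARCH_ITERATIONS,
        cv_folds: int = DEFAULT_CV_FOLDS,
        smote: bool = True,
        smote_k: int = SMOTE_K_NEIGHBORS,
        random_state: int = 0,
    ) -> None:
        self.model = model
        self.search_space = search_space
        self.n_search_iterations = n_search_iterations
        self.cv_folds = cv_folds
        self.smote = smote
        self.smote_k = smote_k
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _space(self) -> dict:
        return (
            self.search_space
            if self.search_space is not None
            else default_search_space(self.model)
        )

    def _fit_fold(self, params, X_tr, y_tr, X_val, seed):
        X_s, X_val_s, _ = standardize(X_tr, X_val)
        if self.smote:
            X_s, y_tr = smote_balance(X_s, y_tr, self.smote_k, seed)
        est = default_estimator(self.model, seed=seed)
        est.set_params(**params)
        est.fit(X_s, y_tr)
        return _score_samples(est, X_val_s)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise InvalidConfigError(
                "training data contains a single class; cannot fit"
            )
        rng = np.random.default_rng(self.random_state)
        sampler = ParameterSampler(
            self._space(),
            n_iter=self.n_search_iterations,
            random_state=int(rng.integers(2**31 - 1)),
        )
        cv_seed = int(rng.integers(2**31 - 1))
        fold_seeds = rng.integers(2**31 - 1, size=self.cv_folds)
        skf = StratifiedKFold(
            n_splits=self.cv_folds, shuffle=True, random_state=cv_seed
        )
        folds = list(skf.split(X, y))

        best_params, best_score = None, -np.inf
        for params in sampler:
            scores = []
            for (tr, val), fseed in zip(folds, fold_seeds):
                if len(np.unique(y[tr])) < 2:
                    raise InvalidConfigError(
                        "degenerate single-class CV training fold"
                    )
                val_scores = self._fit_fold(
                    params, X[tr], y[tr], X[val], int(fseed)
                )
                scores.append(auc(y[val], val_scores))
            mean_score = float(np.mean(scores))
            if mean_score > best_score:
                best_params, best_score = params, mean_score

        refit_seed = int(rng.integers(2**31 - 1))
        X_s, _, scaler = standardize(X)
        y_fit = y
        if self.smote:
            X_s, y_fit = smote_balance(X_s, y_fit, self.smote_k, refit_seed)
        est = default_estimator(self.model, seed=refit_seed)
        est.set_params(**best_params)
        if not hasattr(est, "predict_proba"):
            # SVM decision scores are mapped to probabilities by Platt
            # scaling (sigmoid calibration on internal CV predictions)
            est = CalibratedClassifierCV(est, method="sigmoid", cv=5,
                                         ensemble=False)
        est.fit(X_s, y_fit)

        self.classes_ = classes
        self.best_params_ = best_params
        self.best_cv_auc_ = best_score
        self.scaler_ = scaler
        self.estimator_ = est
        return self

    def predict_proba(self, X):
        X_s = self.scaler_.transform(np.asarray(X, dtype=float))
        return self.estimator_.predict_proba(X_s)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_scores(self, X) -> np.ndarray:
        """Continuous scores for AUC (probability of the positive class)."""
        return self.predict_proba(X)[:, 1]


def tune_fit(spec: ModelSpec, train: FeatureMatrix) -> SurfaceClassifier:
    """Fit a :class:`SurfaceClassifier` for ``spec`` on a feature matrix."""
    clf = SurfaceClassifier(
        model=spec.name,
        search_space=spec.search_space,
        n_search_iterations=spec.n_search_iterations,
        random_state=spec.seed,
    )
    return clf.fit(train.X.to_numpy(), train.y)


# ---------------------------------------------------------------------------
# LOSO evaluation


@dataclass
class LOSOReport:
    """Per-subject test AUCs of one model under leave-one-subject-out."""

    model: str
    features: list[str]
    per_subject_auc: dict[str, float]
    mean_auc: float
    sd_auc: float
    predictions: pd.DataFrame = field(repr=False, default=None)
    # predictions columns: subject_id, stride_order, probability, label


def run_loso_evaluation(
    data: FeatureMatrix,
    spec: ModelSpec,
    features: Sequence[str] | None = None,
) -> LOSOReport:
    """Leave-one-subject-out evaluation of one classifier.

    Per partition: standardize on the training subjects, SMOTE the training
    data, tune and refit, then score the held-out subject's strides.  The
    report keeps per-stride predicted probabilities for post-processing.
    """
    if len(data.subjects) < 3:
        raise InvalidConfigError("LOSO evaluation needs at least 3 subjects")
    feats = list(features) if features is not None else data.feature_names
    X_all = data.X.loc[:, feats].to_numpy(dtype=float)
    y_all = np.asarray(data.y)

    per_subject: dict[str, float] = {}
    pred_rows = []
    base_ss = np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 9041])
    fold_seeds = base_ss.generate_state(len(data.subjects)) & 0x7FFFFFFF
    for (train, test, subject), fseed in zip(loso_partitions(data), fold_seeds):
        clf = SurfaceClassifier(
            model=spec.name,
            search_space=spec.search_space,
            n_search_iterations=spec.n_search_iterations,
            random_state=int(fseed),
        )
        try:
            clf.fit(X_all[train], y_all[train])
            probs = clf.decision_scores(X_all[test])
            per_subject[subject] = auc(y_all[test], probs)
        except (InvalidConfigError, UndefinedMetricError) as exc:
            raise type(exc)(f"subject {subject}: {exc}") from exc
        for order, (row, p) in enumerate(zip(test, probs)):
            pred_rows.append(
                {
                    "subject_id": subject,
                    "stride_order": order,
                    "probability": float(p),
                    "label": int(y_all[row]),
                }
            )

    values = np.array(list(per_subject.values()))
    return LOSOReport(
        model=spec.name,
        features=feats,
        per_subject_auc=per_subject,
        mean_auc=float(values.mean()),
        sd_auc=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        predictions=pd.DataFrame(pred_rows),
    )


def cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    make_estimator: Callable[[int], BaseEstimator],
    folds: int = DEFAULT_CV_FOLDS,
    repeats: int = 1,
    seed: int = 0,
    smote: bool = True,
) -> float:
    """Mean AUC of repeated stratified k-fold CV with fold-safe preprocessing.

    Used wherever the protocol calls for a repeated-CV metric rather than a
    held-out subject (location comparison, incremental feature curves).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        for tr, val in skf.split(X, y):
            fseed = int(rng.integers(2**31 - 1))
            X_s, X_val_s, _ = standardize(X[tr], X[val])
            y_tr = y[tr]
            if smote:
                X_s, y_tr = smote_balance(X_s, y_tr, SMOTE_K_NEIGHBORS, fseed)
            est = clone(make_estimator(fseed))
            est.fit(X_s, y_tr)
            scores.append(auc(y[val], _score_samples(est, X_val_s)))
    return float(np.mean(scores))
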