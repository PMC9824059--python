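"""Feature ranking and subset-size selection.

Two selectors are compared:

* **Elastic net (ENET)** — an L1+L2-penalized model is tuned over a grid of
  mixing parameter alpha (0 = ridge, 1 = lasso) and regularization strength
  lambda by stratified five-fold CV maximizing AUC, refitted on the full
  training set, and features are ranked by absolute coefficient.  Because
  the response is binary, ranking uses the elastic-net-penalized logistic
  objective by default; the squared-error variant is available via
  ``loss="squared"``.
* **mRMR-FCQ** — greedy forward selection scoring each candidate by the
  one-way ANOVA F-statistic against the class label divided by its mean
  absolute Pearson correlation with the already-selected set.

Within a leave-one-subject-out protocol each iteration contributes a top-10
list; the lists are profiled by selection frequency, features of equal
frequency are added batch-by-batch to an AUC-vs-subset-size curve, and the
knee of that curve (the Kneedle algorithm) gives the final subset size.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import f_classif
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import InvalidConfigError
from .features import FeatureMatrix
from .modeling import ModelSpec, auc, cv_auc, default_estimator

TOP_K = 10  # features kept per LOSO iteration, both selectors

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 0, 9))


@dataclass
class ENETConfig:
    """Grid-search configuration for the elastic-net ranker."""

    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID
    cv_folds: int = 5
    seed: int = 0
    loss: str = "logistic"  # or "squared"

    def __post_init__(self) -> None:
        if len(self.alpha_grid) == 0 or len(self.lambda_grid) == 0:
            raise InvalidConfigError("grids must be non-empty")
        if any(not (0.0 <= a <= 1.0) for a in self.alpha_grid):
            raise InvalidConfigError("alpha values must lie in [0, 1]")
        if any(lam <= 0 for lam in self.lambda_grid):
            raise InvalidConfigError("lambda values must be positive")
        if self.loss not in ("logistic", "squared"):
            raise InvalidConfigError("loss must be 'logistic' or 'squared'")


class ElasticNetRanker(BaseEstimator):
    """Rank features by |coefficient| of a CV-tuned elastic net.

    Fitted attributes: ``best_params_`` (alpha, lambda), ``coef_`` (named
    coefficients of the full-data refit), ``ranking_`` (all features by
    descending |coefficient|, ties alphabetical), ``top_features_`` (the
    first ``n_top``).
    """

    def __init__(
        self,
        alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
        lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
        cv_folds: int = 5,
        n_top: int = TOP_K,
        loss: str = "logistic",
        random_state: int = 0,
    ) -> None:
        self.alpha_grid = alpha_grid
        self.lambda_grid = lambda_grid
        self.cv_folds = cv_folds
        self.n_top = n_top
        self.loss = loss
        self.random_state = random_state

    def _make_model(self, alpha: float, lam: float, n: int):
        if self.loss == "squared":
            return ElasticNet(
                alpha=lam, l1_ratio=alpha, max_iter=5000,
                random_state=self.random_state,
            )
        # sklearn's logistic objective is C * sum(loss) + penalty, so the
        # per-sample-averaged penalty weight lambda maps to C = 1 / (n*lambda)
        # tol 1e-3 is ample for coefficient ranking and AUC-based grid choice
        return LogisticRegression(
            solver="saga", l1_ratio=float(alpha), C=1.0 / (n * lam),
            max_iter=1000, tol=1e-3, random_state=self.random_state,
        )

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X = pd.DataFrame(X)
        if feature_names is not None:
            X.columns = list(feature_names)
        else:
            X.columns = [str(c) for c in X.columns]
        if len(X) == 0:
            raise InvalidConfigError("cannot rank features of an empty matrix")
        y = np.asarray(y)
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
        n = len(Xv)

        skf = StratifiedKFold(
            n_splits=self.cv_folds, shuffle=True,
            random_state=self.random_state,
        )
        folds = list(skf.split(Xv, y))
        lambdas = sorted(self.lambda_grid, reverse=True)
        score_sums: dict[tuple[float, float], float] = {
            (a, l): 0.0 for a in self.alpha_grid for l in lambdas
        }
        for tr, val in folds:
            scaler = StandardScaler().fit(Xv[tr])
            X_tr, X_val = scaler.transform(Xv[tr]), scaler.transform(Xv[val])
            for alpha in self.alpha_grid:
                model = None
                # walk the penalty path from strong to weak shrinkage,
                # warm-starting each fit from the previous solution
                for lam in lambdas:
                    fresh = self._make_model(alpha, lam, len(tr))
                    if model is None or not hasattr(fresh, "warm_start"):
                        model = fresh
                        if hasattr(model, "warm_start"):
                            model.warm_start = True
                    else:
                        model.set_params(**{
                            "C" if hasattr(fresh, "C") else "alpha": (
                                fresh.C if hasattr(fresh, "C") else fresh.alpha
                            )
                        })
                    model.fit(X_tr, y[tr])
                    raw = (
                        model.decision_function(X_val)
                        if hasattr(model, "decision_function")
                        else model.predict(X_val)
                    )
                    # constant scores (full shrinkage) rank at chance
                    if np.ptp(raw) == 0:
                        score_sums[(alpha, lam)] += 0.5
                    else:
                        score_sums[(alpha, lam)] += auc(y[val], raw)

        best, best_score = None, -np.inf
        for alpha in self.alpha_grid:
            for lam in lambdas:
                mean_score = score_sums[(alpha, lam)] / len(folds)
                if mean_score > best_score:
                    best, best_score = (alpha, lam), mean_score

        alpha, lam = best
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                ("model", self._make_model(alpha, lam, n)),
            ]
        )
        pipe.fit(Xv, y)
        coefs = np.ravel(pipe.named_steps["model"].coef_)
        order = sorted(range(len(names)), key=lambda i: (-abs(coefs[i]), names[i]))

        self.best_params_ = {"alpha": float(alpha), "lambda": float(lam)}
        self.best_cv_auc_ = best_score
        self.coef_ = pd.Series(coefs, index=names)
        self.ranking_ = [names[i] for i in order]
        self.top_features_ = self.ranking_[: self.n_top]
        return self


def enet_rank(
    train: FeatureMatrix, config: ENETConfig | None = None
) -> list[str]:
    """Top-10 feature names by elastic-net coefficient magnitude.

    If fewer than 10 coefficients are nonzero, the list is padded by
    descending |coefficient| with an alphabetical tie-break (zeros included).
    """
    config = config or ENETConfig()
    ranker = ElasticNetRanker(
        alpha_grid=config.alpha_grid,
        lambda_grid=config.lambda_grid,
        cv_folds=config.cv_folds,
        loss=config.loss,
        random_state=config.seed,
    )
    ranker.fit(train.X, train.y)
    return ranker.top_features_


# ---------------------------------------------------------------------------
# mRMR-FCQ


def _f_statistic(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0
    f, _ = f_classif(x.reshape(-1, 1), y)
    return float(f[0])


@dataclass
class MRMRState:
    """Greedy-selection state: the selected set and last-iteration scores."""

    selected: list[str] = field(default_factory=list)
    scores: dict[str, float] = field(default_factory=dict)


def mrmr_score(
    candidate: np.ndarray,
    y: np.ndarray,
    selected: Sequence[np.ndarray],
) -> float:
    """F-statistic relevance over mean |Pearson correlation| redundancy.

    With an empty selected set the score is the F-statistic alone; a
    zero-variance candidate scores 0; the redundancy denominator is floored
    at 1e-12.
    """
    candidate = np.asarray(candidate, dtype=float)
    y = np.asarray(y)
    if len(candidate) != len(y):
        raise InvalidConfigError("candidate and labels differ in length")
    if np.ptp(candidate) == 0:
        return 0.0
    relevance = _f_statistic(candidate, y)
    if not selected:
        return relevance
    corrs = []
    for s in selected:
        s = np.asarray(s, dtype=float)
        if np.ptp(s) == 0:
            corrs.append(0.0)
        else:
            corrs.append(abs(float(np.corrcoef(s, candidate)[0, 1])))
    denom = max(float(np.mean(corrs)), 1e-12)
    return relevance / denom


class MRMRSelector(BaseEstimator):
    """Greedy mRMR-FCQ forward selection of ``k`` features.

    Fitted attributes: ``selected_`` (ordered feature names), ``state_``
    (final :class:`MRMRState`), ``support_`` (boolean mask in input order).
    """

    def __init__(self, k: int = TOP_K) -> None:
        self.k = k

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X = pd.DataFrame(X)
        if feature_names is not None:
            X.columns = list(feature_names)
        else:
            X.columns = [str(c) for c in X.columns]
        y = np.asarray(y)
        names = list(X.columns)
        if self.k > len(names):
            raise InvalidConfigError(
                f"k={self.k} exceeds the number of features ({len(names)})"
            )
        cols = {n: X[n].to_numpy(dtype=float) for n in names}
        relevance = {n: _f_statistic(cols[n], y) for n in names}

        # precompute |Pearson correlation|; zero-variance columns correlate 0
        Xv = X.to_numpy(dtype=float)
        sd = Xv.std(axis=0)
        safe = np.where(sd == 0, 1.0, sd)
        Z = (Xv - Xv.mean(axis=0)) / safe
        corr = np.abs(Z.T @ Z) / len(Xv)
        corr[sd == 0, :] = 0.0
        corr[:, sd == 0] = 0.0
        idx = {n: i for i, n in enumerate(names)}

        state = MRMRState()
        remaining = list(names)
        for _ in range(self.k):
            scores = {}
            for cand in remaining:
                if not state.selected:
                    scores[cand] = relevance[cand]
                elif sd[idx[cand]] == 0:
                    scores[cand] = 0.0
                else:
                    denom = float(
                        np.mean(
                            [corr[idx[s], idx[cand]] for s in state.selected]
                        )
                    )
                    scores[cand] = relevance[cand] / max(denom, 1e-12)
            best = min(remaining, key=lambda n: (-scores[n], n))
            state.selected.append(best)
            state.scores = scores
            remaining.remove(best)

        self.selected_ = list(state.selected)
        self.state_ = state
        self.support_ = np.array([n in set(state.selected) for n in names])
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        return X.loc[:, self.selected_].to_numpy()


def mrmr_select(train: FeatureMatrix, k: int = TOP_K) -> list[str]:
    """Ordered top-k feature names by greedy mRMR-FCQ."""
    selector = MRMRSelector(k=k)
    selector.fit(train.X, train.y)
    return selector.selected_


# ---------------------------------------------------------------------------
# profiling and knee detection


@dataclass
class SelectionProfile:
    """Selection frequency of features across LOSO iterations."""

    counts: dict[str, int]
    order: list[str]  # by count desc, ties alphabetical

    @classmethod
    def from_lists(cls, per_iteration: Sequence[Sequence[str]]):
        counter: Counter[str] = Counter()
        for top in per_iteration:
            if len(top) != TOP_K:
                raise InvalidConfigError(
                    f"each iteration must contribute {TOP_K} features, "
                    f"got {len(top)}"
                )
            if len(set(top)) != len(top):
                raise InvalidConfigError("duplicate feature in a top list")
            counter.update(top)
        order = sorted(counter, key=lambda n: (-counter[n], n))
        return cls(counts=dict(counter), order=order)

    def batches(self) -> list[list[str]]:
        """Groups of equal-count features in profile order."""
        out: list[list[str]] = []
        for name in self.order:
            if out and self.counts[out[-1][-1]] == self.counts[name]:
                out[-1].append(name)
            else:
                out.append([name])
        return out


def profile_selections(
    per_iteration_top10: Sequence[Sequence[str]],
) -> SelectionProfile:
    return SelectionProfile.from_lists(per_iteration_top10)


@dataclass
class KneeCurve:
    """Performance (mean AUC) versus cumulative number of features."""

    x: np.ndarray  # increasing feature counts
    y: np.ndarray  # mean AUC per batch
    sensitivity: float = 1.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise InvalidConfigError("x and y must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise InvalidConfigError("x must be strictly increasing")


def kneedle_knee(curve: KneeCurve) -> float | None:
    """Knee of a concave increasing curve (Kneedle).

    Min-max normalize both axes, form the difference curve d = y_n - x_n,
    take local maxima of d as knee candidates, and return the first
    candidate whose following difference values drop below its
    sensitivity-adjusted threshold.  Returns None for curves without
    curvature (e.g. a straight line).
    """
    x, y, s = curve.x, curve.y, curve.sensitivity
    if len(x) < 3:
        raise InvalidConfigError("knee detection needs at least 3 points")
    x_n = (x - x.min()) / (x.max() - x.min())
    if np.ptp(y) == 0:
        y_n = np.zeros_like(y)
    else:
        y_n = (y - y.min()) / (y.max() - y.min())
    d = y_n - x_n

    maxima = [
        i
        for i in range(1, len(d) - 1)
        if d[i] > d[i - 1] and d[i] >= d[i + 1]
    ]
    if not maxima:
        return None
    mean_spacing = float(np.mean(np.diff(x_n)))
    for pos, i in enumerate(maxima):
        threshold = d[i] - s * mean_spacing
        nxt = maxima[pos + 1] if pos + 1 < len(maxima) else len(d)
        for j in range(i + 1, nxt):
            if d[j] < threshold:
                return float(x[i])
    return None


def incremental_feature_curve(
    profile: SelectionProfile,
    data: FeatureMatrix,
    model_specs: Sequence[ModelSpec],
    cv_folds: int = 5,
    cv_repeats: int = 5,
    seed: int = 0,
    sensitivity: float = 1.0,
) -> dict[str, KneeCurve]:
    """AUC-vs-feature-count curve per model, adding profile batches in order.

    Equal-frequency features enter together (batch-by-batch); after each
    batch every model's AUC is estimated by repeated stratified five-fold CV
    with default hyperparameters.
    """
    if not profile.order:
        raise InvalidConfigError("selection profile is empty")
    batches = profile.batches()
    xs = np.cumsum([len(b) for b in batches])
    y_all = np.asarray(data.y)

    curves: dict[str, KneeCurve] = {}
    for spec in model_specs:
        ys = []
        cumulative: list[str] = []
        for batch in batches:
            cumulative.extend(batch)
            X = data.X.loc[:, cumulative].to_numpy(dtype=float)
            ys.append(
                cv_auc(
                    X,
                    y_all,
                    lambda fs, name=spec.name: default_estimator(name, seed=fs),
                    folds=cv_folds,
                    repeats=cv_repeats,
                    seed=seed,
                )
            )
        curves[spec.name] = KneeCurve(
            x=xs.copy(), y=np.asarray(ys), sensitivity=sensitivity
        )
    return curves


def loso_selection_profile(
    data: FeatureMatrix,
    method: str,
    enet_config: ENETConfig | None = None,
    k: int = TOP_K,
) -> tuple[SelectionProfile, list[list[str]]]:
    """Run a selector inside every LOSO iteration and profile its top lists."""
    from .modeling import loso_partitions

    per_iteration: list[list[str]] = []
    for train, _, _ in loso_partitions(data):
        sub = data.subset(rows=train)
        if method == "enet":
            per_iteration.append(enet_rank(sub, enet_config))
        elif method == "mrmr":
            per_iteration.append(mrmr_select(sub, k))
        else:
            raise InvalidConfigError(f"unknown selection method {method!r}")
    return profile_selections(per_iteration), per_iteration
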