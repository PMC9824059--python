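"""Sensor-location comparison: per-location AUC distributions, one-way ANOVA
and Tukey HSD post-hoc pairwise tests.

For each leave-one-subject-out iteration and each sensor location, the metric
is the mean AUC of five-times-repeated stratified five-fold CV on the
training subjects' strides with the full 40-feature set and default model
hyperparameters, yielding one metric set per (classifier, location).  A
one-way ANOVA then tests whether location affects classification performance,
followed by Tukey's HSD for the pairwise location contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import InvalidConfigError
from .features import FeatureMatrix
from .modeling import ModelSpec, cv_auc, default_estimator, loso_partitions


@dataclass
class LocationMetricSet:
    """Per (classifier, location): one CV AUC per LOSO iteration."""

    values: dict[tuple[str, str], np.ndarray]
    subjects: list[str]

    def group(self, model: str) -> dict[str, np.ndarray]:
        return {
            loc: vals
            for (m, loc), vals in self.values.items()
            if m == model
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (model, loc), vals in self.values.items():
            for subject, v in zip(self.subjects, vals):
                rows.append(
                    {
                        "model": model,
                        "location": loc,
                        "held_out_subject": subject,
                        "auc": float(v),
                    }
                )
        return pd.DataFrame(rows)


def location_auc_distributions(
    cohort_features: Mapping[str, FeatureMatrix],
    specs: Sequence[ModelSpec],
    cv_folds: int = 5,
    cv_repeats: int = 5,
    seed: int = 0,
) -> LocationMetricSet:
    """CV-AUC metric sets per classifier and location under LOSO.

    All locations must hold the same subjects with aligned strides.  The
    metric for an iteration is computed on the training portion (the held-out
    subject is untouched).
    """
    locations = list(cohort_features)
    ref = cohort_features[locations[0]]
    for loc in locations[1:]:
        other = cohort_features[loc]
        if other.subjects != ref.subjects or other.n != ref.n:
            raise InvalidConfigError(
                f"location {loc!r} disagrees with {locations[0]!r} on "
                "subjects or stride counts"
            )

    partitions = loso_partitions(ref)
    # one CV seed per (iteration, classifier), shared by all locations: the
    # locations hold the same strides row for row, so evaluating them on the
    # same fold partition makes the comparison paired and removes fold-split
    # noise from the between-location differences
    seeds = (
        np.random.SeedSequence([seed & 0x7FFFFFFF, 551]).generate_state(
            len(partitions) * len(specs)
        )
        & 0x7FFFFFFF
    )
    values: dict[tuple[str, str], list[float]] = {
        (spec.name, loc): [] for spec in specs for loc in locations
    }
    i = 0
    for train, _, _ in partitions:
        for spec in specs:
            for loc in locations:
                fm = cohort_features[loc]
                X = fm.X.to_numpy(dtype=float)[train]
                y = np.asarray(fm.y)[train]
                score = cv_auc(
                    X,
                    y,
                    lambda fs, name=spec.name: default_estimator(name, seed=fs),
                    folds=cv_folds,
                    repeats=cv_repeats,
                    seed=int(seeds[i]),
                )
                values[(spec.name, loc)].append(score)
            i += 1
    return LocationMetricSet(
        values={k: np.asarray(v) for k, v in values.items()},
        subjects=[s for _, _, s in partitions],
    )


def one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F and p over k groups.

    Conventions for degenerate inputs: zero within-group variance with equal
    means gives (0, 1); zero within-group variance with unequal means gives
    (inf, 0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InvalidConfigError("ANOVA needs >= 2 groups of >= 2 values each")
    within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    means = [g.mean() for g in groups]
    if within == 0.0:
        if np.ptp(means) == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


@dataclass
class TukeyComparison:
    """One pairwise location contrast from Tukey's HSD."""

    group_1: str
    group_2: str
    mean_difference: float
    adjusted_p: float
    ci_lower: float
    ci_upper: float
    reject: bool


def tukey_hsd(
    groups: Mapping[str, np.ndarray], alpha: float = 0.05
) -> list[TukeyComparison]:
    """All pairwise comparisons via the studentized-range distribution.

    ``reject`` is True iff the adjusted p is below alpha iff the simultaneous
    CI excludes zero.  Classic (equal-n) Tukey HSD when group sizes match;
    statsmodels applies the Tukey-Kramer adjustment automatically otherwise.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(names) < 2 or any(len(a) < 2 for a in arrays):
        raise InvalidConfigError("Tukey needs >= 2 groups of >= 2 values each")

    within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    if within == 0.0:
        out = []
        for n1, n2 in combinations(names, 2):
            diff = float(groups[n2].mean() - groups[n1].mean())
            degenerate_reject = diff != 0.0
            out.append(
                TukeyComparison(
                    group_1=n1,
                    group_2=n2,
                    mean_difference=diff,
                    adjusted_p=0.0 if degenerate_reject else 1.0,
                    ci_lower=diff,
                    ci_upper=diff,
                    reject=degenerate_reject,
                )
            )
        return out

    endog = np.concatenate(arrays)
    labels = np.concatenate(
        [np.full(len(a), n, dtype=object) for n, a in zip(names, arrays)]
    )
    res = pairwise_tukeyhsd(endog, labels, alpha=alpha)
    table = res.summary().data[1:]
    ci = res.confint
    out = []
    for row, (lo, hi), p, rej, diff in zip(
        table, ci, res.pvalues, res.reject, res.meandiffs
    ):
        out.append(
            TukeyComparison(
                group_1=str(row[0]),
                group_2=str(row[1]),
                mean_difference=float(diff),
                adjusted_p=float(p),
                ci_lower=float(lo),
                ci_upper=float(hi),
                reject=bool(rej),
            )
        )
    return out


def location_comparison_tables(
    metrics: LocationMetricSet, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA table and Tukey table across locations, one block per model."""
    anova_rows, tukey_rows = [], []
    models = sorted({m for m, _ in metrics.values})
    for model in models:
        grp = metrics.group(model)
        f, p = one_way_anova(list(grp.values()))
        anova_rows.append({"model": model, "F": f, "p_value": p})
        for cmp_ in tukey_hsd(grp, alpha=alpha):
            tukey_rows.append(
                {
                    "model": model,
                    "group_1": cmp_.group_1,
                    "group_2": cmp_.group_2,
                    "mean_difference": cmp_.mean_difference,
                    "adjusted_p": cmp_.adjusted_p,
                    "ci_lower": cmp_.ci_lower,
                    "ci_upper": cmp_.ci_upper,
                    "reject": cmp_.reject,
                }
            )
    return pd.DataFrame(anova_rows), pd.DataFrame(tukey_rows)
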