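"""Feature selection: elastic-net ranking, mRMR-FCQ oracle equivalence,
selection profiling and Kneedle knee detection."""

import numpy as np
import pandas as pd
import pytest

from gaitsurface import (
    ENETConfig,
    InvalidConfigError,
    KneeCurve,
    enet_rank,
    incremental_feature_curve,
    kneedle_knee,
    mrmr_score,
    mrmr_select,
    profile_selections,
)
from gaitsurface.features import FeatureMatrix
from gaitsurface.modeling import ModelSpec
from gaitsurface.selection import MRMRSelector

from conftest import planted_matrix

SMALL_ENET = ENETConfig(
    alpha_grid=(0.1, 0.5, 0.9),
    lambda_grid=(1e-3, 1e-2, 1e-1, 1.0),
    seed=0,
)


def _matrix_from_arrays(cols: dict, y) -> FeatureMatrix:
    X = pd.DataFrame(cols)
    y = np.asarray(y, dtype=int)
    return FeatureMatrix(
        X=X,
        y=y,
        subject_ids=np.array(["P1"] * len(X), dtype=object),
    )


# ---------------------------------------------------------------------------
# elastic net


def test_enet_ranks_sole_informative_feature_first():
    rng = np.random.default_rng(0)
    n = 200
    y = (rng.random(n) < 0.5).astype(int)
    cols = {f"noise{i:02d}": rng.normal(size=n) for i in range(39)}
    cols["aaa_signal"] = y + rng.normal(0.0, 0.05, size=n)
    fm = _matrix_from_arrays(cols, y)
    top = enet_rank(fm, SMALL_ENET)
    assert len(top) == 10
    assert top[0] == "aaa_signal"


def test_enet_full_shrinkage_falls_back_alphabetical():
    rng = np.random.default_rng(1)
    n = 100
    y = (rng.random(n) < 0.5).astype(int)
    cols = {f"f{i:02d}": rng.normal(size=n) for i in range(15)}
    fm = _matrix_from_arrays(cols, y)
    cfg = ENETConfig(alpha_grid=(1.0,), lambda_grid=(10.0,), seed=0)
    top = enet_rank(fm, cfg)
    assert top == sorted(cols)[:10]


def test_enet_grouping_effect_on_duplicated_feature():
    """The ridge component spreads weight over identical columns."""
    rng = np.random.default_rng(2)
    n = 300
    y = (rng.random(n) < 0.5).astype(int)
    signal = y + rng.normal(0.0, 0.3, size=n)
    cols = {"dupA": signal, "dupB": signal.copy()}
    cols.update({f"noise{i}": rng.normal(size=n) for i in range(6)})
    fm = _matrix_from_arrays(cols, y)
    from gaitsurface.selection import ElasticNetRanker

    ranker = ElasticNetRanker(
        alpha_grid=(0.2,), lambda_grid=(1e-2,), random_state=0
    )
    ranker.fit(fm.X, fm.y)
    ca, cb = ranker.coef_["dupA"], ranker.coef_["dupB"]
    assert abs(ca) > 0 and abs(cb) > 0
    assert abs(ca - cb) < 0.1 * abs(ca)


def test_enet_empty_matrix_rejected():
    fm = planted_matrix(n=40, seed=0)[0]
    empty = FeatureMatrix(
        X=fm.X.iloc[:0],
        y=fm.y[:0],
        subject_ids=fm.subject_ids[:0],
        labels=fm.labels[:0],
    )
    with pytest.raises(InvalidConfigError):
        enet_rank(empty, SMALL_ENET)


# ---------------------------------------------------------------------------
# mRMR


def _anova_f_oracle(x, y):
    """Textbook two-group one-way ANOVA F."""
    x = np.asarray(x, dtype=float)
    groups = [x[y == c] for c in np.unique(y)]
    grand = x.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(x) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def test_mrmr_score_empty_set_equals_f_statistic():
    y = np.array([0] * 10 + [1] * 10)
    rng = np.random.default_rng(3)
    x = y + rng.normal(0.0, 0.5, size=20)
    assert mrmr_score(x, y, []) == pytest.approx(_anova_f_oracle(x, y))


def test_mrmr_score_perfect_redundancy_divides_by_one():
    y = np.array([0] * 10 + [1] * 10)
    rng = np.random.default_rng(4)
    x = y + rng.normal(0.0, 0.5, size=20)
    assert mrmr_score(x, y, [x.copy()]) == pytest.approx(
        _anova_f_oracle(x, y)
    )


def test_mrmr_score_constant_candidate_is_zero():
    y = np.array([0, 0, 1, 1])
    assert mrmr_score(np.ones(4), y, []) == 0.0


def test_mrmr_score_length_mismatch():
    with pytest.raises(InvalidConfigError):
        mrmr_score(np.ones(3), np.array([0, 1]), [])


def _brute_force_mrmr(X: pd.DataFrame, y, k):
    """Literal greedy F/mean-correlation quotient, recomputed from scratch."""
    remaining = list(X.columns)
    selected = []
    while len(selected) < k:
        best_name, best_score = None, None
        for name in sorted(remaining):
            x = X[name].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                score = 0.0
            else:
                f = _anova_f_oracle(x, y)
                if selected:
                    rho = np.mean(
                        [
                            abs(np.corrcoef(X[s].to_numpy(), x)[0, 1])
                            for s in selected
                        ]
                    )
                    score = f / max(rho, 1e-12)
                else:
                    score = f
            if best_score is None or score > best_score:
                best_name, best_score = name, score
        selected.append(best_name)
        remaining.remove(best_name)
    return selected


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_mrmr_select_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 200
    y = (rng.random(n) < 0.4).astype(int)
    base = y + rng.normal(0.0, 1.0, size=n)
    cols = {
        "a_sig": base,
        "b_cor": base + rng.normal(0.0, 0.4, size=n),
        "c_ind": y + rng.normal(0.0, 2.0, size=n),
        "d_noise": rng.normal(size=n),
        "e_noise": rng.normal(size=n),
    }
    fm = _matrix_from_arrays(cols, y)
    assert mrmr_select(fm, 5) == _brute_force_mrmr(fm.X, y, 5)


def test_mrmr_first_pick_is_max_f(ankle_features):
    from sklearn.feature_selection import f_classif

    f, _ = f_classif(ankle_features.X.to_numpy(), ankle_features.y)
    best = ankle_features.feature_names[int(np.argmax(f))]
    assert mrmr_select(ankle_features, 1)[0] == best


def test_mrmr_k_equals_p_is_permutation(ankle_features):
    out = mrmr_select(ankle_features, 40)
    assert sorted(out) == sorted(ankle_features.feature_names)


def test_mrmr_k_too_large(ankle_features):
    with pytest.raises(InvalidConfigError):
        mrmr_select(ankle_features, 41)


def test_selectors_invariant_to_column_order():
    fm, _ = planted_matrix(n=160, seed=5)
    reversed_fm = FeatureMatrix(
        X=fm.X[list(fm.X.columns)[::-1]],
        y=fm.y,
        subject_ids=fm.subject_ids,
        labels=fm.labels,
    )
    assert mrmr_select(fm, 8) == mrmr_select(reversed_fm, 8)
    assert enet_rank(fm, SMALL_ENET) == enet_rank(reversed_fm, SMALL_ENET)


# ---------------------------------------------------------------------------
# profiling


def test_profile_counts_and_order():
    lists = [[f"f{i}" for i in range(10)]] * 12
    profile = profile_selections(lists)
    assert set(profile.counts.values()) == {12}
    assert len(profile.order) == 10
    # a feature in 7 of 12 lists
    lists = [[f"f{i}" for i in range(10)] for _ in range(5)]
    lists += [["g0"] + [f"f{i}" for i in range(1, 10)] for _ in range(7)]
    profile = profile_selections(lists)
    assert profile.counts["g0"] == 7
    assert profile.counts["f0"] == 5
    # profile can be longer than 10 when iterations disagree
    assert len(profile.order) == 11


def test_profile_rejects_short_lists():
    with pytest.raises(InvalidConfigError):
        profile_selections([["a", "b"]])


def test_profile_batches_group_equal_counts():
    lists = [["a", "b"] + [f"f{i}" for i in range(8)]] * 12
    lists[0] = ["a", "b"] + [f"g{i}" for i in range(8)]
    profile = profile_selections(lists)
    batches = profile.batches()
    assert batches[0] == ["a", "b"]  # count 12
    sizes = [len(b) for b in batches]
    assert sum(sizes) == len(profile.order)


# ---------------------------------------------------------------------------
# kneedle


def _brute_force_knee(x, y, sensitivity=1.0):
    """Difference-curve maximization on the normalized curve."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xn = (x - x.min()) / (x.max() - x.min())
    yn = (y - y.min()) / (y.max() - y.min()) if np.ptp(y) else np.zeros_like(y)
    d = yn - xn
    candidates = [
        i for i in range(1, len(d) - 1) if d[i] > d[i - 1] and d[i] >= d[i + 1]
    ]
    for pos, i in enumerate(candidates):
        thr = d[i] - sensitivity * np.mean(np.diff(xn))
        stop = candidates[pos + 1] if pos + 1 < len(candidates) else len(d)
        if any(d[j] < thr for j in range(i + 1, stop)):
            return float(x[i])
    return None


def test_kneedle_straight_line_has_no_knee():
    x = np.arange(11, dtype=float)
    assert kneedle_knee(KneeCurve(x=x, y=x / 10.0)) is None


def test_kneedle_concave_curve_matches_oracle():
    x = np.arange(1.0, 18.0)
    y = x ** 0.25
    knee = kneedle_knee(KneeCurve(x=x, y=y))
    assert knee == _brute_force_knee(x, y)
    assert knee is not None


def test_kneedle_plateau_after_eighth_point():
    x = np.arange(1.0, 18.0)
    y = np.minimum(x / 8.0, 1.0) + 0.0001 * x  # steep rise, plateau at 8
    knee = kneedle_knee(KneeCurve(x=x, y=y))
    assert knee == _brute_force_knee(x, y)
    assert knee == pytest.approx(8.0)


def test_kneedle_needs_three_points():
    with pytest.raises(InvalidConfigError):
        kneedle_knee(KneeCurve(x=np.array([1.0, 2.0]), y=np.array([0.1, 0.2])))


# ---------------------------------------------------------------------------
# incremental curve


def test_batch_rule_cumulative_positions():
    """Counts (12, 12, 7, 7, 7) batch as sizes 2 then 3, x = (2, 5)."""
    lists = []
    for i in range(12):
        row = ["a1", "a2"]
        row += ["b1", "b2", "b3"] if i < 7 else ["c1", "c2", "c3"]
        row += [f"pad{j}" for j in range(5)]
        lists.append(row)
    profile = profile_selections(lists)
    sizes = [len(b) for b in profile.batches()]
    # pads count 12 join the first batch; b's (7) and c's (5) follow
    assert profile.counts["a1"] == 12 and profile.counts["b1"] == 7
    assert sizes[0] == 7  # a1, a2 + 5 pads all at count 12
    assert sizes[1] == 3  # the three count-7 features
    assert sizes[2] == 3  # the three count-5 features


def test_incremental_curve_follows_profile_batches():
    fm, _ = planted_matrix(n=150, n_informative=4, n_noise=8, seed=6)
    names = fm.feature_names  # 12 features
    lists = []
    for i in range(12):
        row = list(names[:8])
        row += [names[8 + (i + j) % 4] for j in range(2)]
        lists.append(row)
    profile = profile_selections(lists)
    assert [len(b) for b in profile.batches()] == [8, 4]
    curves = incremental_feature_curve(
        profile,
        fm,
        [ModelSpec(name="LR", seed=0)],
        cv_folds=5,
        cv_repeats=1,
        seed=0,
    )
    curve = curves["LR"]
    assert np.array_equal(curve.x, [8, 12])
    assert np.all((curve.y >= 0) & (curve.y <= 1))


def test_single_batch_curve_has_no_knee():
    lists = [[f"f{i}" for i in range(10)]] * 5
    profile = profile_selections(lists)
    assert len(profile.batches()) == 1
    with pytest.raises(InvalidConfigError):
        kneedle_knee(KneeCurve(x=np.array([10.0]), y=np.array([0.9])))
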