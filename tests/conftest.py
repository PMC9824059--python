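import numpy as np
import pytest

from gaitsurface import (
    FeatureMatrix,
    default_cohort_config,
    simulate_cohort,
)
from gaitsurface.pipeline import extract_cohort_features
from gaitsurface.segmentation import StrideSegment
from gaitsurface.simulate import ANKLE, GOOD, IRREGULAR


def make_stride(
    ml,
    v,
    ap,
    *,
    stride_time=1.0,
    label=GOOD,
    subject="S01",
    start_time=0.0,
    context=None,
):
    """StrideSegment from raw channel arrays (context defaults to empty)."""
    ml = np.asarray(ml, dtype=float)
    v = np.asarray(v, dtype=float)
    ap = np.asarray(ap, dtype=float)
    n = len(v)
    if context is None:
        context = (np.empty(0), np.empty(0), np.empty(0))
    ctx_ml, ctx_v, ctx_ap = (np.asarray(c, dtype=float) for c in context)
    return StrideSegment(
        subject_id=subject,
        start_index=int(start_time * 100),
        end_index=int(start_time * 100) + n,
        start_time=start_time,
        stride_time=stride_time,
        v=v,
        ap=ap,
        ml=ml,
        context_v=ctx_v,
        context_ap=ctx_ap,
        context_ml=ctx_ml,
        surface_label=label,
    )


def constant_stride(ml_val, v_val, ap_val, n=100, **kw):
    return make_stride(
        np.full(n, float(ml_val)),
        np.full(n, float(v_val)),
        np.full(n, float(ap_val)),
        **kw,
    )


@pytest.fixture(scope="session")
def cohort_features():
    """Feature matrices for a 4-subject default cohort, all locations."""
    recs = simulate_cohort(default_cohort_config(4, seed=42))
    return extract_cohort_features(recs)


@pytest.fixture(scope="session")
def ankle_features(cohort_features) -> FeatureMatrix:
    return cohort_features[ANKLE]


def planted_matrix(
    n=240, n_informative=8, n_noise=32, effect=1.0, seed=0
) -> tuple[FeatureMatrix, list[str]]:
    """Feature matrix with planted informative columns (standardized effect).

    Informative columns get a mean shift of ``effect`` SDs for the positive
    class; the rest are pure noise.  Subjects are assigned in blocks so LOSO
    machinery works on it too.
    """
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.35).astype(int)
    import pandas as pd

    names_inf = [f"inf{i:02d}" for i in range(n_informative)]
    names_noise = [f"noise{i:02d}" for i in range(n_noise)]
    cols = {}
    for name in names_inf:
        cols[name] = rng.normal(0.0, 1.0, n) + effect * y
    for name in names_noise:
        cols[name] = rng.normal(0.0, 1.0, n)
    X = pd.DataFrame(cols)
    X = X[sorted(X.columns)]
    block = max(n // 8, 1)
    subjects = np.array([f"P{(i // block) + 1:02d}" for i in range(n)])
    labels = np.where(y == 1, IRREGULAR, GOOD)
    return (
        FeatureMatrix(X=X, y=y, subject_ids=subjects, labels=labels),
        names_inf,
    )
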