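"""Per-stride gait features: 20 base features plus 20 between-stride
variability features (40 per sensor).

Conventions (documented design choices):

* Magnitude features are the MEAN per-sample value over their window — the
  mean Euclidean norm sqrt(ML^2 + V^2 + AP^2) for the VM family, the mean
  absolute value for single-direction variants.  The mean (rather than a sum)
  keeps magnitude features invariant to stride duration, so they carry
  information separate from stride time.
* Windows, as fractions of the stride (heel strike to next heel strike):
  whole stride; initial 5% (early stance); the double-stance window spans
  [-10%, +10%] around the initial heel strike, using pre-stride context
  samples for the negative half (truncated at bout start); the mid-stance
  window is [25%, 35%] of the cycle; heel-strike max/SD features use the
  initial 10%.
* Variability of each base feature is the sample SD over a centered window of
  five strides within the bout, truncated at bout edges; bouts of fewer than
  three strides get variability 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FeatureExtractionError, InvalidConfigError
from .segmentation import StrideSegment
from .simulate import IRREGULAR

BASE_FEATURE_NAMES: tuple[str, ...] = (
    "VM", "VM5", "LVM", "VVM", "AVM",
    "VMD", "LVMD", "VVMD", "AVMD",
    "VM30", "LVM30", "VVM30", "AVM30",
    "LHM", "LHSD", "VHM", "VHSD", "AHM", "AHSD",
    "ST",
)

FEATURE_NAMES: tuple[str, ...] = BASE_FEATURE_NAMES + tuple(
    f"{name}_var" for name in BASE_FEATURE_NAMES
)

MIN_STRIDE_SAMPLES = 20
VARIABILITY_WINDOW = 5  # strides, centered


def extract_base_features(stride: StrideSegment) -> dict[str, float]:
    """The 20 base features of one stride segment."""
    ml, v, ap = stride.ml, stride.v, stride.ap
    n = len(v)
    if n < MIN_STRIDE_SAMPLES:
        raise FeatureExtractionError(
            f"stride of subject {stride.subject_id} starting at sample "
            f"{stride.start_index} has only {n} samples "
            f"(need >= {MIN_STRIDE_SAMPLES})"
        )
    norm = np.sqrt(ml**2 + v**2 + ap**2)

    n5 = max(int(round(0.05 * n)), 1)
    n10 = max(int(round(0.10 * n)), 2)
    lo30, hi30 = int(round(0.25 * n)), int(round(0.35 * n))

    # double-stance window: up to 10% of the stride before the heel strike
    # (from the preceding context) plus the initial 10% after it
    ctx = min(len(stride.context_v), n10)
    d_ml = np.concatenate([stride.context_ml[-ctx:] if ctx else ml[:0], ml[:n10]])
    d_v = np.concatenate([stride.context_v[-ctx:] if ctx else v[:0], v[:n10]])
    d_ap = np.concatenate([stride.context_ap[-ctx:] if ctx else ap[:0], ap[:n10]])
    d_norm = np.sqrt(d_ml**2 + d_v**2 + d_ap**2)

    feats = {
        "VM": float(norm.mean()),
        "VM5": float(norm[:n5].mean()),
        "LVM": float(np.abs(ml).mean()),
        "VVM": float(np.abs(v).mean()),
        "AVM": float(np.abs(ap).mean()),
        "VMD": float(d_norm.mean()),
        "LVMD": float(np.abs(d_ml).mean()),
        "VVMD": float(np.abs(d_v).mean()),
        "AVMD": float(np.abs(d_ap).mean()),
        "VM30": float(norm[lo30:hi30].mean()),
        "LVM30": float(np.abs(ml[lo30:hi30]).mean()),
        "VVM30": float(np.abs(v[lo30:hi30]).mean()),
        "AVM30": float(np.abs(ap[lo30:hi30]).mean()),
        "LHM": float(np.abs(ml[:n10]).max()),
        "LHSD": float(np.std(ml[:n10], ddof=1)),
        "VHM": float(np.abs(v[:n10]).max()),
        "VHSD": float(np.std(v[:n10], ddof=1)),
        "AHM": float(np.abs(ap[:n10]).max()),
        "AHSD": float(np.std(ap[:n10], ddof=1)),
        "ST": float(stride.stride_time),
    }
    return feats


def extract_variability_features(
    ordered_base: list[dict[str, float]],
) -> list[dict[str, float]]:
    """Between-stride variability of each base feature.

    For stride i, the sample SD of each feature over strides [i-2, i+2]
    (truncated at bout edges); bouts of fewer than 3 strides yield zeros.
    """
    n = len(ordered_base)
    half = VARIABILITY_WINDOW // 2
    out: list[dict[str, float]] = []
    if n == 0:
        return out
    table = np.array(
        [[row[name] for name in BASE_FEATURE_NAMES] for row in ordered_base]
    )
    for i in range(n):
        if n < 3:
            sds = np.zeros(len(BASE_FEATURE_NAMES))
        else:
            window = table[max(0, i - half) : i + half + 1]
            sds = np.std(window, axis=0, ddof=1)
        out.append(
            {f"{name}_var": float(sd) for name, sd in zip(BASE_FEATURE_NAMES, sds)}
        )
    return out


@dataclass
class FeatureMatrix:
    """n strides x 40 features, with labels and subject ids.

    ``y`` encodes Irregular as 1 (the positive class).
    """

    X: pd.DataFrame
    y: np.ndarray
    subject_ids: np.ndarray
    labels: np.ndarray = field(default=None)  # original string labels

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.X) != len(self.subject_ids):
            raise InvalidConfigError("X, y and subject_ids must align")
        if self.labels is None:
            self.labels = np.where(np.asarray(self.y) == 1, "Irregular", "Good")
        if self.X.isna().any().any():
            raise InvalidConfigError("feature matrix contains missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(s, None)
        return list(seen)

    def subset(self, rows=None, features=None) -> "FeatureMatrix":
        X = self.X
        y = np.asarray(self.y)
        sids = np.asarray(self.subject_ids)
        labels = np.asarray(self.labels)
        if rows is not None:
            X, y, sids, labels = X.iloc[rows], y[rows], sids[rows], labels[rows]
        if features is not None:
            X = X.loc[:, list(features)]
        return FeatureMatrix(
            X=X.reset_index(drop=True), y=y, subject_ids=sids, labels=labels
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "stride_index": np.arange(self.n),
                "label": self.labels,
            }
        )
        return pd.concat([df, self.X.reset_index(drop=True)], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        meta = {"subject_id", "stride_index", "label"}
        missing = meta - set(df.columns)
        if missing:
            raise InvalidConfigError(f"feature table missing columns {missing}")
        feat_cols = [c for c in df.columns if c not in meta]
        y = (df["label"].to_numpy() == IRREGULAR).astype(int)
        return cls(
            X=df[feat_cols].reset_index(drop=True),
            y=y,
            subject_ids=df["subject_id"].to_numpy(),
            labels=df["label"].to_numpy(),
        )


def build_feature_matrix(strides: list[StrideSegment]) -> FeatureMatrix:
    """Assemble the n x 40 matrix from stride segments.

    Strides are grouped by subject (one bout per subject recording) and
    ordered by time within subject; columns follow the canonical registry:
    the 20 base names then the 20 ``_var`` names.
    """
    if not strides:
        raise InvalidConfigError("cannot build a feature matrix from no strides")
    by_subject: dict[str, list[StrideSegment]] = {}
    for s in strides:
        by_subject.setdefault(s.subject_id, []).append(s)

    rows, y, sids, labels = [], [], [], []
    for subject in sorted(by_subject):
        bout = sorted(by_subject[subject], key=lambda s: s.start_time)
        base = [extract_base_features(s) for s in bout]
        var = extract_variability_features(base)
        for s, b, v in zip(bout, base, var):
            rows.append({**b, **v})
            y.append(1 if s.surface_label == IRREGULAR else 0)
            sids.append(subject)
            labels.append(s.surface_label)
    X = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    return FeatureMatrix(
        X=X,
        y=np.asarray(y, dtype=int),
        subject_ids=np.asarray(sids, dtype=object),
        labels=np.asarray(labels, dtype=object),
    )
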