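"""Sliding-window aggregation of per-stride predictions.

On irregular ground only some strides are visibly disturbed, so a single
stride is a noisy unit of prediction.  Averaging the predicted
irregular-surface probability over k consecutive strides (step one stride)
reduces that noise; the window's ground truth is the majority stride label,
ties going to Irregular (the positive class).  Windows never span subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, UndefinedMetricError
from .modeling import LOSOReport, auc


@dataclass
class WindowPrediction:
    """Aggregated prediction for k consecutive strides of one subject."""

    subject_id: str
    window_start_stride: int
    k: int
    probability: float
    window_label: int  # 1 = Irregular


def aggregate_stride_predictions(
    probs: Sequence[float],
    labels: Sequence[int],
    k: int,
    subject_id: str = "",
) -> list[WindowPrediction]:
    """n - k + 1 sliding windows over one subject's time-ordered strides."""
    if k < 1:
        raise InvalidConfigError("k must be >= 1")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(probs) != len(labels):
        raise InvalidConfigError("probs and labels differ in length")
    n = len(probs)
    if k > n:
        warnings.warn(
            f"subject {subject_id!r}: k={k} exceeds {n} strides; no windows",
            stacklevel=2,
        )
        return []
    out = []
    for start in range(n - k + 1):
        window_probs = probs[start : start + k]
        window_labels = labels[start : start + k]
        n_irr = int(window_labels.sum())
        out.append(
            WindowPrediction(
                subject_id=subject_id,
                window_start_stride=start,
                k=k,
                probability=float(window_probs.mean()),
                window_label=1 if 2 * n_irr >= k else 0,
            )
        )
    return out


def postprocess_curve(
    per_subject_predictions: Mapping[str, tuple[Sequence[float], Sequence[int]]],
    k_values: Sequence[int],
) -> pd.DataFrame:
    """Mean across-subject window AUC for each window length k.

    For every k, windows are built per subject, the AUC is computed over each
    subject's pooled windows, and subject AUCs are averaged.  Subjects whose
    windows are single-class at some k are skipped for that k with a warning.
    At k = 1 the result equals the per-stride LOSO mean AUC.
    """
    rows = []
    for k in k_values:
        subject_aucs = []
        n_windows = 0
        for subject, (probs, labels) in per_subject_predictions.items():
            windows = aggregate_stride_predictions(probs, labels, k, subject)
            if not windows:
                continue
            w_labels = np.array([w.window_label for w in windows])
            w_probs = np.array([w.probability for w in windows])
            n_windows += len(windows)
            try:
                subject_aucs.append(auc(w_labels, w_probs))
            except UndefinedMetricError:
                warnings.warn(
                    f"subject {subject!r}: single-class windows at k={k}; "
                    "skipped",
                    stacklevel=2,
                )
        if not subject_aucs:
            raise UndefinedMetricError(f"no scorable windows at k={k}")
        rows.append(
            {
                "k": int(k),
                "mean_auc": float(np.mean(subject_aucs)),
                "n_subjects": len(subject_aucs),
                "n_windows": n_windows,
            }
        )
    return pd.DataFrame(rows)


def report_to_per_subject(report: LOSOReport) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-subject (probabilities, labels) from a LOSO report's predictions."""
    preds = report.predictions
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for subject, grp in preds.groupby("subject_id", sort=False):
        grp = grp.sort_values("stride_order")
        out[str(subject)] = (
            grp["probability"].to_numpy(),
            grp["label"].to_numpy(),
        )
    return out
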