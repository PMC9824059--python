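"""Axis mapping, heel-strike detection and stride segmentation.

A stride (gait cycle) runs between two consecutive heel strikes of the same
foot.  Heel strikes are detected on the anteroposterior (AP) acceleration of
the ankle sensor, which shows one pronounced peak per stride: the AP channel
is zero-phase low-pass filtered, the dominant stride period is estimated from
the autocorrelation, and peaks are picked with a prominence floor and a
minimum separation tied to that period.  Hip and head recordings of the same
subject are segmented with the ankle-derived heel strikes, since the three
channels are sample-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InvalidConfigError, NoGaitDetectedError
from .simulate import (
    ANKLE,
    GOOD,
    HEAD,
    HIP,
    IRREGULAR,
    AccelerometerRecording,
)

# Detection defaults (overridable per call): zero-phase Butterworth low-pass
# at 10 Hz, peak prominence >= 0.5 x SD of the filtered AP signal, minimum
# peak separation 0.6 x the autocorrelation-estimated stride period.
LOWPASS_CUTOFF_HZ = 10.0
PROMINENCE_FACTOR = 0.5
MIN_SEPARATION_FACTOR = 0.6
PERIOD_SEARCH_RANGE_S = (0.4, 2.5)

# Strides outside this duration window (turns, pauses) are discarded.
STRIDE_TIME_RANGE_S = (0.4, 3.0)

#: Fraction of the stride duration kept as pre-stride context (for features
#: evaluated across the heel strike, e.g. the double-stance window).
CONTEXT_FRACTION = 0.10


@dataclass
class DirectionalSignal:
    """A recording re-expressed in anatomical V / AP / ML directions."""

    timestamps: np.ndarray
    v: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    location: str
    subject_id: str
    sample_labels: np.ndarray
    sampling_rate: float


@dataclass
class StrideSegment:
    """One gait cycle between two consecutive heel strikes."""

    subject_id: str
    start_index: int
    end_index: int
    start_time: float
    stride_time: float
    v: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    context_v: np.ndarray
    context_ap: np.ndarray
    context_ml: np.ndarray
    surface_label: str

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index


def map_axes(recording: AccelerometerRecording) -> DirectionalSignal:
    """Map sensor X/Y/Z axes to V/AP/ML anatomical directions.

    Ankle: X, Y, Z carry V, AP, ML.  Hip and head: X, Y, Z carry V, ML, AP.
    """
    xyz = recording.xyz
    if recording.location == ANKLE:
        v, ap, ml = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    elif recording.location in (HIP, HEAD):
        v, ml, ap = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    else:
        raise InvalidConfigError(f"unknown location {recording.location!r}")
    return DirectionalSignal(
        timestamps=recording.timestamps,
        v=np.asarray(v, dtype=float),
        ap=np.asarray(ap, dtype=float),
        ml=np.asarray(ml, dtype=float),
        location=recording.location,
        subject_id=recording.subject_id,
        sample_labels=recording.sample_labels,
        sampling_rate=recording.sampling_rate,
    )


def _estimate_stride_period(
    x: np.ndarray, fs: float, lag_range: tuple[float, float]
) -> float:
    """Dominant period from the autocorrelation peak within ``lag_range``."""
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise NoGaitDetectedError("signal has no variance; no gait detected")
    ac = sps.correlate(x, x, mode="full")[len(x) - 1 :]
    lo = int(lag_range[0] * fs)
    hi = min(int(lag_range[1] * fs) + 1, len(ac))
    if hi - lo < 3:
        raise NoGaitDetectedError("signal too short for period estimation")
    # periodic gait shows a genuine local autocorrelation peak at the stride
    # lag; noise autocorrelation decays without one and is rejected
    peaks, _ = sps.find_peaks(ac[lo:hi])
    peaks = [p for p in peaks if ac[lo + p] >= 0.15 * ac[0]]
    if not peaks:
        raise NoGaitDetectedError(
            "no autocorrelation peak in the stride-period range"
        )
    best = max(peaks, key=lambda p: ac[lo + p])
    return (lo + best) / fs


def detect_heel_strikes(
    signal: DirectionalSignal,
    *,
    cutoff_hz: float = LOWPASS_CUTOFF_HZ,
    prominence_factor: float = PROMINENCE_FACTOR,
    min_separation_factor: float = MIN_SEPARATION_FACTOR,
) -> np.ndarray:
    """Heel-strike sample indices from the AP channel (ankle sensor).

    Pipeline: zero-phase low-pass filter -> autocorrelation period estimate
    -> prominence/separation-constrained local maxima.
    """
    fs = signal.sampling_rate
    ap = np.asarray(signal.ap, dtype=float)
    if len(ap) < 3 * fs:
        raise NoGaitDetectedError("need at least 3 s of signal")
    sos = sps.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, ap)
    period = _estimate_stride_period(filtered, fs, PERIOD_SEARCH_RANGE_S)
    peaks, _ = sps.find_peaks(
        filtered,
        prominence=prominence_factor * filtered.std(),
        distance=max(int(min_separation_factor * period * fs), 1),
    )
    if len(peaks) == 0:
        raise NoGaitDetectedError("no peaks above the prominence floor")
    return peaks.astype(int)


def segment_strides(
    signal: DirectionalSignal,
    heel_strikes: np.ndarray,
    *,
    stride_time_range: tuple[float, float] = STRIDE_TIME_RANGE_S,
) -> list[StrideSegment]:
    """One segment per consecutive heel-strike pair, duration-filtered.

    The surface label of a stride is the majority of its per-sample labels;
    ties go to Irregular (the positive class).  Fewer than two heel strikes
    yield an empty list.
    """
    hs = np.asarray(heel_strikes, dtype=int)
    if len(hs) < 2:
        return []
    t = signal.timestamps
    segments: list[StrideSegment] = []
    lo_t, hi_t = stride_time_range
    for start, end in zip(hs[:-1], hs[1:]):
        if end <= start:
            raise InvalidConfigError("heel strikes must be strictly increasing")
        stride_time = float(t[end] - t[start])
        if not (lo_t < stride_time < hi_t):
            continue
        n_ctx = int(np.floor(CONTEXT_FRACTION * (end - start)))
        ctx_lo = max(start - n_ctx, 0)
        labels = signal.sample_labels[start:end]
        n_irr = int(np.sum(labels == IRREGULAR))
        label = IRREGULAR if 2 * n_irr >= len(labels) else GOOD
        segments.append(
            StrideSegment(
                subject_id=signal.subject_id,
                start_index=int(start),
                end_index=int(end),
                start_time=float(t[start]),
                stride_time=stride_time,
                v=signal.v[start:end].copy(),
                ap=signal.ap[start:end].copy(),
                ml=signal.ml[start:end].copy(),
                context_v=signal.v[ctx_lo:start].copy(),
                context_ap=signal.ap[ctx_lo:start].copy(),
                context_ml=signal.ml[ctx_lo:start].copy(),
                surface_label=label,
            )
        )
    return segments


def segment_recording(
    recording: AccelerometerRecording,
    heel_strikes: np.ndarray | None = None,
) -> list[StrideSegment]:
    """Convenience: map axes and segment; detects heel strikes if not given."""
    signal = map_axes(recording)
    if heel_strikes is None:
        heel_strikes = detect_heel_strikes(signal)
    return segment_strides(signal, heel_strikes)
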