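"""Synthetic cohorts of labelled tri-axial walking recordings.

The generator emulates the statistical structure a wearable-sensor surface
classifier has to cope with: subjects walk with their own stride period and
signal amplitude; each stride repeats a smooth three-channel gait template
(vertical heel-strike impulse and mid-stance trough, a pronounced once-per-
stride anteroposterior peak that anchors stride segmentation, low-amplitude
mediolateral sway); irregular surfaces perturb stride timing and pulse
amplitudes and intermittently interrupt a stride (inflated period plus an
extra mediolateral/vertical transient) while the surface label stays
Irregular throughout the segment.

One event stream per subject drives all three sensor locations, so the three
recordings of a subject are sample-aligned and share heel-strike ground truth;
only the sensor noise differs per location.  Body acceleration is attenuated
at the hip and head relative to the ankle, whereas the additive sensor noise
is not — this is what makes the surface effect hardest to read far from the
ground.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .errors import InvalidConfigError

GOOD = "Good"
IRREGULAR = "Irregular"
SURFACE_LABELS = (GOOD, IRREGULAR)

ANKLE = "ankle"
HIP = "hip"
HEAD = "head"
LOCATIONS = (ANKLE, HIP, HEAD)
_LOCATION_INDEX = {loc: i for i, loc in enumerate(LOCATIONS)}

#: Gait template: per channel, tuples of (phase in [0, 1), amplitude in g,
#: width as a fraction of the stride period).  Calibration constants chosen to
#: give a single dominant AP peak per stride at the heel strike, a vertical
#: impact + mid-stance trough, and gentle mediolateral sway.
GAIT_TEMPLATE: Mapping[str, tuple[tuple[float, float, float], ...]] = {
    "v": ((0.03, 0.85, 0.025), (0.30, -0.45, 0.09), (0.62, 0.35, 0.05)),
    "ap": ((0.00, 1.00, 0.022), (0.55, -0.35, 0.06)),
    "ml": ((0.25, 0.18, 0.12), (0.75, -0.18, 0.12)),
}

#: Extra pulses rendered for an interrupted stride (stumble-like transient).
INTERRUPT_TRANSIENT: Mapping[str, tuple[tuple[float, float, float], ...]] = {
    "v": ((0.50, 0.55, 0.04),),
    "ml": ((0.48, 0.45, 0.05),),
}

#: Period inflation factor applied to interrupted strides (>= 1.2 by design).
INTERRUPT_PERIOD_FACTOR = 1.25

#: Natural gait is nonstationary: a slow AR(1) "gait state" per subject
#: modulates the stride-timing jitter CV and the pulse-amplitude perturbation
#: SD multiplicatively (factor exp(gain * state)).  Stretches of good-surface
#: walking can therefore look locally variable and calm stretches of
#: irregular walking locally steady, which is what keeps single strides from
#: being trivially classifiable.
GAIT_STATE_RHO = 0.8
GAIT_STATE_GAIN = 0.7

DEFAULT_SAMPLING_RATE = 100.0
DEFAULT_NOISE_SD = 0.05
DEFAULT_ATTENUATION = {ANKLE: 1.0, HIP: 0.5, HEAD: 0.3}

#: Additive sensor noise is white noise of SD ``noise_sd`` plus baseline
#: wander (low-pass-filtered noise, cutoff below the stride rate) of the
#: same SD.  The wander does not average out within a stride, so it sets the
#: noise floor that attenuated body acceleration at the hip and head has to
#: beat.
BASELINE_WANDER_RATIO = 1.0
BASELINE_WANDER_CUTOFF_HZ = 0.8

#: Surface-induced amplitude deviations and interrupt transients attenuate by
#: ``attenuation ** DEVIATION_ATTENUATION_EXPONENT`` on top of the overall
#: amplitude attenuation: impact-related content is damped by soft tissue
#: more steeply than the carrier gait pattern.
DEVIATION_ATTENUATION_EXPONENT = 1.75

#: 120 s per subject split 65:35 between Good and Irregular time, with four
#: short irregular stretches interspersed along the walk; the course starts
#: and ends on good pavement as a real walking path would.
DEFAULT_SURFACE_SEQUENCE: tuple[tuple[str, float], ...] = (
    (GOOD, 15.6), (IRREGULAR, 10.5),
    (GOOD, 15.6), (IRREGULAR, 10.5),
    (GOOD, 15.6), (IRREGULAR, 10.5),
    (GOOD, 15.6), (IRREGULAR, 10.5),
    (GOOD, 15.6),
)


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject gait parameters (random effects of the cohort).

    ``timing_variability_scale`` multiplies the surface-specific stride-period
    jitter CV for this subject: some people are naturally steadier walkers
    than others, which is what makes leave-one-subject-out generalization a
    real test rather than a formality.
    """

    subject_id: str
    base_stride_period: float = 1.10  # seconds
    amplitude_scale: float = 1.0
    noise_sd: float = DEFAULT_NOISE_SD  # g
    timing_variability_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.6 < self.base_stride_period < 2.0):
            raise InvalidConfigError(
                f"base_stride_period must lie in (0.6, 2.0) s, got "
                f"{self.base_stride_period}"
            )
        if self.amplitude_scale <= 0:
            raise InvalidConfigError("amplitude_scale must be > 0")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if self.timing_variability_scale <= 0:
            raise InvalidConfigError("timing_variability_scale must be > 0")


@dataclass(frozen=True)
class SurfaceEffect:
    """How a surface type perturbs the gait of every subject."""

    period_jitter_cv: float
    amplitude_perturb_sd: float
    interrupt_prob: float
    location_attenuation: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTENUATION)
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.interrupt_prob <= 1.0):
            raise InvalidConfigError("interrupt_prob must lie in [0, 1]")
        att = self.location_attenuation
        missing = set(LOCATIONS) - set(att)
        if missing:
            raise InvalidConfigError(f"location_attenuation missing {missing}")
        if att[ANKLE] != 1.0:
            raise InvalidConfigError("location_attenuation[ankle] must be 1.0")
        for loc in (HIP, HEAD):
            if not (0.0 <= att[loc] <= 1.0):
                raise InvalidConfigError(
                    f"location_attenuation[{loc}] must lie in [0, 1]"
                )


#: Default surface effects.  Timing defaults: stride-period CV 2% on good
#: pavement vs 6% plus intermittent interruptions (p = 0.3) on irregular
#: ground.  Amplitude defaults are calibration constants: pulse-amplitude
#: perturbation CV 5% (good) vs 25% (irregular).
def good_surface_effect() -> SurfaceEffect:
    return SurfaceEffect(period_jitter_cv=0.02, amplitude_perturb_sd=0.05,
                         interrupt_prob=0.0)


def irregular_surface_effect() -> SurfaceEffect:
    return SurfaceEffect(period_jitter_cv=0.06, amplitude_perturb_sd=0.25,
                         interrupt_prob=0.3)


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort; same config => same cohort."""

    subjects: tuple[SubjectParams, ...]
    surface_sequence: tuple[tuple[str, float], ...] = DEFAULT_SURFACE_SEQUENCE
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    seed: int = 0
    good_effect: SurfaceEffect = field(default_factory=good_surface_effect)
    irregular_effect: SurfaceEffect = field(
        default_factory=irregular_surface_effect
    )

    def __post_init__(self) -> None:
        if len(self.subjects) < 2:
            raise InvalidConfigError("a cohort needs at least 2 subjects")
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling_rate must be positive")
        for label, duration in self.surface_sequence:
            if label not in SURFACE_LABELS:
                raise InvalidConfigError(f"unknown surface label {label!r}")
            if duration <= 0:
                raise InvalidConfigError("segment durations must be positive")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def effect_for(self, label: str) -> SurfaceEffect:
        return self.good_effect if label == GOOD else self.irregular_effect


@dataclass
class AccelerometerRecording:
    """Uniformly sampled tri-axial recording with per-sample surface labels."""

    timestamps: np.ndarray  # seconds, strictly increasing, uniform
    xyz: np.ndarray  # n_samples x 3, g
    location: str
    subject_id: str
    sample_labels: np.ndarray  # of GOOD / IRREGULAR strings
    sampling_rate: float
    truth_heel_strikes: np.ndarray | None = None  # sample indices (simulator)

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        if self.xyz.shape != (n, 3) or len(self.sample_labels) != n:
            raise InvalidConfigError(
                "timestamps, xyz rows and sample_labels must have equal length"
            )


def default_cohort_config(
    n_subjects: int, seed: int, between_subject_scale: float = 1.0
) -> CohortConfig:
    """Cohort config with documented defaults.

    Subject random effects: base stride period ~ Normal(1.10 s, 0.05 s)
    (clipped to the admissible range), amplitude scale ~ Normal(1.0, 0.12)
    clipped below at 0.5, timing-variability scale ~ LogNormal(0, 0.4).
    ``between_subject_scale`` multiplies all three random-effect SDs (used
    to stress-test subject-wise generalizability).  Surface schedule: 120 s
    per subject, 65:35 Good:Irregular.  Sampling rate 100 Hz.
    """
    if n_subjects < 2:
        raise InvalidConfigError("n_subjects must be >= 2")
    if between_subject_scale <= 0:
        raise InvalidConfigError("between_subject_scale must be > 0")
    rng = np.random.default_rng(seed)
    bss = between_subject_scale
    subjects = []
    for i in range(n_subjects):
        period = float(np.clip(rng.normal(1.10, 0.05 * bss), 0.75, 1.6))
        amp = float(np.clip(rng.normal(1.0, 0.12 * bss), 0.5, None))
        tvs = float(np.clip(rng.lognormal(0.0, 0.4 * bss), 0.45**bss, 2.2**bss))
        subjects.append(
            SubjectParams(
                subject_id=f"S{i + 1:02d}",
                base_stride_period=period,
                amplitude_scale=amp,
                timing_variability_scale=tvs,
            )
        )
    return CohortConfig(subjects=tuple(subjects), seed=seed)


def null_cohort_config(n_subjects: int, seed: int) -> CohortConfig:
    """Config whose irregular effect equals the good effect (negative control).

    Surface labels are then statistically independent of the signal, so any
    downstream classifier should score at chance.
    """
    cfg = default_cohort_config(n_subjects, seed)
    return dataclasses.replace(cfg, irregular_effect=cfg.good_effect)


# ---------------------------------------------------------------------------
# rendering


def _segment_bounds(
    schedule: Sequence[tuple[SurfaceEffect, str, float]],
) -> tuple[np.ndarray, list[str], list[SurfaceEffect]]:
    edges = [0.0]
    labels, effects = [], []
    for eff, label, duration in schedule:
        if duration <= 0:
            raise InvalidConfigError("segment durations must be positive")
        if label not in SURFACE_LABELS:
            raise InvalidConfigError(f"unknown surface label {label!r}")
        edges.append(edges[-1] + float(duration))
        labels.append(label)
        effects.append(eff)
    return np.asarray(edges), labels, effects


def _draw_events(
    params: SubjectParams,
    schedule: Sequence[tuple[SurfaceEffect, str, float]],
    rng: np.random.Generator,
) -> list[dict]:
    """Stride-event stream shared by all sensor locations of a subject."""
    edges, labels, effects = _segment_bounds(schedule)
    total = float(edges[-1])
    events: list[dict] = []
    t = 0.0
    # stationary initialization: no warm-up artifact at the bout start
    gait_state = float(rng.normal())
    innovation_sd = float(np.sqrt(1.0 - GAIT_STATE_RHO**2))
    while t < total:
        seg = int(np.searchsorted(edges, t, side="right")) - 1
        seg = min(seg, len(labels) - 1)
        eff = effects[seg]
        gait_state = GAIT_STATE_RHO * gait_state + innovation_sd * rng.normal()
        state_factor = float(np.exp(GAIT_STATE_GAIN * gait_state))
        jitter_cv = (
            eff.period_jitter_cv
            * params.timing_variability_scale
            * state_factor
        )
        jitter = rng.normal(0.0, jitter_cv) if jitter_cv else 0.0
        period = params.base_stride_period * (1.0 + jitter)
        interrupted = bool(rng.random() < eff.interrupt_prob)
        if interrupted:
            period *= INTERRUPT_PERIOD_FACTOR
        perturb_sd = eff.amplitude_perturb_sd * state_factor
        stride_amp = 1.0 + (
            rng.normal(0.0, perturb_sd) if perturb_sd else 0.0
        )
        # independent per-pulse amplitude perturbation (within-stride shape
        # irregularity); drawn for every template pulse in channel order
        n_pulses = sum(len(p) for p in GAIT_TEMPLATE.values())
        pulse_amp = 1.0 + (
            rng.normal(0.0, perturb_sd, size=n_pulses)
            if eff.amplitude_perturb_sd
            else np.zeros(n_pulses)
        )
        events.append(
            {
                "t": t,
                "period": period,
                "effect": eff,
                "label": labels[seg],
                "interrupted": interrupted,
                "stride_amp_dev": stride_amp - 1.0,
                "pulse_amp_dev": pulse_amp - 1.0,
            }
        )
        t += period
    return events


def _render_channel(
    out: np.ndarray,
    pulses,
    t0: float,
    period: float,
    amp: float,
    pulse_amps,
    fs: float,
) -> None:
    n = len(out)
    for (phase, a, width), pa in zip(pulses, pulse_amps):
        center = t0 + phase * period
        sigma = max(width * period, 1.5 / fs)
        lo = max(int((center - 4 * sigma) * fs), 0)
        hi = min(int((center + 4 * sigma) * fs) + 1, n)
        if lo >= hi:
            continue
        tt = np.arange(lo, hi) / fs
        out[lo:hi] += a * amp * pa * np.exp(-0.5 * ((tt - center) / sigma) ** 2)


def simulate_recording(
    params: SubjectParams,
    effect_schedule: Sequence[tuple[SurfaceEffect, str, float]],
    location: str,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    seed: int = 0,
) -> AccelerometerRecording:
    """Render one recording for one subject at one sensor location.

    The stride-event stream (timing, amplitude multipliers, interruptions) is
    drawn from ``seed`` alone, so calling this with the same seed for the
    three locations yields sample-aligned recordings sharing heel-strike
    ground truth; sensor noise is drawn from a location-salted stream.
    """
    if location not in LOCATIONS:
        raise InvalidConfigError(f"unknown location {location!r}")
    if sampling_rate <= 0:
        raise InvalidConfigError("sampling_rate must be positive")
    fs = float(sampling_rate)
    rng_events = np.random.default_rng(seed)
    rng_noise = np.random.default_rng([seed, _LOCATION_INDEX[location], 1])

    events = _draw_events(params, effect_schedule, rng_events)
    edges, labels, _ = _segment_bounds(effect_schedule)
    total = float(edges[-1])
    n = int(round(total * fs))
    timestamps = np.arange(n) / fs

    channels = {"v": np.zeros(n), "ap": np.zeros(n), "ml": np.zeros(n)}
    heel_strikes = []
    for ev in events:
        att = ev["effect"].location_attenuation[location]
        dev_att = att ** DEVIATION_ATTENUATION_EXPONENT
        stride_amp = max(1.0 + dev_att * ev["stride_amp_dev"], 0.1)
        amp = params.amplitude_scale * att * stride_amp
        pulse_amp = np.maximum(1.0 + dev_att * ev["pulse_amp_dev"], 0.1)
        idx = int(round(ev["t"] * fs))
        if idx < n:
            heel_strikes.append(idx)
        offset = 0
        for ch in ("v", "ap", "ml"):
            pulses = GAIT_TEMPLATE[ch]
            _render_channel(
                channels[ch], pulses, ev["t"], ev["period"], amp,
                pulse_amp[offset:offset + len(pulses)], fs,
            )
            offset += len(pulses)
        if ev["interrupted"]:
            for ch, pulses in INTERRUPT_TRANSIENT.items():
                _render_channel(
                    channels[ch], pulses, ev["t"], ev["period"],
                    params.amplitude_scale * att * dev_att,
                    np.ones(len(pulses)), fs,
                )

    if params.noise_sd > 0:
        sos = sps.butter(
            2, BASELINE_WANDER_CUTOFF_HZ, btype="low", fs=fs, output="sos"
        )
        # pad the wander noise before zero-phase filtering and trim the
        # centre so the filter's edge transients never reach the recording
        pad = int(10.0 * fs / BASELINE_WANDER_CUTOFF_HZ)
        for ch in channels:
            channels[ch] += rng_noise.normal(0.0, params.noise_sd, size=n)
            raw = rng_noise.normal(0.0, 1.0, size=n + 2 * pad)
            wander = sps.sosfiltfilt(sos, raw)[pad : pad + n]
            sd = wander.std()
            if sd > 0:
                channels[ch] += (
                    BASELINE_WANDER_RATIO * params.noise_sd / sd
                ) * wander

    sample_labels = np.empty(n, dtype=object)
    seg_idx = np.clip(
        np.searchsorted(edges, timestamps, side="right") - 1, 0, len(labels) - 1
    )
    for i, lab in enumerate(labels):
        sample_labels[seg_idx == i] = lab

    xyz = _pack_axes(channels, location)
    return AccelerometerRecording(
        timestamps=timestamps,
        xyz=xyz,
        location=location,
        subject_id=params.subject_id,
        sample_labels=sample_labels,
        sampling_rate=fs,
        truth_heel_strikes=np.asarray(heel_strikes, dtype=int),
    )


def _pack_axes(channels: Mapping[str, np.ndarray], location: str) -> np.ndarray:
    # Sensor frames: ankle X,Y,Z = V, AP, ML; hip and head X,Y,Z = V, ML, AP.
    if location == ANKLE:
        cols = (channels["v"], channels["ap"], channels["ml"])
    else:
        cols = (channels["v"], channels["ml"], channels["ap"])
    return np.column_stack(cols)


def simulate_cohort(config: CohortConfig) -> list[AccelerometerRecording]:
    """Simulate one recording per location per subject (3 x n_subjects).

    The three recordings of a subject share one stride-event stream, so their
    sample labels and true heel strikes are identical — the channels arrive
    pre-aligned, standing in for physical-sensor timestamp synchronization.
    """
    schedule = [
        (config.effect_for(label), label, duration)
        for label, duration in config.surface_sequence
    ]
    subject_seeds = (
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 2718]).generate_state(
            config.n_subjects
        )
        & 0x7FFFFFFF
    )
    recordings = []
    for params, sseed in zip(config.subjects, subject_seeds):
        for location in LOCATIONS:
            recordings.append(
                simulate_recording(
                    params,
                    schedule,
                    location,
                    sampling_rate=config.sampling_rate,
                    seed=int(sseed),
                )
            )
    return recordings
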