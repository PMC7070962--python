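"""Synthetic two-device drowsiness recordings.

Emulates the statistical structure of a 45-min partially automated
simulator drive: each subject carries a latent 6-level drowsiness
trajectory over nine 5-min intervals (rising on average to about minute
30, dipping, then rising again at the end), and the trajectory drives
the autonomic structure of the inter-beat intervals. Drowsiness is
encoded as parasympathetic dominance: higher drowsiness levels raise
the mean RR interval and the amplitude of the high-frequency (0.25 Hz)
modulation relative to the low-frequency (0.10 Hz) one, lowering LF/HF.

An ECG-grade series is generated beat by beat; the wristband-grade
series is derived from it by dropping beats, quantising beat times to
the device's 1/64-s sampling grid, and jittering intervals. Observer
ratings (two raters with independent integer noise) and micro-sleep
events (state-dependent Poisson process, shifted-exponential closure
durations) complete the bundle.

All randomness flows from one master seed through named substreams, so
a cohort is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .ground_truth import (
    INTERVAL_LENGTH_S,
    N_INTERVALS,
    MicroSleepEvent,
    RatingRecord,
)
from .iodata import ECG, WRISTBAND, IBISeries

DRIVE_DURATION_S = N_INTERVALS * INTERVAL_LENGTH_S  # 45 min

LF_TONE_HZ = 0.10
HF_TONE_HZ = 0.25


@dataclass(frozen=True)
class SubjectModel:
    """Per-subject generative parameters.

    State-dependent quantities are linear in (level - 1): drowsy states
    raise meanRR by ``state_shift_ms`` per level and the HF amplitude by
    ``hf_amp_slope`` per level, emulating parasympathetic dominance.
    """

    subject_id: str
    baseline_meanRR: float = 900.0  # ms
    subject_offset: float = 0.0  # ms, inter-driver variance
    state_shift_ms: float = 10.0  # meanRR increase per drowsiness level
    drowsy_shift_ms: float = 25.0  # extra meanRR shift once level >= 4
    lf_amp: float = 30.0  # ms, LF tone amplitude (alert)
    lf_amp_slope: float = -3.0  # per level: sympathetic withdrawal
    hf_amp: float = 10.0  # ms, HF tone amplitude (alert)
    hf_amp_slope: float = 4.0  # per level: parasympathetic rise
    drowsy_hf_boost: float = 15.0  # extra HF amplitude once level >= 4
    noise_sd: float = 15.0  # ms, beat-to-beat Gaussian noise
    hrv_scale: float = 1.0  # per-subject multiplier on amplitudes and noise
    microsleep_rate_per_min: float = 1.5  # in intervals with level >= 4

    def __post_init__(self) -> None:
        if not 600.0 <= self.baseline_meanRR <= 1200.0:
            raise ValueError(f"baseline_meanRR {self.baseline_meanRR} outside [600, 1200] ms")
        if self.lf_amp < 0 or self.hf_amp < 0 or self.noise_sd < 0 or self.hrv_scale <= 0:
            raise ValueError("amplitudes and noise_sd must be >= 0, hrv_scale > 0")

    def amps_at(self, level: int) -> tuple[float, float]:
        drowsy = level >= 4
        lf = max(self.lf_amp + self.lf_amp_slope * (level - 1), 0.0) * self.hrv_scale
        hf = max(self.hf_amp + self.hf_amp_slope * (level - 1)
                 + (self.drowsy_hf_boost if drowsy else 0.0), 0.0) * self.hrv_scale
        return lf, hf

    def mean_rr_at(self, level: int) -> float:
        """State-dependent mean RR: a per-level gradient plus a distinct
        parasympathetic-dominance shift once the state is drowsy."""
        return (self.baseline_meanRR + self.subject_offset
                + self.state_shift_ms * (level - 1)
                + (self.drowsy_shift_ms if level >= 4 else 0.0))


@dataclass(frozen=True)
class DegradationSpec:
    """Wristband-grade degradation of an ECG-grade series."""

    beat_drop_prob: float = 0.10
    time_quantum: float = 1.0 / 64.0  # s, PPG sampling grid
    jitter_sd: float = 4.0  # ms

    def __post_init__(self) -> None:
        if not 0.0 <= self.beat_drop_prob < 1.0:
            raise ValueError("beat_drop_prob must be in [0, 1)")
        if self.time_quantum < 0 or self.jitter_sd < 0:
            raise ValueError("time_quantum and jitter_sd must be >= 0")


#: population mean drowsiness path over the nine intervals: rising to
#: ~minute 30 (interval 5), dipping over minutes 30-40, rising at the end
MEAN_LEVEL_PATH = np.array([1.0, 1.5, 2.0, 2.5, 3.2, 4.0, 3.4, 3.0, 3.6])


def generate_trajectory(seed: int | np.random.Generator, drift: float = 1.0) -> np.ndarray:
    """A 9-interval drowsiness trajectory on {1..6}.

    A bounded random walk around the population mean path scaled by
    ``drift``; drift 0 gives the constant alert trajectory (level 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if drift == 0.0:
        return np.ones(N_INTERVALS, dtype=int)
    subject_gain = rng.normal(1.0, 0.25)
    walk = np.cumsum(rng.normal(0.0, 0.4, size=N_INTERVALS))
    raw = 1.0 + (MEAN_LEVEL_PATH - 1.0) * drift * subject_gain + walk
    return np.clip(np.rint(raw), 1, 6).astype(int)


def generate_ecg_series(
    model: SubjectModel,
    trajectory: np.ndarray,
    seed: int | np.random.Generator,
    duration: float = DRIVE_DURATION_S,
) -> IBISeries:
    """Beat-by-beat ECG-grade IBI series over a 45-min drive.

    RR_i = baseline + offset + state_shift(level) + LF/HF sinusoids at
    0.10/0.25 Hz + Gaussian noise; beat times are cumulative RR sums.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = [0.0]
    rr: list[float] = []
    t = 0.0
    while t < duration:
        idx = min(int(t // INTERVAL_LENGTH_S), N_INTERVALS - 1)
        level = int(trajectory[idx])
        lf, hf = model.amps_at(level)
        mean_rr = model.mean_rr_at(level)
        value = (
            mean_rr
            + lf * np.sin(2 * np.pi * LF_TONE_HZ * t)
            + hf * np.sin(2 * np.pi * HF_TONE_HZ * t)
            + rng.normal(0.0, model.noise_sd * model.hrv_scale)
        )
        if value <= 0:
            raise ValueError(
                f"parameters produced a non-positive RR interval ({value:.1f} ms)"
            )
        rr.append(value)
        t += value / 1000.0
        times.append(t)
    return IBISeries(
        subject_id=model.subject_id,
        device=ECG,
        beat_times=np.asarray(times),
        intervals=np.asarray(rr),
        session_start=0.0,
    )


def degrade_to_wristband(
    series: IBISeries,
    spec: DegradationSpec = DegradationSpec(),
    seed: int | np.random.Generator = 0,
) -> IBISeries:
    """Derive a wristband-grade series: drop beats (merging adjacent
    intervals), quantise beat times to the sampling grid, jitter.

    With drop 0, quantum 0 and jitter 0 this is the identity (up to
    device tag)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = series.beat_times.copy()
    if t.size > 2:
        # first and last beats kept so the recording span is preserved
        keep_inner = rng.uniform(size=t.size - 2) >= spec.beat_drop_prob
        keep = np.concatenate([[True], keep_inner, [True]])
        t = t[keep]
    if spec.jitter_sd > 0 and t.size > 2:
        t[1:-1] = t[1:-1] + rng.normal(0.0, spec.jitter_sd / 1000.0, size=t.size - 2)
        t = np.sort(t)
    if spec.time_quantum > 0:
        t = np.round(t / spec.time_quantum) * spec.time_quantum
        t = t[np.concatenate([[True], np.diff(t) > 0])]  # collapse coincident beats
    intervals = np.diff(t) * 1000.0
    return IBISeries(
        subject_id=series.subject_id,
        device=WRISTBAND,
        beat_times=t,
        intervals=intervals,
        session_start=series.session_start,
    )


def generate_annotations(
    model: SubjectModel,
    trajectory: np.ndarray,
    seed: int | np.random.Generator,
    rater_noise_sd: float = 0.5,
) -> tuple[list[RatingRecord], list[RatingRecord], list[MicroSleepEvent]]:
    """Two raters' interval ratings plus micro-sleep events.

    Each rater reports the true level plus independent rounded Gaussian
    noise clipped to {1..6}. Micro-sleep events occur only in intervals
    with true level >= 4, as a Poisson process at the model's rate, with
    closure durations 1 + Exponential(mean level-dependent) seconds so
    all three duration bins (1-2, 2-4, >= 4 s) are populated.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raters: tuple[list[RatingRecord], list[RatingRecord]] = ([], [])
    events: list[MicroSleepEvent] = []
    for idx in range(N_INTERVALS):
        level = int(trajectory[idx])
        for r, records in enumerate(raters):
            noisy = level + int(np.rint(rng.normal(0.0, rater_noise_sd)))
            records.append(RatingRecord(
                model.subject_id, idx, int(np.clip(noisy, 1, 6)), rater_id=f"r{r + 1}"
            ))
        if level >= 4 and model.microsleep_rate_per_min > 0:
            n_events = rng.poisson(model.microsleep_rate_per_min * INTERVAL_LENGTH_S / 60.0)
            for _ in range(n_events):
                onset = idx * INTERVAL_LENGTH_S + rng.uniform(0.0, INTERVAL_LENGTH_S)
                duration = 1.0 + rng.exponential(0.8 * (level - 3))
                events.append(MicroSleepEvent(model.subject_id, onset, duration))
    return raters[0], raters[1], events


@dataclass
class SubjectBundle:
    model: SubjectModel
    trajectory: np.ndarray
    ecg: IBISeries
    wristband: IBISeries
    ratings_rater1: list[RatingRecord]
    ratings_rater2: list[RatingRecord]
    joint_ratings: list[RatingRecord]
    events: list[MicroSleepEvent]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the generated cohort.

    subject_offset_sd spreads subjects' resting meanRR and
    subject_hrv_scale_sd their overall HRV magnitude (inter-driver
    variance); drift scales the drowsiness trajectory; state_shift_ms /
    hf_amp_slope control how strongly the drowsy state separates in HRV
    space (0 gives state-independent HRV: features carry no class
    information); rater_noise_sd degrades the observer labels."""

    n_subjects: int = 27
    baseline_meanRR: float = 900.0
    subject_offset_sd: float = 40.0  # ms
    subject_hrv_scale_sd: float = 0.3  # log-scale SD of HRV magnitude
    drift: float = 1.0
    state_shift_ms: float = 10.0
    drowsy_shift_ms: float = 25.0
    hf_amp_slope: float = 4.0
    drowsy_hf_boost: float = 15.0
    lf_amp_slope: float = -3.0
    noise_sd: float = 15.0
    rater_noise_sd: float = 0.5
    microsleep_rate_per_min: float = 1.5
    degradation: DegradationSpec = field(default_factory=DegradationSpec)

    def null(self) -> "CohortConfig":
        """The state-independent condition: HRV carries no drowsiness
        information (no state shift, no state-dependent amplitudes) and
        no inter-driver variance, so all windows are exchangeable;
        labels keep their trajectory-driven structure."""
        return replace(self, state_shift_ms=0.0, drowsy_shift_ms=0.0,
                       hf_amp_slope=0.0, drowsy_hf_boost=0.0,
                       lf_amp_slope=0.0, subject_offset_sd=0.0,
                       subject_hrv_scale_sd=0.0)


def recovery_configs(n_subjects: int = 10) -> tuple[CohortConfig, CohortConfig]:
    """The parameter-recovery study conditions.

    The separated condition uses a strong, well-separated autonomic
    encoding (a 60 ms meanRR jump and a 30 ms HF-amplitude boost at the
    transition into the drowsy state) with noise-free observer labels,
    so that the label signal is fully present in the features; the null
    condition is its state-independent counterpart, identical in every
    respect except that the features carry no drowsiness information.
    """
    separated = CohortConfig(
        n_subjects=n_subjects, drowsy_shift_ms=60.0, drowsy_hf_boost=30.0,
        rater_noise_sd=0.0,
    )
    return separated, separated.null()


def _substream(master: np.random.Generator, name: str, subject: str) -> np.random.Generator:
    h = zlib.crc32(f"{name}/{subject}".encode()) % (2 ** 31)
    return np.random.default_rng(int(master.integers(2 ** 31)) ^ h)


def generate_subject(
    config: CohortConfig, subject_id: str, master: np.random.Generator
) -> SubjectBundle:
    # subject-level draws happen unconditionally so that configs which
    # differ only in effect sizes share trajectories under the same seed
    offset = float(master.normal(0.0, 1.0)) * config.subject_offset_sd
    hrv_scale = float(np.exp(master.normal(0.0, 1.0) * config.subject_hrv_scale_sd))
    model = SubjectModel(
        subject_id=subject_id,
        baseline_meanRR=config.baseline_meanRR,
        subject_offset=offset,
        state_shift_ms=config.state_shift_ms,
        drowsy_shift_ms=config.drowsy_shift_ms,
        hf_amp_slope=config.hf_amp_slope,
        drowsy_hf_boost=config.drowsy_hf_boost,
        lf_amp_slope=config.lf_amp_slope,
        noise_sd=config.noise_sd,
        hrv_scale=hrv_scale,
        microsleep_rate_per_min=config.microsleep_rate_per_min,
    )
    trajectory = generate_trajectory(_substream(master, "trajectory", subject_id), config.drift)
    ecg = generate_ecg_series(model, trajectory, _substream(master, "series", subject_id))
    wrist = degrade_to_wristband(ecg, config.degradation,
                                 _substream(master, "degradation", subject_id))
    r1, r2, events = generate_annotations(
        model, trajectory, _substream(master, "annotations", subject_id),
        rater_noise_sd=config.rater_noise_sd,
    )
    # joint rating: consensus by rounding the rater mean (discussion proxy)
    joint = [
        RatingRecord(subject_id, a.interval_index,
                     int(np.clip(np.rint((a.level + b.level) / 2.0), 1, 6)))
        for a, b in zip(r1, r2)
    ]
    return SubjectBundle(model, trajectory, ecg, wrist, r1, r2, joint, events)


def generate_cohort(
    config: CohortConfig = CohortConfig(), seed: int = 0
) -> list[SubjectBundle]:
    """Reproducible cohort of complete subject bundles."""
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.default_rng(seed)
    return [
        generate_subject(config, f"s{i + 1:02d}", master)
        for i in range(config.n_subjects)
    ]
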