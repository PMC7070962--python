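"""Sliding-window HRV feature extraction from inter-beat-interval streams.

A recording is cut into 5-min windows advanced by a configurable step
(2 s by default), and 26 features are computed per window:

* time domain (13): meanRR, maxRR, minRR, rangeRR, SDNN, SDANNIndex,
  maxHR, minHR, meanHR, SDHR, RMSSD, NN50, pNN50;
* frequency domain (10): band powers of the Lomb-Scargle periodogram
  over VLF (0-0.04 Hz), LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz), their
  percentages, normalised LF/HF and the LF/HF ratio;
* nonlinear (3): Poincare SD1, SD2 and their ratio.

The Lomb-Scargle periodogram operates directly on the unevenly sampled
RR series; no interpolation or resampling is applied, and wristband and
ECG streams are processed identically. The periodogram is rescaled so
that its integral over the frequency grid equals the sample variance of
the window's RR intervals, which makes band powers read as ms^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

from .ground_truth import INTERVAL_LENGTH_S, IntervalLabel, binarize
from .iodata import FEATURE_TABLE_META, FEATURE_TABLE_TAIL, IBISeries

log = logging.getLogger(__name__)

TIME_FEATURES = [
    "meanRR", "maxRR", "minRR", "rangeRR", "SDNN", "SDANNIndex",
    "maxHR", "minHR", "meanHR", "SDHR", "RMSSD", "NN50", "pNN50",
]
FREQ_FEATURES = [
    "VLF", "LFpower", "HFpower", "Totalpower",
    "pVLF", "pLF", "pHF", "LFnorm", "HFnorm", "LFHF_ratio",
]
NONLINEAR_FEATURES = ["SD1", "SD2", "SD1SD2_ratio"]
FEATURE_NAMES = TIME_FEATURES + FREQ_FEATURES + NONLINEAR_FEATURES

MIN_INTERVALS_PER_WINDOW = 4


@dataclass(frozen=True)
class WindowSpec:
    window_length: float = 300.0  # s
    step: float = 2.0  # s

    def __post_init__(self) -> None:
        if self.window_length <= 0 or self.step <= 0:
            raise ValueError("window_length and step must be > 0")
        if self.step > self.window_length:
            raise ValueError("step must not exceed window_length")


@dataclass(frozen=True)
class BandDefinition:
    """Contiguous, non-overlapping VLF/LF/HF band edges in Hz."""

    vlf: tuple[float, float] = (0.0, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        edges = [*self.vlf, *self.lf, *self.hf]
        if not (edges[1] == edges[2] and edges[3] == edges[4]):
            raise ValueError("bands must be contiguous")
        if not all(a < b for a, b in (self.vlf, self.lf, self.hf)):
            raise ValueError("band edges must be increasing")


def default_freq_grid(bands: BandDefinition = BandDefinition(), spacing: float = 0.002) -> np.ndarray:
    """Frequency grid 0.002..0.4 Hz at 0.002 Hz spacing (resolves the
    0.04 Hz band edge; zero frequency is excluded)."""
    f_max = bands.hf[1]
    n = int(round(f_max / spacing))
    return spacing * np.arange(1, n + 1)


@dataclass
class Window:
    start: float
    beat_times: np.ndarray  # s, beats with time in [start, start+length)
    rr: np.ndarray  # ms, intervals between consecutive beats in the window


def segment_windows(series: IBISeries, spec: WindowSpec = WindowSpec()) -> list[Window]:
    """Cut a series into sliding windows of spec.window_length advanced by
    spec.step; windows with fewer than 4 intervals are dropped."""
    duration = series.duration
    if duration < spec.window_length:
        log.warning(
            "recording of %.1f s shorter than one %.0f-s window; no windows",
            duration, spec.window_length,
        )
        return []
    n_windows = int(math.floor((duration - spec.window_length) / spec.step)) + 1
    windows: list[Window] = []
    t = series.beat_times
    for i in range(n_windows):
        start = i * spec.step
        lo = int(np.searchsorted(t, start, side="left"))
        hi = int(np.searchsorted(t, start + spec.window_length, side="left"))
        rr = series.intervals[lo:hi - 1] if hi - lo >= 2 else np.empty(0)
        if rr.size < MIN_INTERVALS_PER_WINDOW:
            log.warning("window at %.0f s has %d intervals (<%d); dropped",
                        start, rr.size, MIN_INTERVALS_PER_WINDOW)
            continue
        windows.append(Window(start=start, beat_times=t[lo:hi], rr=rr))
    return windows


def time_features(rr: np.ndarray) -> dict[str, float]:
    """The 13 time-domain features of an RR window (rr in ms).

    SDANNIndex degenerates to SDNN inside a single 5-min window and is
    defined as such (near-duplicate of SDNN by construction).
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError(f"need at least 2 intervals, got {rr.size}")
    hr = 60000.0 / rr
    drr = np.diff(rr)
    sdnn = float(np.std(rr, ddof=1))
    nn50 = int(np.sum(np.abs(drr) > 50.0))
    return {
        "meanRR": float(np.mean(rr)),
        "maxRR": float(np.max(rr)),
        "minRR": float(np.min(rr)),
        "rangeRR": float(np.max(rr) - np.min(rr)),
        "SDNN": sdnn,
        "SDANNIndex": sdnn,
        "maxHR": float(np.max(hr)),
        "minHR": float(np.min(hr)),
        "meanHR": float(np.mean(hr)),
        "SDHR": float(np.std(hr, ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(drr ** 2))),
        "NN50": float(nn50),
        "pNN50": 100.0 * nn50 / drr.size,
    }


def lomb_scargle_psd(beat_times: np.ndarray, rr: np.ndarray, freq_grid: np.ndarray) -> np.ndarray:
    """Lomb-Scargle PSD (ms^2/Hz) of an RR series on a frequency grid.

    The series is mean-centred; the raw periodogram is rescaled so its
    trapezoidal integral over the grid equals the sample variance of rr,
    giving band integrals in ms^2. A constant series yields a zero PSD.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if rr.size < MIN_INTERVALS_PER_WINDOW:
        raise ValueError(f"need at least {MIN_INTERVALS_PER_WINDOW} points")
    if beat_times.size != rr.size:
        # intervals are attributed to the time of the beat that ends them
        beat_times = beat_times[1:rr.size + 1]
    centered = rr - rr.mean()
    var = float(np.var(rr, ddof=1))
    if var == 0.0:
        return np.zeros_like(freq_grid)
    power = lombscargle(beat_times, centered, 2.0 * np.pi * freq_grid)
    total = float(np.trapezoid(power, freq_grid))
    if total <= 0.0:
        return np.zeros_like(freq_grid)
    return power * (var / total)


def frequency_features(
    beat_times: np.ndarray,
    rr: np.ndarray,
    bands: BandDefinition = BandDefinition(),
    freq_grid: np.ndarray | None = None,
) -> dict[str, float]:
    """The 10 frequency-domain features from the Lomb-Scargle PSD.

    Band powers are trapezoidal integrals of the PSD over the band's grid
    points; Totalpower is their sum. When HF power is zero the LF/HF
    ratio is undefined and stored as NaN (the window is later dropped).
    """
    if freq_grid is None:
        freq_grid = default_freq_grid(bands)
    psd = lomb_scargle_psd(beat_times, rr, freq_grid)

    def band_power(band: tuple[float, float]) -> float:
        lo, hi = band
        mask = (freq_grid >= lo) & (freq_grid <= hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freq_grid[mask]))

    vlf = band_power(bands.vlf)
    lf = band_power(bands.lf)
    hf = band_power(bands.hf)
    total = vlf + lf + hf
    if total == 0.0:
        pvlf = plf = phf = lfn = hfn = ratio = float("nan")
    else:
        pvlf, plf, phf = (100.0 * p / total for p in (vlf, lf, hf))
        denom = total - vlf
        lfn = 100.0 * lf / denom if denom > 0 else float("nan")
        hfn = 100.0 * hf / denom if denom > 0 else float("nan")
        ratio = lf / hf if hf > 0 else float("nan")
    if not math.isfinite(ratio):
        log.warning("undefined LF/HF ratio (HF power %.3g); window will be dropped", hf)
    return {
        "VLF": vlf, "LFpower": lf, "HFpower": hf, "Totalpower": total,
        "pVLF": pvlf, "pLF": plf, "pHF": phf,
        "LFnorm": lfn, "HFnorm": hfn, "LFHF_ratio": ratio,
    }


def poincare_features(rr: np.ndarray) -> dict[str, float]:
    """Poincare SD1/SD2 of an RR window.

    SD1^2 = var(successive differences)/2 and SD2^2 = 2*var(rr) - SD1^2,
    both with population variances so the identity holds exactly.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise ValueError(f"need at least 3 intervals, got {rr.size}")
    drr = np.diff(rr)
    sd1 = math.sqrt(np.var(drr) / 2.0)
    sd2_sq = 2.0 * np.var(rr) - sd1 ** 2
    sd2 = math.sqrt(max(sd2_sq, 0.0))
    ratio = sd1 / sd2 if sd2 > 0 else float("nan")
    if sd2 == 0:
        log.warning("SD2 = 0; SD1/SD2 undefined for this window")
    return {"SD1": sd1, "SD2": sd2, "SD1SD2_ratio": ratio}


def feature_vector(
    window: Window,
    bands: BandDefinition = BandDefinition(),
    freq_grid: np.ndarray | None = None,
) -> dict[str, float]:
    """All 26 features of one window, in the fixed declared order."""
    feats = {}
    feats.update(time_features(window.rr))
    feats.update(frequency_features(window.beat_times, window.rr, bands, freq_grid))
    feats.update(poincare_features(window.rr))
    return {name: feats[name] for name in FEATURE_NAMES}


def label_windows(
    windows: list[Window],
    labels: list[IntervalLabel],
    spec: WindowSpec = WindowSpec(),
) -> list[tuple[Window, IntervalLabel]]:
    """Attach per-interval labels to windows by the interval containing
    the window's end; windows ending in an unlabeled interval are dropped.

    The end is the last instant covered, so a window [0, 300) belongs to
    interval 0 while [298, 598) belongs to interval 1 — each window
    carries the most recent drowsiness state.
    """
    by_index = {l.interval_index: l for l in labels}
    out: list[tuple[Window, IntervalLabel]] = []
    for w in windows:
        end = w.start + spec.window_length
        idx = int(math.ceil(end / INTERVAL_LENGTH_S)) - 1
        label = by_index.get(idx)
        if label is not None:
            out.append((w, label))
    return out


def extract_labeled_features(
    series: IBISeries,
    labels: list[IntervalLabel],
    spec: WindowSpec = WindowSpec(),
    bands: BandDefinition = BandDefinition(),
    freq_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full per-series pipeline: segment, featurise, label.

    Returns the labeled feature table (one row per retained window);
    windows with undefined features (NaN) are dropped with a warning.
    """
    if freq_grid is None:
        freq_grid = default_freq_grid(bands)
    windows = segment_windows(series, spec)
    rows = []
    for window, label in label_windows(windows, labels, spec):
        feats = feature_vector(window, bands, freq_grid)
        if any(not math.isfinite(v) for v in feats.values()):
            log.warning("window at %.0f s has undefined features; dropped", window.start)
            continue
        rows.append(
            {"subject": series.subject_id, "device": series.device,
             "window_start_s": window.start, **feats,
             "level": label.level, "binary_class": binarize(label.level)}
        )
    columns = FEATURE_TABLE_META + FEATURE_NAMES + FEATURE_TABLE_TAIL
    return pd.DataFrame(rows, columns=columns)
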