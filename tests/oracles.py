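"""Independent reference implementations used only as test oracles.

Everything here is computed from first principles (plain loops, the
classic textbook formulas, exhaustive search) and shares no code with
the package paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def time_features_oracle(rr) -> dict[str, float]:
    """Textbook time-domain HRV statistics via plain Python."""
    rr = [float(v) for v in rr]
    n = len(rr)
    mean = sum(rr) / n
    var_s = sum((v - mean) ** 2 for v in rr) / (n - 1)
    hr = [60000.0 / v for v in rr]
    mean_hr = sum(hr) / n
    var_hr = sum((v - mean_hr) ** 2 for v in hr) / (n - 1)
    diffs = [rr[i + 1] - rr[i] for i in range(n - 1)]
    nn50 = sum(1 for d in diffs if abs(d) > 50.0)
    return {
        "meanRR": mean,
        "maxRR": max(rr),
        "minRR": min(rr),
        "rangeRR": max(rr) - min(rr),
        "SDNN": math.sqrt(var_s),
        "SDANNIndex": math.sqrt(var_s),
        "maxHR": max(hr),
        "minHR": min(hr),
        "meanHR": mean_hr,
        "SDHR": math.sqrt(var_hr),
        "RMSSD": math.sqrt(sum(d * d for d in diffs) / len(diffs)),
        "NN50": float(nn50),
        "pNN50": 100.0 * nn50 / len(diffs),
    }


def poincare_oracle(rr) -> dict[str, float]:
    """SD1 from the successive-difference definition, SD2 from the
    population-variance identity, via plain Python."""
    rr = [float(v) for v in rr]
    n = len(rr)
    diffs = [rr[i + 1] - rr[i] for i in range(n - 1)]
    md = sum(diffs) / len(diffs)
    var_d = sum((d - md) ** 2 for d in diffs) / len(diffs)
    sd1 = math.sqrt(var_d / 2.0)
    mean = sum(rr) / n
    var_p = sum((v - mean) ** 2 for v in rr) / n
    sd2 = math.sqrt(max(2.0 * var_p - sd1 ** 2, 0.0))
    return {"SD1": sd1, "SD2": sd2,
            "SD1SD2_ratio": sd1 / sd2 if sd2 > 0 else float("nan")}


def lomb_classic(t, y, freqs) -> np.ndarray:
    """Classic Lomb periodogram (tau-shifted least squares), raw power."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.empty(len(freqs))
    for i, f in enumerate(freqs):
        w = 2.0 * np.pi * f
        tau = np.arctan2(np.sum(np.sin(2 * w * t)), np.sum(np.cos(2 * w * t))) / (2 * w)
        c = np.cos(w * (t - tau))
        s = np.sin(w * (t - tau))
        out[i] = 0.5 * ((y @ c) ** 2 / (c @ c) + (y @ s) ** 2 / (s @ s))
    return out


def _trapz(y, x) -> float:
    return float(sum((y[i] + y[i + 1]) * (x[i + 1] - x[i]) / 2.0 for i in range(len(y) - 1)))


def psd_oracle(beat_times, rr, freqs) -> np.ndarray:
    """Variance-normalised classic Lomb PSD of a mean-centred RR series."""
    rr = np.asarray(rr, dtype=float)
    t = np.asarray(beat_times, dtype=float)
    if t.size != rr.size:
        t = t[1:rr.size + 1]
    y = rr - rr.mean()
    var = float(np.sum(y ** 2) / (rr.size - 1))
    if var == 0.0:
        return np.zeros(len(freqs))
    raw = lomb_classic(t, y, freqs)
    total = _trapz(raw, freqs)
    return raw * var / total


def band_powers_oracle(beat_times, rr, freqs, bands) -> dict[str, float]:
    """Trapezoidal band integrals of the oracle PSD; bands is a dict
    name -> (lo, hi)."""
    psd = psd_oracle(beat_times, rr, freqs)
    freqs = np.asarray(freqs)
    out = {}
    for name, (lo, hi) in bands.items():
        m = (freqs >= lo) & (freqs <= hi)
        out[name] = _trapz(psd[m].tolist(), freqs[m].tolist())
    return out


def dft_periodogram(y, fourier_index_max) -> np.ndarray:
    """|DFT|^2 / n at Fourier frequencies 1..fourier_index_max for a
    unit-spaced series."""
    y = np.asarray(y, dtype=float)
    n = y.size
    out = np.empty(fourier_index_max)
    for k in range(1, fourier_index_max + 1):
        e = np.exp(-2j * np.pi * k * np.arange(n) / n)
        out[k - 1] = np.abs(np.sum(y * e)) ** 2 / n
    return out


def _pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    den = math.sqrt(float(a @ a) * float(b @ b))
    if den == 0.0:
        return 0.0
    return float(a @ b) / den


def cfs_exhaustive(X, y, names) -> tuple[tuple[str, ...], float]:
    """Best CFS subset by brute force over all non-empty subsets.

    Correlations are computed with a locally defined Pearson formula;
    ties break on smaller subsets, then lexicographic order.
    """
    X = np.asarray(X, dtype=float)
    y_arr = np.asarray(y)
    y01 = y_arr.astype(float) if y_arr.dtype.kind in "fiu" \
        else np.unique(y_arr, return_inverse=True)[1].astype(float)
    p = len(names)
    rcf = [abs(_pearson(X[:, j], y01)) for j in range(p)]
    rff = np.zeros((p, p))
    for i, j in itertools.combinations(range(p), 2):
        rff[i, j] = rff[j, i] = abs(_pearson(X[:, i], X[:, j]))

    best_subset, best_merit = (), 0.0
    for k in range(1, p + 1):
        for combo in itertools.combinations(range(p), k):
            mc = sum(rcf[j] for j in combo) / k
            if k == 1:
                mf = 0.0
            else:
                pairs = list(itertools.combinations(combo, 2))
                mf = sum(rff[i][j] for i, j in pairs) / len(pairs)
            merit = k * mc / math.sqrt(k + k * (k - 1) * mf)
            key = tuple(sorted(names[j] for j in combo))
            if merit > best_merit + 1e-12 or (
                abs(merit - best_merit) <= 1e-12
                and (len(key), key) < (len(best_subset), best_subset)
            ):
                best_subset, best_merit = key, merit
    return best_subset, best_merit


def stump_exhaustive(x, y):
    """Best 1-D threshold split by brute force: returns (errors, thr)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    uniq = np.unique(x)
    best = (len(y) + 1, None)
    for thr in (uniq[:-1] + uniq[1:]) / 2.0:
        for lp in classes:
            for rp in classes:
                err = int(np.sum(y[x <= thr] != lp)) + int(np.sum(y[x > thr] != rp))
                if err < best[0]:
                    best = (err, thr)
    return best
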