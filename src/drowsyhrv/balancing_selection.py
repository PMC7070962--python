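"""Class balancing (SMOTE) and correlation-based feature subset selection.

Both operations are applied to training folds only, never to test data.

SMOTE oversamples the minority class to exact parity with the majority
by interpolating between a minority instance and one of its k nearest
minority neighbours: ``x_new = x + u * (x_nn - x)``, u ~ Uniform(0, 1).

CFSS scores a subset S of k features by the merit

    merit(S) = k * mean|r_cf| / sqrt(k + k (k - 1) * mean|r_ff|)

where r_cf are Pearson feature-class correlations (point-biserial with a
0/1-coded class) and r_ff the pairwise feature-feature correlations
within S. A forward best-first search maximises the merit, expanding the
open subset of highest merit by single-feature additions and stopping
after a fixed number of consecutive expansions without improving the
global best. Ties break on lexicographic feature order, making the
search deterministic.
"""

from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FeatureSubset:
    selected: tuple[str, ...]
    merit: float


def smote(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class to exact parity.

    Original rows are preserved unchanged (and first, in input order);
    synthetic rows follow. k is clipped to minority_count - 1 when the
    minority class is too small for the requested neighbourhood.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"smote expects a binary class vector, got classes {classes}")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    minority_idx = np.nonzero(y == minority)[0]
    m = minority_idx.size
    if m < 2:
        raise ValueError(f"minority class has {m} instance(s); need >= 2")
    if k >= m:
        warnings.warn(f"smote k={k} >= minority count {m}; clipping to {m - 1}")
        k = m - 1
    n_new = int(counts.max() - counts.min())

    Xm = X[minority_idx]
    # pairwise Euclidean distances within the minority class
    d2 = np.sum((Xm[:, None, :] - Xm[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = rng.integers(0, m, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    x0 = Xm[base]
    x1 = Xm[nn[base, pick]]
    synthetic = x0 + u[:, None] * (x1 - x0)

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    """|Pearson correlation|, 0 when either vector is constant."""
    sa, sb = np.std(a), np.std(b)
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def correlation_tables(
    X: np.ndarray, y: np.ndarray, feature_names: list[str]
) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Absolute feature-class (point-biserial) and feature-feature
    Pearson correlations, keyed by feature name."""
    X = np.asarray(X, dtype=float)
    y_arr = np.asarray(y)
    if y_arr.dtype.kind in "fiu":
        y01 = y_arr.astype(float)
    else:  # categorical labels -> 0/1 codes (sign is irrelevant under |r|)
        y01 = np.unique(y_arr, return_inverse=True)[1].astype(float)
    rcf = {name: _abs_corr(X[:, j], y01) for j, name in enumerate(feature_names)}
    rff = {}
    for (i, a), (j, b) in itertools.combinations(enumerate(feature_names), 2):
        r = _abs_corr(X[:, i], X[:, j])
        rff[(a, b)] = r
        rff[(b, a)] = r
    return rcf, rff


def cfs_merit(
    subset: tuple[str, ...],
    rcf: dict[str, float],
    rff: dict[tuple[str, str], float],
) -> float:
    """CFS merit of a feature subset; 0 for the empty subset."""
    k = len(subset)
    if k == 0:
        return 0.0
    mean_rcf = float(np.mean([rcf[f] for f in subset]))
    if k == 1:
        mean_rff = 0.0
    else:
        mean_rff = float(np.mean([rff[(a, b)] for a, b in itertools.combinations(subset, 2)]))
    return k * mean_rcf / np.sqrt(k + k * (k - 1) * mean_rff)


def best_first_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    max_stale: int = 5,
) -> FeatureSubset:
    """Forward best-first search maximising the CFS merit.

    Starts from the empty set, expands the open subset of highest merit
    by all single-feature additions, and stops after ``max_stale``
    consecutive expansions that fail to improve the global best.
    """
    if len(feature_names) < 2:
        raise ValueError("need at least 2 features to select from")
    names = sorted(feature_names)
    rcf, rff = correlation_tables(
        np.asarray(X)[:, [feature_names.index(n) for n in names]], y, names
    )

    # heap of (-merit, subset); subsets as sorted tuples for tie-breaking
    start: tuple[str, ...] = ()
    open_heap: list[tuple[float, tuple[str, ...]]] = [(0.0, start)]
    visited: set[tuple[str, ...]] = {start}
    best_subset, best_merit = start, 0.0
    stale = 0

    while open_heap and stale < max_stale:
        _, current = heapq.heappop(open_heap)
        improved = False
        for name in names:
            if name in current:
                continue
            child = tuple(sorted(current + (name,)))
            if child in visited:
                continue
            visited.add(child)
            merit = cfs_merit(child, rcf, rff)
            heapq.heappush(open_heap, (-merit, child))
            if merit > best_merit + 1e-12:
                best_subset, best_merit = child, merit
                improved = True
        stale = 0 if improved else stale + 1

    if not best_subset:
        # degenerate scoring (all correlations 0): keep the minimal
        # lexicographically-first single feature for a non-empty subset
        best_subset = (names[0],)
        best_merit = cfs_merit(best_subset, rcf, rff)
    return FeatureSubset(selected=best_subset, merit=float(best_merit))


def subset_occurrences(subsets: list[FeatureSubset]) -> pd.DataFrame:
    """Fold-wise selected subsets tallied as 'subset x occurrence count'."""
    counts: dict[tuple[str, ...], int] = {}
    for s in subsets:
        counts[s.selected] = counts.get(s.selected, 0) + 1
    rows = [{"subset": ", ".join(k), "occurrences": v}
            for k, v in sorted(counts.items(), key=lambda kv: -kv[1])]
    return pd.DataFrame(rows, columns=["subset", "occurrences"])
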