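"""Dynamic-time-warping kernels.

Classic unconstrained DTW with a multivariate Euclidean local cost and unit
step pattern (no window, no normalization), plus the subsequence variant in
which a short query may align to any contiguous part of a longer series.
Kernels are numba-compiled; inputs are (T, d) float64 arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dtw_distance", "subsequence_dtw"]


@njit(cache=True)
def _dtw_cost(a: np.ndarray, b: np.ndarray) -> float:
    n, m, d = a.shape[0], b.shape[0], a.shape[1]
    prev = np.empty(m)
    cur = np.empty(m)
    for j in range(m):
        acc = 0.0
        for k in range(d):
            diff = a[0, k] - b[j, k]
            acc += diff * diff
        c = np.sqrt(acc)
        prev[j] = c if j == 0 else prev[j - 1] + c
    for i in range(1, n):
        for j in range(m):
            acc = 0.0
            for k in range(d):
                diff = a[i, k] - b[j, k]
                acc += diff * diff
            c = np.sqrt(acc)
            if j == 0:
                cur[j] = prev[0] + c
            else:
                best = prev[j]
                if prev[j - 1] < best:
                    best = prev[j - 1]
                if cur[j - 1] < best:
                    best = cur[j - 1]
                cur[j] = best + c
        prev, cur = cur, prev
    return prev[m - 1]


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """DTW dissimilarity between two multivariate sequences.

    Zero iff the sequences are equal up to repetition of points; symmetric
    and non-negative but not a metric (the triangle inequality may fail).
    """
    return float(_dtw_cost(_as_series(a), _as_series(b)))


def _as_series(x) -> np.ndarray:
    """Coerce to a (T, d) float64 array; 1-D input is a univariate series."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    return np.ascontiguousarray(x)


@njit(cache=True)
def _subseq_matrix(q: np.ndarray, s: np.ndarray) -> np.ndarray:
    n, m, d = q.shape[0], s.shape[0], q.shape[1]
    D = np.empty((n, m))
    for j in range(m):
        acc = 0.0
        for k in range(d):
            diff = q[0, k] - s[j, k]
            acc += diff * diff
        D[0, j] = np.sqrt(acc)  # free start along the series
    for i in range(1, n):
        for j in range(m):
            acc = 0.0
            for k in range(d):
                diff = q[i, k] - s[j, k]
                acc += diff * diff
            c = np.sqrt(acc)
            if j == 0:
                D[i, 0] = D[i - 1, 0] + c
            else:
                best = D[i - 1, j]
                if D[i - 1, j - 1] < best:
                    best = D[i - 1, j - 1]
                if D[i, j - 1] < best:
                    best = D[i, j - 1]
                D[i, j] = best + c
    return D


def subsequence_dtw(query: np.ndarray, series: np.ndarray):
    """Align a short query against any contiguous window of a series.

    Returns ``(cost, (a, b), path)`` where ``series[a:b+1]`` is the matched
    window (free start and end) and ``path`` is the list of (query index,
    series index) pairs of the optimal alignment.
    """
    q = _as_series(query)
    s = _as_series(series)
    D = _subseq_matrix(q, s)
    n, m = D.shape
    b = int(np.argmin(D[n - 1]))
    cost = float(D[n - 1, b])
    # traceback
    path = [(n - 1, b)]
    i, j = n - 1, b
    while i > 0:
        if j == 0:
            i -= 1
        else:
            moves = ((i - 1, j - 1), (i - 1, j), (i, j - 1))
            i, j = min(moves, key=lambda ij: D[ij])
        path.append((i, j))
    path.reverse()
    a = path[0][1]
    return cost, (a, b), path
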