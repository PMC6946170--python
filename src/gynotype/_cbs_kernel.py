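"""Inner kernels for circular binary segmentation.

The arc statistic for a candidate arc (i, j] of a length-n region is
the squared mean-shift contrast between the arc and its complement,

    stat(i, j) = (S_j - S_i - k/n * S_n)^2 / (k * (n - k)),   k = j - i,

which is a monotone transform of the two-sample t statistic at fixed
within-region variance; the permutation null calibrates it exactly.
Candidate arcs are constrained so every resulting segment has at least
``min_width`` windows.

Kernels are compiled with numba when available; a vectorized numpy
fallback keeps the package functional without it.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap(args[0]) if args and callable(args[0]) else wrap


@njit(cache=True)
def _max_arc_stat_jit(x: np.ndarray, min_width: int):
    n = x.shape[0]
    s = np.empty(n + 1)
    s[0] = 0.0
    for t in range(n):
        s[t + 1] = s[t] + x[t]
    total = s[n]
    best = -1.0
    bi, bj = -1, -1
    for i in range(0, n):
        if i != 0 and i < min_width:
            continue
        for j in range(i + 1, n + 1):
            k = j - i
            if k < min_width or n - k < min_width:
                if n - k < min_width:
                    break
                continue
            if j != n and n - j < min_width:
                continue
            d = s[j] - s[i] - k * total / n
            stat = d * d / (k * (n - k))
            if stat > best:
                best = stat
                bi, bj = i, j
    return best, bi, bj


@njit(cache=True)
def _batch_max_stats_jit(xs: np.ndarray, min_width: int) -> np.ndarray:
    out = np.empty(xs.shape[0])
    for r in range(xs.shape[0]):
        best, _, _ = _max_arc_stat_jit(xs[r], min_width)
        out[r] = best
    return out


def _max_arc_stat_numpy(x: np.ndarray, min_width: int):
    n = x.shape[0]
    s = np.concatenate([[0.0], np.cumsum(x)])
    total = s[n]
    jj, ii = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="xy")
    k = jj - ii
    valid = (k >= min_width) & ((n - k) >= min_width)
    valid &= (ii == 0) | (ii >= min_width)
    valid &= (jj == n) | ((n - jj) >= min_width)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = s[jj] - s[ii] - k * total / n
        stat = np.where(valid, d * d / np.where(valid, k * (n - k), 1), -1.0)
    flat = int(np.argmax(stat))
    bi, bj = flat // (n + 1), flat % (n + 1)
    best = float(stat[bi, bj])
    if best < 0:
        return -1.0, -1, -1
    return best, bi, bj


def max_arc_stat(x: np.ndarray, min_width: int):
    """Best arc statistic and its (i, j) boundaries; (-1, -1, -1) if no valid arc."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if HAVE_NUMBA:
        return _max_arc_stat_jit(x, min_width)
    return _max_arc_stat_numpy(x, min_width)


def batch_max_stats(xs: np.ndarray, min_width: int) -> np.ndarray:
    xs = np.ascontiguousarray(xs, dtype=np.float64)
    if HAVE_NUMBA:
        return _batch_max_stats_jit(xs, min_width)
    return np.array([_max_arc_stat_numpy(row, min_width)[0] for row in xs])
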