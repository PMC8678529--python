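"""Dynamic time warping distances and barycenter averaging for data slots.

Distances use the symmetric step pattern (insertions, deletions and
diagonal matches all weighted 1), no warping-window constraint by default
and no path-length normalisation — all compared slots have equal length, so
normalisation would only rescale every distance by the same factor.

Two multivariate modes are supported:

``independent``
    univariate DTW per kinematic variable, distances summed (default: each
    variable of one slot is compared with the corresponding variable of the
    other).
``dependent``
    a single DP over time with the Euclidean norm across all variables as
    local cost.

DTW is symmetric and zero on identical inputs but does not satisfy the
triangle inequality; the distance matrix is not a metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

MODES = ("independent", "dependent")


# ---------------------------------------------------------------------------
# numba kernels.  w < 0 disables the Sakoe-Chiba band.


@njit(cache=True, fastmath=True)
def _dtw_uni(a, b, w):
    n, m = a.shape[0], b.shape[0]
    inf = np.inf
    prev = np.full(m, inf)
    cur = np.full(m, inf)
    prev[0] = abs(a[0] - b[0])
    hi0 = m if w < 0 else min(m, 1 + w)
    for j in range(1, hi0):
        prev[j] = prev[j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        lo = 0 if w < 0 else max(0, i - w)
        hi = m if w < 0 else min(m, i + w + 1)
        for j in range(m):
            cur[j] = inf
        for j in range(lo, hi):
            c = abs(a[i] - b[j])
            best = inf
            if j > 0:
                best = prev[j - 1]
                if cur[j - 1] < best:
                    best = cur[j - 1]
            if prev[j] < best:
                best = prev[j]
            cur[j] = c + best
        prev, cur = cur, prev
    return prev[m - 1]


@njit(cache=True, fastmath=True)
def _dtw_indep(A, B, w):
    total = 0.0
    for v in range(A.shape[1]):
        total += _dtw_uni(A[:, v], B[:, v], w)
    return total


@njit(cache=True, fastmath=True)
def _dtw_dep(A, B, w):
    n, m, nv = A.shape[0], B.shape[0], A.shape[1]
    inf = np.inf
    prev = np.full(m, inf)
    cur = np.full(m, inf)

    s = 0.0
    for v in range(nv):
        d = A[0, v] - B[0, v]
        s += d * d
    prev[0] = np.sqrt(s)
    hi0 = m if w < 0 else min(m, 1 + w)
    for j in range(1, hi0):
        s = 0.0
        for v in range(nv):
            d = A[0, v] - B[j, v]
            s += d * d
        prev[j] = prev[j - 1] + np.sqrt(s)
    for i in range(1, n):
        lo = 0 if w < 0 else max(0, i - w)
        hi = m if w < 0 else min(m, i + w + 1)
        for j in range(m):
            cur[j] = inf
        for j in range(lo, hi):
            s = 0.0
            for v in range(nv):
                d = A[i, v] - B[j, v]
                s += d * d
            c = np.sqrt(s)
            best = inf
            if j > 0:
                best = prev[j - 1]
                if cur[j - 1] < best:
                    best = cur[j - 1]
            if prev[j] < best:
                best = prev[j]
            cur[j] = c + best
        prev, cur = cur, prev
    return prev[m - 1]


@njit(cache=True, fastmath=True)
def _acc_matrix(A, B, squared):
    """Full accumulated-cost matrix (dependent local cost), for traceback."""
    n, m, nv = A.shape[0], B.shape[0], A.shape[1]
    acc = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            s = 0.0
            for v in range(nv):
                d = A[i, v] - B[j, v]
                s += d * d
            c = s if squared else np.sqrt(s)
            if i == 0 and j == 0:
                acc[i, j] = c
            elif i == 0:
                acc[i, j] = acc[i, j - 1] + c
            elif j == 0:
                acc[i, j] = acc[i - 1, j] + c
            else:
                best = acc[i - 1, j - 1]
                if acc[i - 1, j] < best:
                    best = acc[i - 1, j]
                if acc[i, j - 1] < best:
                    best = acc[i, j - 1]
                acc[i, j] = best + c
    return acc


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WarpPath:
    """A monotone alignment between two sequences.

    Starts at (0, 0), ends at (n-1, m-1); each step advances one or both
    indices by one.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        p = self.pairs
        if not p or p[0] != (0, 0):
            raise ValueError("warp path must start at (0, 0)")
        for (i0, j0), (i1, j1) in zip(p, p[1:]):
            if (i1 - i0, j1 - j0) not in {(1, 0), (0, 1), (1, 1)}:
                raise ValueError("warp path steps must be (1,0), (0,1) or (1,1)")


def _traceback(acc: np.ndarray) -> WarpPath:
    """Follow minimal predecessors from the end; diagonal preferred on ties."""
    i, j = acc.shape[0] - 1, acc.shape[1] - 1
    pairs = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, up, left = acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            if diag <= up and diag <= left:
                i, j = i - 1, j - 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        pairs.append((i, j))
    return WarpPath(tuple(reversed(pairs)))


def _as_2d(x) -> np.ndarray:
    arr = np.ascontiguousarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("sequence must be a non-empty 1-D or 2-D array")
    return arr


def dtw_distance(
    a,
    b,
    mode: str = "independent",
    window: int | None = None,
    return_path: bool = False,
):
    """DTW distance between two (samples, variables) sequences.

    With ``return_path=True`` the optimal :class:`WarpPath` is also
    returned; for multivariate inputs this requires ``mode='dependent'``
    (independent mode has one path per variable, not a single alignment).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    A, B = _as_2d(a), _as_2d(b)
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"variable-count mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    w = -1 if window is None else int(window)
    if not return_path:
        if mode == "dependent" or A.shape[1] == 1:
            if A.shape[1] == 1:
                return float(_dtw_uni(A[:, 0], B[:, 0], w))
            return float(_dtw_dep(A, B, w))
        return float(_dtw_indep(A, B, w))
    if mode == "independent" and A.shape[1] > 1:
        raise ValueError("a single warp path requires mode='dependent'")
    acc = _acc_matrix(A, B, False)
    return float(acc[-1, -1]), _traceback(acc)


@dataclass
class DistanceMatrix:
    """Symmetric slot-by-slot DTW distances."""

    d: np.ndarray
    slot_ids: list[str]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = self.d.shape[0]
        if self.d.ndim != 2 or self.d.shape[1] != n:
            raise ValueError("distance matrix must be square")
        if len(self.slot_ids) != n:
            raise ValueError("slot_ids length must match matrix size")
        if not np.isfinite(self.d).all() or (self.d < 0).any():
            raise ValueError("distances must be finite and non-negative")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.d.shape[0]


def _slot_arrays(slots) -> tuple[list[np.ndarray], list[str]]:
    arrays, ids = [], []
    for k, s in enumerate(slots):
        arr = _as_2d(getattr(s, "data", s))
        arrays.append(arr)
        ids.append(getattr(s, "source_id", str(k)))
    return arrays, ids


def dtw_distance_matrix(
    slots: Sequence, mode: str = "independent", window: int | None = None
) -> DistanceMatrix:
    """All pairwise DTW distances of a homogeneous slot list."""
    arrays, ids = _slot_arrays(slots)
    n = len(arrays)
    if n < 2:
        raise ValueError("need at least two slots")
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"slots are not homogeneous in shape: {shapes}")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dtw_distance(
                arrays[i], arrays[j], mode=mode, window=window
            )
    return DistanceMatrix(d=d, slot_ids=ids)


def slot_to_centroid_distances(
    slots: Sequence, centroids: Sequence[np.ndarray], mode: str = "independent"
) -> np.ndarray:
    """(n_slots, n_centroids) DTW distances to explicit centroid sequences."""
    arrays, _ = _slot_arrays(slots)
    out = np.empty((len(arrays), len(centroids)))
    for j, c in enumerate(centroids):
        C = _as_2d(c)
        for i, a in enumerate(arrays):
            out[i, j] = dtw_distance(a, C, mode=mode)
    return out


def _dba_iteration_uni(seqs_v: list[np.ndarray], avg_v: np.ndarray) -> np.ndarray:
    sums = np.zeros(avg_v.shape[0])
    counts = np.zeros(avg_v.shape[0])
    for s in seqs_v:
        acc = _acc_matrix(avg_v[:, None], s[:, None], True)
        for i, j in _traceback(acc).pairs:
            sums[i] += s[j]
            counts[i] += 1
    return sums / counts


def dba_average(
    sequences: Sequence,
    init=None,
    max_iter: int = 30,
    tol: float = 1e-6,
    mode: str = "independent",
    return_trace: bool = False,
):
    """DTW barycenter average of a set of equal-variable sequences.

    Each iteration aligns every member to the current average (DP on
    squared local cost, for which the mean update below is the exact
    minimiser) and replaces each average sample by the mean of the member
    samples aligned to it; the summed squared alignment cost is
    non-increasing and iteration stops when its decrease falls below
    ``tol`` (relative).  Under independent mode each variable is averaged
    by its own univariate alignment; dependent mode warps all variables
    along one path.  ``init`` defaults to the member with the smallest
    summed DTW distance to all others (the medoid), so the result is
    deterministic.  The returned sequence has the length of ``init``.
    """
    arrays, _ = _slot_arrays(sequences)
    if len(arrays) == 0:
        raise ValueError("need at least one sequence")
    if len({a.shape[1] for a in arrays}) != 1:
        raise ValueError("sequences must share a variable count")
    if init is None:
        if len(arrays) == 1:
            avg = arrays[0].copy()
            return (avg, [0.0]) if return_trace else avg
        sums = np.zeros(len(arrays))
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                dij = dtw_distance(arrays[i], arrays[j], mode=mode)
                sums[i] += dij
                sums[j] += dij
        avg = arrays[int(np.argmin(sums))].copy()
    else:
        avg = _as_2d(init).copy()

    def objective(av):
        total = 0.0
        for s in arrays:
            if mode == "independent":
                for v in range(av.shape[1]):
                    total += _acc_matrix(av[:, v : v + 1], s[:, v : v + 1], True)[-1, -1]
            else:
                total += _acc_matrix(av, s, True)[-1, -1]
        return total

    trace = [objective(avg)]
    for _ in range(max_iter):
        if mode == "independent":
            new = np.column_stack(
                [
                    _dba_iteration_uni([s[:, v] for s in arrays], avg[:, v])
                    for v in range(avg.shape[1])
                ]
            )
        else:
            sums = np.zeros_like(avg)
            counts = np.zeros(avg.shape[0])
            for s in arrays:
                acc = _acc_matrix(avg, s, True)
                for i, j in _traceback(acc).pairs:
                    sums[i] += s[j]
                    counts[i] += 1
            new = sums / counts[:, None]
        avg = new
        trace.append(objective(avg))
        prev, cur = trace[-2], trace[-1]
        if prev - cur < tol * max(prev, 1.0):
            break
    if return_trace:
        return avg, trace
    return avg
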