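"""Independent brute-force oracles shared by the test modules."""

from functools import lru_cache
from itertools import combinations

import numpy as np


def enumerate_paths(n, m):
    """All monotone warp paths from (0,0) to (n-1,m-1)."""

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0 and j == 0:
            return [((0, 0),)]
        out = []
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            pi, pj = i - di, j - dj
            if pi >= 0 and pj >= 0:
                out.extend(p + ((i, j),) for p in rec(pi, pj))
        return out

    return rec(n - 1, m - 1)


def brute_force_dtw(a, b, mode):
    """Minimal path cost by full enumeration (tiny sequences only)."""
    A = a if a.ndim == 2 else a[:, None]
    B = b if b.ndim == 2 else b[:, None]
    if mode == "independent" and A.shape[1] > 1:
        return sum(
            brute_force_dtw(A[:, v], B[:, v], "independent")
            for v in range(A.shape[1])
        )
    best = np.inf
    for path in enumerate_paths(A.shape[0], B.shape[0]):
        cost = sum(np.linalg.norm(A[i] - B[j]) for i, j in path)
        best = min(best, cost)
    return best


def exhaustive_kmedoid_cost(d, K):
    """Optimal k-medoid total cost by enumerating all medoid sets."""
    return min(
        d[:, list(m)].min(axis=1).sum()
        for m in combinations(range(d.shape[0]), K)
    )
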