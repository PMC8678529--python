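"""K-medoids (PAM) and DBA-centroid clustering over DTW distances.

Both methods follow the same protocol: random centroid initialisation,
iterative refinement to a local optimum, repeated over several restarts,
keeping the solution with the lowest total cost (sum of each slot's DTW
distance to its own centroid).  Runs are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dtw import (
    DistanceMatrix,
    dba_average,
    dtw_distance,
    slot_to_centroid_distances,
)


@dataclass
class ClusterSolution:
    """A slot partition with its centroids and bookkeeping.

    ``labels`` are 0-based cluster indices (rendered tables add 1);
    ``medoids`` holds slot indices for PAM, ``centroids`` the averaged
    sequences for DBA.  ``centroid_dist`` (n x K) stores each slot's DTW
    distance to every centroid; ``centroid_pair_dist`` (K x K) the
    centroid-centroid distances; ``centroid_global_dist`` (K,) the distance
    of each centroid to the whole-data centroid (used by the
    Calinski-Harabasz index).
    """

    method: str
    K: int
    labels: np.ndarray
    total_cost: float
    centroid_dist: np.ndarray
    centroid_pair_dist: np.ndarray
    medoids: list[int] | None = None
    centroids: list[np.ndarray] | None = None
    centroid_global_dist: np.ndarray | None = None
    restarts: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        counts = np.bincount(self.labels, minlength=self.K)
        if len(counts) != self.K or (counts == 0).any():
            raise ValueError("every cluster must be non-empty")
        n = len(self.labels)
        own = self.centroid_dist[np.arange(n), self.labels]
        if (own > self.centroid_dist.min(axis=1) + 1e-9).any():
            raise ValueError("assignment is not locally optimal")
        if abs(self.total_cost - own.sum()) > 1e-6 * max(1.0, own.sum()):
            raise ValueError("total_cost inconsistent with assignment")

    @property
    def n(self) -> int:
        return len(self.labels)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def to_dict(self) -> dict:
        """JSON-serializable summary: assignment, medoids, cost, config."""
        return {
            "method": self.method,
            "K": self.K,
            "labels": self.labels.tolist(),
            "medoids": self.medoids,
            "total_cost": self.total_cost,
            "restarts": self.restarts,
            "seed": self.seed,
        }


def medoid_of(dm: DistanceMatrix | np.ndarray, members: Sequence[int]) -> int:
    """The member with the smallest summed distance to the other members.

    Ties break toward the lowest slot index.
    """
    d = dm.d if isinstance(dm, DistanceMatrix) else np.asarray(dm)
    members = np.asarray(sorted(members), dtype=int)
    if members.size == 0:
        raise ValueError("members must be non-empty")
    sub = d[np.ix_(members, members)]
    return int(members[int(np.argmin(sub.sum(axis=1)))])


def assign_to_medoids(
    d: np.ndarray, medoids: Sequence[int]
) -> tuple[np.ndarray, float]:
    """Nearest-medoid labels (ties -> lowest cluster index) and total cost."""
    cd = d[:, list(medoids)]
    labels = np.argmin(cd, axis=1)
    cost = float(cd[np.arange(len(labels)), labels].sum())
    return labels, cost


def _swap_cost(d: np.ndarray, medoids: np.ndarray) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def is_swap_optimal(dm: DistanceMatrix | np.ndarray, medoids: Sequence[int]) -> bool:
    """True if no single medoid/non-medoid exchange lowers the total cost."""
    d = dm.d if isinstance(dm, DistanceMatrix) else np.asarray(dm)
    medoids = np.asarray(medoids, dtype=int)
    base = _swap_cost(d, medoids)
    others = np.setdiff1d(np.arange(d.shape[0]), medoids)
    for pos in range(len(medoids)):
        trial = medoids.copy()
        for cand in others:
            trial[pos] = cand
            if _swap_cost(d, trial) < base - 1e-12:
                return False
        trial[pos] = medoids[pos]
    return True


def _pam_single(d: np.ndarray, K: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    n = d.shape[0]
    medoids = np.sort(rng.choice(n, size=K, replace=False))
    cost = _swap_cost(d, medoids)
    while True:
        best_cost, best_swap = cost, None
        others = np.setdiff1d(np.arange(n), medoids)
        for pos in range(K):
            trial = medoids.copy()
            for cand in others:
                trial[pos] = cand
                c = _swap_cost(d, trial)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (pos, cand)
            trial[pos] = medoids[pos]
        if best_swap is None:
            return medoids, cost
        medoids[best_swap[0]] = best_swap[1]
        medoids = np.sort(medoids)
        cost = best_cost


def pam_cluster(
    dm: DistanceMatrix,
    K: int,
    restarts: int = 10,
    seed: int | None = None,
) -> ClusterSolution:
    """PAM k-medoids on a precomputed distance matrix.

    Each restart draws K random initial medoids and runs a steepest-descent
    swap phase (the single most cost-reducing medoid/non-medoid exchange is
    applied until none reduces the cost).  The best of ``restarts`` runs by
    total cost is returned; medoid indices are sorted so cluster numbering
    is stable.
    """
    n = dm.n
    if K < 2:
        raise ValueError("K must be at least 2")
    if K >= n:
        raise ValueError(f"K={K} must be smaller than the slot count {n}")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float] | None = None
    for _ in range(restarts):
        medoids, cost = _pam_single(dm.d, K, rng)
        if best is None or cost < best[1] - 1e-12:
            best = (medoids, cost)
    medoids, cost = best
    labels, cost = assign_to_medoids(dm.d, medoids)
    g = medoid_of(dm, range(n))
    return ClusterSolution(
        method="DTW-PAM",
        K=K,
        labels=labels,
        total_cost=cost,
        centroid_dist=dm.d[:, medoids],
        centroid_pair_dist=dm.d[np.ix_(medoids, medoids)],
        centroid_global_dist=dm.d[medoids, g],
        medoids=[int(m) for m in medoids],
        restarts=restarts,
        seed=seed,
    )


def solution_from_medoids(dm: DistanceMatrix, medoids: Sequence[int]) -> ClusterSolution:
    """Build a ClusterSolution from explicit medoid indices (testing and
    exhaustive-search baselines)."""
    medoids = np.asarray(sorted(medoids), dtype=int)
    labels, cost = assign_to_medoids(dm.d, medoids)
    g = medoid_of(dm, range(dm.n))
    return ClusterSolution(
        method="DTW-PAM",
        K=len(medoids),
        labels=labels,
        total_cost=cost,
        centroid_dist=dm.d[:, medoids],
        centroid_pair_dist=dm.d[np.ix_(medoids, medoids)],
        centroid_global_dist=dm.d[medoids, g],
        medoids=[int(m) for m in medoids],
    )


def dba_cluster(
    slots: Sequence,
    K: int,
    restarts: int = 10,
    seed: int | None = None,
    max_iter: int = 20,
    mode: str = "independent",
    dba_max_iter: int = 10,
    dm: DistanceMatrix | None = None,
    compute_global: bool = True,
) -> ClusterSolution:
    """K-means-style clustering with DBA-averaged centroid sequences.

    Slots are assigned to the nearest centroid by DTW distance, centroids
    are recomputed by :func:`swayclust.dtw.dba_average` (seeded with the
    current centroid), and the loop runs to an assignment fixed point or
    ``max_iter``.  A cluster emptied during iteration is re-seeded with the
    slot farthest from its nearest centroid.  Best of ``restarts`` by total
    cost.  ``dm``, when available, seeds the whole-data centroid average
    with the overall medoid for the Calinski-Harabasz reference.
    """
    from .dtw import _slot_arrays

    arrays, _ = _slot_arrays(slots)
    n = len(arrays)
    if K < 1:
        raise ValueError("K must be at least 1")
    if K >= n:
        raise ValueError(f"K={K} must be smaller than the slot count {n}")
    if K == 1:  # degenerate but well-defined: one DBA average of everything
        overall = dba_average(arrays, max_iter=dba_max_iter, mode=mode)
        cd = slot_to_centroid_distances(arrays, [overall], mode=mode)
        return ClusterSolution(
            method="DTW-DBA",
            K=1,
            labels=np.zeros(n, dtype=int),
            total_cost=float(cd.sum()),
            centroid_dist=cd,
            centroid_pair_dist=np.zeros((1, 1)),
            centroid_global_dist=np.zeros(1),
            centroids=[overall],
            restarts=restarts,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        idx = rng.choice(n, size=K, replace=False)
        centroids = [arrays[i].copy() for i in idx]
        labels = None
        for _ in range(max_iter):
            cd = slot_to_centroid_distances(arrays, centroids, mode=mode)
            new_labels = np.argmin(cd, axis=1)
            for k in range(K):  # re-seed emptied clusters with the worst-fit slot
                if not (new_labels == k).any():
                    far = int(np.argmax(cd[np.arange(n), new_labels]))
                    new_labels[far] = k
                    centroids[k] = arrays[far].copy()
            if labels is not None and np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
            centroids = [
                dba_average(
                    [arrays[i] for i in np.flatnonzero(labels == k)],
                    init=centroids[k],
                    max_iter=dba_max_iter,
                    mode=mode,
                )
                for k in range(K)
            ]
        cd = slot_to_centroid_distances(arrays, centroids, mode=mode)
        labels, cost = np.argmin(cd, axis=1), float(
            cd[np.arange(n), np.argmin(cd, axis=1)].sum()
        )
        if ((np.bincount(labels, minlength=K)) == 0).any():
            continue  # degenerate restart
        if best is None or cost < best[2] - 1e-12:
            best = (centroids, labels, cost, cd)
    if best is None:
        raise RuntimeError("all restarts collapsed to fewer than K clusters")
    centroids, labels, cost, cd = best
    pair = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            pair[i, j] = pair[j, i] = dtw_distance(
                centroids[i], centroids[j], mode=mode
            )
    global_dist = None
    if compute_global:
        init = arrays[medoid_of(dm, range(n))] if dm is not None else None
        overall = dba_average(arrays, init=init, max_iter=dba_max_iter, mode=mode)
        global_dist = np.array(
            [dtw_distance(c, overall, mode=mode) for c in centroids]
        )
    return ClusterSolution(
        method="DTW-DBA",
        K=K,
        labels=labels,
        total_cost=cost,
        centroid_dist=cd,
        centroid_pair_dist=pair,
        centroid_global_dist=global_dist,
        centroids=centroids,
        restarts=restarts,
        seed=seed,
    )
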