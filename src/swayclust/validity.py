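"""Cluster validity indices and the (slot length, K, method) grid search.

All three indices are computed in DTW-distance space, consistent with the
clustering geometry: "centroids" are the solution's medoids (PAM) or DBA
averages, and squared DTW distances stand in for squared Euclidean ones in
the Calinski-Harabasz sums.  Davies-Bouldin is lower-better;
Calinski-Harabasz and Dunn are higher-better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cluster import ClusterSolution, dba_cluster, pam_cluster
from .dtw import DistanceMatrix, dtw_distance_matrix
from .preprocess import PreprocessConfig, preprocess_cohort


def _deltas(solution: ClusterSolution) -> np.ndarray:
    """Mean distance of each cluster's members to their own centroid."""
    return np.array(
        [
            solution.centroid_dist[solution.members(k), k].mean()
            for k in range(solution.K)
        ]
    )


def davies_bouldin(solution: ClusterSolution) -> float:
    """DB = (1/K) sum_i max_{j != i} (delta_i + delta_j) / d(c_i, c_j).

    delta_i is the mean distance of cluster i's members to its centroid and
    d(c_i, c_j) the centroid-centroid distance.  Lower is better.
    """
    if solution.K < 2:
        raise ValueError("Davies-Bouldin requires at least two clusters")
    pair = solution.centroid_pair_dist
    off = ~np.eye(solution.K, dtype=bool)
    if (pair[off] == 0).any():
        raise ValueError("degenerate solution: coincident centroids")
    delta = _deltas(solution)
    ratio = (delta[:, None] + delta[None, :]) / np.where(off, pair, np.inf)
    return float(np.where(off, ratio, -np.inf).max(axis=1).mean())


def calinski_harabasz(solution: ClusterSolution) -> float:
    """C-H = [(N-K)/(K-1)] * BGSS/WGSS with squared DTW distances.

    WGSS sums each slot's squared distance to its own centroid; BGSS sums
    n_i times the squared distance of centroid i to the whole-data centroid
    (the overall medoid for PAM, the overall DBA average for DBA).  Higher
    is better.
    """
    if solution.K < 2:
        raise ValueError("Calinski-Harabasz requires at least two clusters")
    if solution.centroid_global_dist is None:
        raise ValueError("solution lacks centroid-to-global distances")
    n = solution.n
    if n <= solution.K:
        raise ValueError("need more slots than clusters")
    own = solution.centroid_dist[np.arange(n), solution.labels]
    wgss = float(np.sum(own**2))
    sizes = np.bincount(solution.labels, minlength=solution.K)
    bgss = float(np.sum(sizes * solution.centroid_global_dist**2))
    if wgss == 0.0:
        warnings.warn("zero within-cluster scatter; C-H is infinite")
        return float("inf")
    return (n - solution.K) / (solution.K - 1) * bgss / wgss


def dunn_index(dm: DistanceMatrix, solution: ClusterSolution) -> float:
    """D = (min between-cluster slot distance) / (max cluster diameter).

    Higher is better; a zero diameter (all clusters internally identical)
    yields +inf with a warning.
    """
    if solution.K < 2:
        raise ValueError("Dunn requires at least two clusters")
    labels = solution.labels
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(len(labels), dtype=bool)
    d_min = float(dm.d[~same].min())
    intra = dm.d[same & off_diag]
    d_max = float(intra.max()) if intra.size else 0.0
    if d_max == 0.0:
        warnings.warn("zero within-cluster diameter; Dunn is infinite")
        return float("inf")
    return d_min / d_max


def solution_validity(dm: DistanceMatrix, solution: ClusterSolution) -> dict:
    return {
        "ch": calinski_harabasz(solution),
        "db": davies_bouldin(solution),
        "dunn": dunn_index(dm, solution),
    }


@dataclass(frozen=True)
class GridConfig:
    restarts: int = 10
    seed: int | None = None
    mode: str = "independent"
    preprocess: PreprocessConfig = PreprocessConfig()
    dba_max_iter: int = 10
    max_iter: int = 20


def select_best(report: pd.DataFrame, rule: str = "vote") -> int:
    """Pick the report row of the best (t, K, method) cell.

    ``vote``: majority rank vote — each index ranks every cell (C-H and
    Dunn descending, DB ascending) and the cell with the smallest rank sum
    wins, ties broken by the larger C-H.  ``ch``/``db``/``dunn``:
    single-index selection.
    """
    if rule == "ch":
        return int(report["ch"].idxmax())
    if rule == "db":
        return int(report["db"].idxmin())
    if rule == "dunn":
        return int(report["dunn"].idxmax())
    if rule != "vote":
        raise ValueError(f"unknown selection rule {rule!r}")
    rank_sum = (
        report["ch"].rank(ascending=False)
        + report["db"].rank(ascending=True)
        + report["dunn"].rank(ascending=False)
    )
    top = rank_sum[rank_sum == rank_sum.min()].index
    return int(report.loc[top, "ch"].idxmax())


def grid_search(
    cohort: list,
    ts: list[float],
    Ks: list[int],
    methods: tuple[str, ...] = ("DTW-PAM",),
    config: GridConfig | None = None,
    rule: str = "vote",
    return_solutions: bool = False,
):
    """Cluster validity over the (slot length, cluster count, method) grid.

    Per cell: preprocess the cohort at slot length t, compute the DTW
    distance matrix (shared across K and methods for that t), cluster with
    the configured restarts, and score the winning solution with the three
    indices.  The returned DataFrame mirrors the validity-table layout
    (t, K, method, C-H, DB, D) with the selected cell flagged.
    """
    if not ts or not Ks or not methods:
        raise ValueError("grids must be non-empty")
    config = config or GridConfig()
    rows = []
    solutions = {}
    for t in ts:
        slots = preprocess_cohort(cohort, t, config.preprocess)
        dm = dtw_distance_matrix(slots, mode=config.mode)
        for method in methods:
            for K in Ks:
                if method == "DTW-PAM":
                    sol = pam_cluster(
                        dm, K, restarts=config.restarts, seed=config.seed
                    )
                elif method == "DTW-DBA":
                    sol = dba_cluster(
                        slots,
                        K,
                        restarts=config.restarts,
                        seed=config.seed,
                        max_iter=config.max_iter,
                        mode=config.mode,
                        dba_max_iter=config.dba_max_iter,
                        dm=dm,
                    )
                else:
                    raise ValueError(f"unknown method {method!r}")
                scores = solution_validity(dm, sol)
                rows.append({"t": t, "K": K, "method": method, **scores})
                solutions[(t, K, method)] = (sol, dm, slots)
    report = pd.DataFrame(rows)
    report["chosen"] = False
    best = select_best(report, rule=rule)
    report.loc[best, "chosen"] = True
    if return_solutions:
        return report, solutions
    return report
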