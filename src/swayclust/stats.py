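"""Post-hoc comparisons between clusters and the transition summaries.

For every (kinematic variable, sway parameter) pair the per-cluster value
groups are first gated: if every group passes Shapiro-Wilk normality and
the groups pass Bartlett's homogeneity test, pairwise comparisons use
Tukey-Kramer; otherwise a pairwise rank-sum (Mann-Whitney) test with
Benjamini-Hochberg adjustment across the C(K,2) pairs of that row.  Slots
from one recording are treated as independent observations — a property of
the procedure being reproduced, not a statistical endorsement.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterSolution
from .features import PARAMETERS
from .preprocess import Slot


def gate_test_choice(
    groups: list[np.ndarray], alpha_gate: float = 0.05
) -> str:
    """Choose ``'tukey'`` or ``'wilcoxon'`` for a family of cluster groups.

    Tukey-Kramer is used only when every group passes Shapiro-Wilk
    (p >= alpha_gate) AND Bartlett's test passes; any failure — including a
    constant group, on which Shapiro-Wilk is undefined — falls back to the
    rank-based branch.  Groups with fewer than 3 values are excluded with a
    warning.
    """
    usable = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        g = g[np.isfinite(g)]
        if len(g) < 3:
            warnings.warn("group with fewer than 3 values excluded from gate")
            continue
        usable.append(g)
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 3 values")
    for g in usable:
        if np.ptp(g) == 0:
            return "wilcoxon"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if sps.shapiro(g).pvalue < alpha_gate:
                return "wilcoxon"
    if sps.bartlett(*usable).pvalue < alpha_gate:
        return "wilcoxon"
    return "tukey"


def _pair_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 1.0  # identical constant groups carry no evidence
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def pairwise_wilcoxon_bh(
    groups: list[np.ndarray], alpha: float = 0.05
) -> tuple[set[tuple[int, int]], dict[tuple[int, int], float]]:
    """Rank-sum test per unordered cluster pair with BH adjustment.

    Groups are independent slot sets, so the rank-sum (Mann-Whitney) form
    of the Wilcoxon test applies.  All C(K,2) p-values of the family are
    adjusted jointly; pairs with adjusted p < alpha are returned, keyed by
    0-based group indices.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pairs = list(combinations(range(len(arrays)), 2))
    raw = np.array([_pair_pvalue(arrays[i], arrays[j]) for i, j in pairs])
    adjusted = benjamini_hochberg(raw)
    adj = dict(zip(pairs, adjusted))
    significant = {p for p in pairs if adj[p] < alpha}
    return significant, adj


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, >= raw)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def pairwise_tukey(
    groups: list[np.ndarray], alpha: float = 0.05
) -> tuple[set[tuple[int, int]], dict[tuple[int, int], float]]:
    """Tukey-Kramer pairwise comparison (studentized range)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    res = sps.tukey_hsd(*arrays)
    pairs = list(combinations(range(len(arrays)), 2))
    adj = {(i, j): float(res.pvalue[i, j]) for i, j in pairs}
    significant = {p for p in pairs if adj[p] < alpha}
    return significant, adj


def _format_pairs(pairs: set[tuple[int, int]]) -> str:
    if not pairs:
        return "None"
    return ", ".join(f"{i + 1}&{j + 1}" for i, j in sorted(pairs))


def build_significance_table(
    features: pd.DataFrame,
    alpha: float = 0.05,
    alpha_gate: float = 0.05,
) -> pd.DataFrame:
    """Which cluster pairs differ, per kinematic variable and parameter.

    ``features`` is the frame from :func:`swayclust.features.featurize`
    with 1-based cluster labels attached.  Returns one row per variable
    with, per parameter, the significant pair set (rendered ``"1&2, 1&3"``
    or ``"None"``) and the branch taken.  NaN values (e.g. the frequency of
    a constant series) are dropped within their group.
    """
    clusters = sorted(features["cluster"].unique())
    if len(clusters) < 2 or 0 in clusters:
        raise ValueError("features must carry >= 2 real cluster labels")
    rows = []
    for (index, part, side, axis), sub in features.groupby(
        ["index", "part", "side", "axis"], sort=True
    ):
        row = {"index": index, "part": part, "side": side, "axis": axis}
        for parameter in PARAMETERS:
            groups = [
                sub.loc[sub["cluster"] == c, parameter].dropna().to_numpy()
                for c in clusters
            ]
            branch = gate_test_choice(groups, alpha_gate=alpha_gate)
            if branch == "tukey":
                sig, _ = pairwise_tukey(groups, alpha=alpha)
            else:
                sig, _ = pairwise_wilcoxon_bh(groups, alpha=alpha)
            row[f"{parameter}_pairs"] = _format_pairs(sig)
            row[f"{parameter}_branch"] = branch
        rows.append(row)
    return pd.DataFrame(rows).sort_values("index").reset_index(drop=True)


def order_clusters_by_onset(
    slots: list[Slot], solution: ClusterSolution
) -> ClusterSolution:
    """Renumber clusters by decreasing median days after onset.

    Cluster labels out of PAM/DBA are arbitrary; the reporting convention
    used here numbers them so cluster 1 has the largest median onset days
    (the most chronic group) and cluster K the smallest, which makes
    recovery-related drift read as K -> ... -> 1.  Ties break by the
    original index.
    """
    if len(slots) != solution.n:
        raise ValueError("slot list and solution size differ")
    import dataclasses

    onset = np.array([s.metadata.get("days_after_onset", -1) for s in slots])
    medians = [
        float(np.median(onset[solution.members(k)])) for k in range(solution.K)
    ]
    order = sorted(range(solution.K), key=lambda k: (-medians[k], k))
    perm = np.empty(solution.K, dtype=int)  # old label -> new label
    for new, old in enumerate(order):
        perm[old] = new
    return dataclasses.replace(
        solution,
        labels=perm[solution.labels],
        centroid_dist=solution.centroid_dist[:, order],
        centroid_pair_dist=solution.centroid_pair_dist[np.ix_(order, order)],
        centroid_global_dist=(
            None
            if solution.centroid_global_dist is None
            else solution.centroid_global_dist[order]
        ),
        medoids=(
            None
            if solution.medoids is None
            else [solution.medoids[k] for k in order]
        ),
        centroids=(
            None
            if solution.centroids is None
            else [solution.centroids[k] for k in order]
        ),
    )


def build_transition_table(
    slots: list[Slot], solution: ClusterSolution
) -> pd.DataFrame:
    """Per-recording slot labels and majority cluster, by onset day.

    One row per (subject, session), sorted by subject then days after
    onset, with the 1-based label of every slot, the majority label
    (ties -> lower cluster index, flagged) and the disease type.  Rows with
    missing subject metadata are flagged rather than dropped.
    """
    if len(slots) != solution.n:
        raise ValueError("slot list and solution size differ")
    per_rec: dict[int, dict] = {}
    for s_idx, slot in enumerate(slots):
        entry = per_rec.setdefault(
            slot.recording_index,
            {
                "subject_id": slot.metadata.get("subject_id"),
                "disease": slot.metadata.get("disease"),
                "days_after_onset": slot.metadata.get("days_after_onset"),
                "labels": {},
            },
        )
        entry["labels"][slot.slot_index] = int(solution.labels[s_idx]) + 1
    rows = []
    for rec_idx in sorted(per_rec):
        entry = per_rec[rec_idx]
        labels = [entry["labels"][k] for k in sorted(entry["labels"])]
        counts = pd.Series(labels).value_counts()
        top = counts[counts == counts.max()].index
        majority = int(min(top))
        flagged = entry["subject_id"] is None or entry["days_after_onset"] in (
            None,
            -1,
        )
        rows.append(
            {
                "subject_id": entry["subject_id"],
                "disease": entry["disease"],
                "days_after_onset": entry["days_after_onset"],
                "slot_labels": " ".join(str(v) for v in labels),
                "majority": majority,
                "tie": len(top) > 1,
                "metadata_missing": flagged,
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["subject_id", "days_after_onset"], kind="stable"
    ).reset_index(drop=True)


def cluster_characteristics(
    slots: list[Slot], solution: ClusterSolution
) -> pd.DataFrame:
    """Median onset days and age, and disease mix, per cluster (1-based)."""
    if len(slots) != solution.n:
        raise ValueError("slot list and solution size differ")
    records = pd.DataFrame(
        {
            "cluster": solution.labels + 1,
            "days_after_onset": [s.metadata.get("days_after_onset") for s in slots],
            "age": [s.metadata.get("age") for s in slots],
            "disease": [s.metadata.get("disease") for s in slots],
        }
    )
    rows = []
    for c, sub in records.groupby("cluster"):
        mix = sub["disease"].value_counts(normalize=True)
        rows.append(
            {
                "cluster": c,
                "days_after_onset": float(sub["days_after_onset"].median()),
                "age": float(sub["age"].median()),
                "frac_CH": float(mix.get("CH", 0.0)),
                "frac_CI": float(mix.get("CI", 0.0)),
            }
        )
    return pd.DataFrame(rows)
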