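#!/usr/bin/env python
"""Cluster the cohort at the selected configuration and extract sway
features.

Uses the configuration flagged in results/validity_grid.csv (falling back
to t=5 s, K=4, DTW-PAM if the grid has not been run), assigns every 5-s
slot to a cluster, and writes:

- results/cluster_characteristics.csv — median days after onset, median
  age and disease mix per cluster;
- results/sway_feature_medians.csv — median amplitude, SD and sway
  frequency per (body part, side, axis, cluster);
- scratch/sway_features.csv — the full per-slot, per-variable feature
  table (large);
- scratch/figures/ — box plots of medial-lateral amplitude and frequency
  by cluster.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import COHORT_SEED, RESULTS, SCRATCH, load_cohort, slots_and_distances

from swayclust.cluster import dba_cluster, pam_cluster
from swayclust.features import featurize
from swayclust.plots import parameter_boxplot
from swayclust.stats import cluster_characteristics, order_clusters_by_onset


def selected_configuration():
    grid_path = os.path.join(RESULTS, "validity_grid.csv")
    if os.path.exists(grid_path):
        grid = pd.read_csv(grid_path)
        sel = grid[grid["chosen"]].iloc[0]
        return float(sel["t"]), int(sel["K"]), sel["method"]
    return 5.0, 4, "DTW-PAM"


def main():
    t, K, method = selected_configuration()
    print(f"configuration: t={t:g}s, K={K}, {method}")
    recs = load_cohort()
    slots, dm = slots_and_distances(recs, t)
    if method == "DTW-PAM":
        sol = pam_cluster(dm, K, restarts=10, seed=COHORT_SEED)
    else:
        sol = dba_cluster(slots, K, restarts=3, seed=COHORT_SEED, dm=dm)
    sol = order_clusters_by_onset(slots, sol)  # cluster 1 = most chronic
    chars = cluster_characteristics(slots, sol)
    chars.to_csv(os.path.join(RESULTS, "cluster_characteristics.csv"), index=False)
    print(chars.to_string(index=False))

    feats = featurize(slots, sol)
    feats.to_csv(os.path.join(SCRATCH, "sway_features.csv"), index=False)
    medians = (
        feats.groupby(["part", "side", "axis", "cluster"])[
            ["amplitude", "sd", "frequency"]
        ]
        .median()
        .reset_index()
    )
    medians.to_csv(os.path.join(RESULTS, "sway_feature_medians.csv"), index=False)

    figdir = os.path.join(SCRATCH, "figures")
    os.makedirs(figdir, exist_ok=True)
    for parameter in ("amplitude", "frequency"):
        parameter_boxplot(
            feats,
            parameter=parameter,
            axis="X",
            side="Left",
            out=os.path.join(figdir, f"{parameter}_ml_by_cluster.png"),
        )
    com_x = medians[(medians["part"] == "com") & (medians["axis"] == "X")]
    print("\nCOM medial-lateral medians by cluster:")
    print(com_x.to_string(index=False))
    print("wrote results/cluster_characteristics.csv, results/sway_feature_medians.csv")


if __name__ == "__main__":
    main()
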