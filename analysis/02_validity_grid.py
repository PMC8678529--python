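#!/usr/bin/env python
"""Cluster-validity grid over slot length, cluster count and method.

For every combination of slot length t in {3, 5, 6, 10} s, K in {3, 4, 5}
and method in {DTW-PAM, DTW-DBA}, clusters the cohort's slots on the DTW
distance matrix and scores the winning solution with the Calinski-Harabasz,
Davies-Bouldin and Dunn indices.  PAM runs with the protocol's 10 random
restarts; the DBA variant uses 3 restarts and capped iterations, a runtime
compromise for the twelve-cell grid (each DBA cell re-averages centroid
sequences under DTW alignment).  Writes results/validity_grid.csv with the
selected configuration flagged.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import COHORT_SEED, RESULTS, load_cohort, slots_and_distances

from swayclust.cluster import dba_cluster, pam_cluster
from swayclust.validity import select_best, solution_validity

TS = (3.0, 5.0, 6.0, 10.0)
KS = (3, 4, 5)


def main():
    recs = load_cohort()
    rows = []
    for t in TS:
        slots, dm = slots_and_distances(recs, t)
        print(f"t={t:g}s: {len(slots)} slots")
        for K in KS:
            pam = pam_cluster(dm, K, restarts=10, seed=COHORT_SEED)
            rows.append(
                {"t": t, "K": K, "method": "DTW-PAM", **solution_validity(dm, pam)}
            )
            dba = dba_cluster(
                slots,
                K,
                restarts=3,
                seed=COHORT_SEED,
                max_iter=8,
                dba_max_iter=5,
                dm=dm,
            )
            rows.append(
                {"t": t, "K": K, "method": "DTW-DBA", **solution_validity(dm, dba)}
            )
            print(f"  K={K}: PAM C-H {rows[-2]['ch']:.1f}, DBA C-H {rows[-1]['ch']:.1f}")
    report = pd.DataFrame(rows)
    report["chosen"] = False
    best = select_best(report, rule="vote")
    report.loc[best, "chosen"] = True
    os.makedirs(RESULTS, exist_ok=True)
    report.to_csv(os.path.join(RESULTS, "validity_grid.csv"), index=False)
    sel = report.loc[best]
    print(
        f"\nselected: t={sel['t']:g}s, K={sel['K']}, {sel['method']} "
        f"(C-H {sel['ch']:.1f}, DB {sel['db']:.2f}, D {sel['dunn']:.3f})"
    )
    print("wrote results/validity_grid.csv")


if __name__ == "__main__":
    main()
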