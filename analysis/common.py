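"""Shared configuration for the analysis drivers.

The study cohort is fully synthetic and deterministic: 31 quiet-standing
recordings (30 s at 60 Hz, 33 kinematic variables) over 10 post-stroke
subjects, with the planted sway regime drifting with days after onset for
the hemorrhage (CH) subjects and onset-independent for the infarction (CI)
subjects.  Recordings are written once under scratch/ (large raw CSVs);
distance matrices are cached there as .npy so later drivers reuse them.
"""

from __future__ import annotations

import os

import numpy as np

from swayclust.dtw import DistanceMatrix, dtw_distance_matrix
from swayclust.io import read_cohort, write_cohort
from swayclust.preprocess import preprocess_cohort
from swayclust.synthetic import CohortSpec, generate_cohort, planted_onset_drift

COHORT_SEED = 42
ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
SCRATCH = os.path.join(ROOT, "scratch")
RESULTS = os.path.join(ROOT, "results")
COHORT_DIR = os.path.join(SCRATCH, "cohort")


def cohort_spec() -> CohortSpec:
    return planted_onset_drift(CohortSpec(seed=COHORT_SEED))


def build_cohort():
    """Generate (or reload) the study cohort and its ground truth."""
    spec = cohort_spec()
    recs, truth = generate_cohort(spec)
    if not os.path.exists(os.path.join(COHORT_DIR, "metadata.yaml")):
        write_cohort(recs, COHORT_DIR)
    return recs, truth


def load_cohort():
    """Reload the cohort from disk through the CSV reader (round-trip)."""
    if not os.path.exists(os.path.join(COHORT_DIR, "metadata.yaml")):
        build_cohort()
    return read_cohort(COHORT_DIR)


def slots_and_distances(recs, t: float, mode: str = "independent"):
    """Preprocessed slots plus the (cached) DTW distance matrix at slot
    length t."""
    slots = preprocess_cohort(recs, t)
    cache = os.path.join(SCRATCH, f"dm_t{t:g}_{mode}.npy")
    if os.path.exists(cache):
        d = np.load(cache)
        dm = DistanceMatrix(d, [s.source_id for s in slots])
    else:
        dm = dtw_distance_matrix(slots, mode=mode)
        os.makedirs(SCRATCH, exist_ok=True)
        np.save(cache, dm.d)
    return slots, dm
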