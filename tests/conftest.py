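import numpy as np
import pytest

from swayclust.io import COLUMNS, MARKERS, Recording
from swayclust.synthetic import CohortSpec, generate_cohort


def standing_recording(
    n_samples: int = 600,
    rate: float = 60.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> Recording:
    """A plausible static standing pose, optionally jittered."""
    rng = np.random.default_rng(seed)
    pose = np.zeros(33)
    heights = {"shoulder": 1400.0, "hip": 900.0, "knee": 500.0, "ankle": 80.0, "toe": 0.0}
    for part, side in MARKERS.sources:
        if part == "com":
            continue
        sgn = -1.0 if side == "L" else 1.0
        cols = MARKERS.source_columns(part, side)
        pose[cols] = (sgn * 120.0, 0.0, heights[part])
    pose[MARKERS.source_columns("com", None)] = (0.0, 0.0, 950.0)
    data = np.tile(pose, (n_samples, 1))
    if jitter:
        data = data + rng.normal(0.0, jitter, size=data.shape)
    return Recording(subject_id="S1", data=data, rate=rate)


@pytest.fixture
def static_rec() -> Recording:
    return standing_recording()


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 2-subject, 2-cluster cohort (15 s recordings)."""
    from swayclust.synthetic import SubjectSpec

    spec = CohortSpec(
        roster=(
            SubjectSpec("A1", "CH", 60, (100, 200, 300), "left"),
            SubjectSpec("A2", "CI", 70, (100, 400, 800), "right"),
        ),
        k_true=2,
        cluster_frequencies=(0.6, 1.2),
        cluster_amplitude=(1.0, 6.0),
        duration=15.0,
        seed=11,
    )
    return generate_cohort(spec)
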