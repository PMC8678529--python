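"""Synthetic quiet-standing cohorts with planted cluster structure.

Each recording is a static standing pose (built from the subject's segment
lengths) plus postural sway: one dominant sinusoid per recording whose
frequency and amplitude are set by the recording's planted cluster, with
low-pass-filtered Gaussian measurement noise per channel.  Sway frequencies
default to the 0.5-1.5 Hz band observed in quiet standing, amplitudes are
larger for the trunk (shoulder, hip, COM) than for the leg markers, and the
COM is a fixed-weight average of the ten markers, so height scaling and COM
features are exercised end-to-end.  Cohort metadata (subjects, stroke
subtype, age, measurement days after onset, hemiplegic side) follows the
clinical-cohort schema this generator emulates.

The generator is deterministic given the spec's seed: identical specs give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .io import AXES, MARKERS, Recording


@dataclass(frozen=True)
class SubjectSpec:
    subject_id: str
    disease: str
    age: float
    days_after_onset: tuple[int, ...]
    hemiplegia: str


#: Default cohort roster: 10 male post-stroke subjects (5 CH, 5 CI) with
#: repeated sessions, 31 recordings in total.
DEFAULT_ROSTER: tuple[SubjectSpec, ...] = (
    SubjectSpec("CH1", "CH", 54, (1108, 1150), "right"),
    SubjectSpec("CH2", "CH", 48, (122, 129, 136, 143), "left"),
    SubjectSpec("CH3", "CH", 59, (51, 58, 65, 79, 93), "left"),
    SubjectSpec("CH4", "CH", 63, (520, 527, 534), "either"),
    SubjectSpec("CH5", "CH", 54, (315, 340, 358), "right"),
    SubjectSpec("CI1", "CI", 52, (74, 88, 109, 176), "right"),
    SubjectSpec("CI2", "CI", 75, (132, 147), "left"),
    SubjectSpec("CI3", "CI", 80, (69, 80), "right"),
    SubjectSpec("CI4", "CI", 63, (91, 108), "left"),
    SubjectSpec("CI5", "CI", 69, (992, 1007, 1020, 1051), "right"),
)

#: Baseline sway amplitude (mm) per marker: trunk markers sway more than the
#: leg, decreasing from shoulder to toe.
DEFAULT_MARKER_AMPLITUDE: Mapping[str, float] = {
    "shoulder": 14.0,
    "hip": 10.0,
    "knee": 3.5,
    "ankle": 1.5,
    "toe": 1.0,
}

#: Anthropometric COM weights per marker (both sides together they sum to 1);
#: trunk-heavy, placing the COM amplitude between hip and shoulder.
DEFAULT_COM_WEIGHTS: Mapping[str, float] = {
    "shoulder": 0.20,
    "hip": 0.22,
    "knee": 0.05,
    "ankle": 0.02,
    "toe": 0.01,
}

#: Sway is largest medial-laterally, smaller antero-posteriorly, smallest
#: vertically.
DEFAULT_AXIS_FACTORS: Mapping[str, float] = {"X": 1.0, "Y": 0.8, "Z": 0.4}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults emulate the clinical recording protocol: 60 Hz for 30 s, 31
    sessions over 10 subjects, four planted sway regimes with frequencies
    inside 0.5-1.5 Hz (multiples of the 0.2 Hz resolution of a 5-s slot)
    and well-separated amplitude multipliers, assigned per recording.
    Multipliers are spaced by a constant additive gap: within-regime DTW
    scatter grows linearly with amplitude, so equal gaps keep every
    adjacent pair of regimes separated by a margin that dominates the
    scatter of the largest one.
    """

    roster: tuple[SubjectSpec, ...] = DEFAULT_ROSTER
    k_true: int = 4
    cluster_frequencies: tuple[float, ...] = (0.6, 0.8, 1.2, 1.4)
    cluster_amplitude: tuple[float, ...] = (1.0, 5.0, 9.0, 13.0)
    marker_amplitude_mm: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_AMPLITUDE)
    )
    com_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COM_WEIGHTS)
    )
    axis_factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AXIS_FACTORS)
    )
    noise_sd_mm: float = 0.5
    noise_cutoff_hz: float = 5.0
    hemiplegia_ratio: float = 1.0
    segment_lengths_mm: tuple[float, float, float] = (500.0, 430.0, 420.0)
    stature_range: tuple[float, float] = (0.9, 1.1)
    rate: float = 60.0
    duration: float = 30.0
    cluster_assignment: Mapping[tuple[str, int], int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cluster_frequencies) != self.k_true:
            raise ValueError("one frequency per planted cluster required")
        if len(self.cluster_amplitude) != self.k_true:
            raise ValueError("one amplitude multiplier per cluster required")
        nyq = self.rate / 2
        if not all(0 < f < nyq for f in self.cluster_frequencies):
            raise ValueError(f"frequencies must lie in (0, {nyq}) Hz")
        if not all(a > 0 for a in self.cluster_amplitude):
            raise ValueError("amplitude multipliers must be positive")
        amps = self.marker_amplitude_mm
        if not (
            min(amps["shoulder"], amps["hip"])
            > amps["knee"]
            > max(amps["ankle"], amps["toe"])
        ):
            raise ValueError(
                "marker amplitudes must decrease from trunk to foot"
            )
        if self.noise_sd_mm < 0 or self.hemiplegia_ratio <= 0:
            raise ValueError("invalid noise or asymmetry parameter")

    @property
    def n_recordings(self) -> int:
        return sum(len(s.days_after_onset) for s in self.roster)

    def sessions(self) -> list[tuple[SubjectSpec, int]]:
        return [
            (subj, day) for subj in self.roster for day in subj.days_after_onset
        ]


@dataclass
class GroundTruth:
    """Planted cluster id per recording, inherited by each of its slots."""

    recording_labels: np.ndarray
    session_keys: list[tuple[str, int]]

    def slot_labels(self, slots) -> np.ndarray:
        """Expand recording labels to a pooled slot list (via
        ``recording_index``)."""
        return np.array(
            [self.recording_labels[s.recording_index] for s in slots]
        )


def _default_assignment(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_recordings
    base = np.tile(np.arange(spec.k_true), n // spec.k_true + 1)[:n]
    return rng.permutation(base)


def planted_onset_drift(
    spec: CohortSpec,
    schedule: Sequence[tuple[float, int]] | None = None,
) -> CohortSpec:
    """Assign true clusters as a step function of days after onset (CH only).

    ``schedule`` is a list of (day upper bound, 0-based cluster) steps; the
    default four-step schedule sends early-onset CH sessions to cluster 4
    (1-based) and late ones down to cluster 1, mirroring a gradual recovery
    drift.  CI subjects keep one onset-independent cluster each, drawn
    deterministically from the spec seed.  Days beyond the last bound raise.
    """
    if schedule is None:
        if spec.k_true != 4:
            raise ValueError("default schedule requires k_true=4")
        schedule = [(180, 3), (420, 2), (900, 1), (float("inf"), 0)]
    rng = np.random.default_rng(spec.seed + 1)
    assignment: dict[tuple[str, int], int] = {}
    for subj in spec.roster:
        if subj.disease == "CH":
            for day in subj.days_after_onset:
                for bound, cluster in schedule:
                    if day <= bound:
                        assignment[(subj.subject_id, day)] = cluster
                        break
                else:
                    raise ValueError(
                        f"day {day} not covered by the drift schedule"
                    )
        else:
            cluster = int(rng.integers(spec.k_true))
            for day in subj.days_after_onset:
                assignment[(subj.subject_id, day)] = cluster
    return replace(spec, cluster_assignment=assignment)


def _static_pose(spec: CohortSpec, stature: float) -> np.ndarray:
    """(33,) canonical-order rest position of all sources, mm."""
    l1, l2, l3 = (v * stature for v in spec.segment_lengths_mm)
    z_ankle = 80.0 * stature
    z_knee, z_hip, z_shoulder = z_ankle + l3, z_ankle + l3 + l2, z_ankle + l3 + l2 + l1
    half_width = {
        "shoulder": 180.0,
        "hip": 120.0,
        "knee": 110.0,
        "ankle": 100.0,
        "toe": 100.0,
    }
    height = {
        "shoulder": z_shoulder,
        "hip": z_hip,
        "knee": z_knee,
        "ankle": z_ankle,
        "toe": 0.0,
    }
    pose = np.zeros(33)
    for part, side in MARKERS.sources:
        if part == "com":
            continue
        sgn = -1.0 if side == "L" else 1.0
        x = sgn * half_width[part] * stature
        y = 150.0 * stature if part == "toe" else 0.0
        cols = MARKERS.source_columns(part, side)
        pose[cols] = (x, y, height[part])
    return pose


def _fill_com(data: np.ndarray, weights: Mapping[str, float]) -> None:
    com = np.zeros((data.shape[0], 3))
    for part, side in MARKERS.sources:
        if part == "com":
            continue
        com += weights[part] * data[:, MARKERS.source_columns(part, side)]
    data[:, MARKERS.source_columns("com", None)] = com


def generate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[list[Recording], GroundTruth]:
    """Generate the cohort described by ``spec``.

    Returns the recordings (one per roster session, canonical 33-column
    arrays in mm) and the planted ground truth.  ``seed`` overrides
    ``spec.seed`` when given.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sessions = spec.sessions()
    if spec.cluster_assignment is None:
        labels = _default_assignment(spec, rng)
    else:
        try:
            labels = np.array(
                [
                    spec.cluster_assignment[(subj.subject_id, day)]
                    for subj, day in sessions
                ]
            )
        except KeyError as exc:
            raise ValueError(f"cluster_assignment missing session {exc}") from exc
    if ((labels < 0) | (labels >= spec.k_true)).any():
        raise ValueError("cluster assignment outside 0..k_true-1")

    n_samples = int(round(spec.rate * spec.duration))
    tgrid = np.arange(n_samples) / spec.rate
    stature = {
        subj.subject_id: rng.uniform(*spec.stature_range) for subj in spec.roster
    }
    sos = signal.butter(
        2, spec.noise_cutoff_hz, btype="low", fs=spec.rate, output="sos"
    )
    recordings = []
    for (subj, day), cluster in zip(sessions, labels):
        freq = spec.cluster_frequencies[cluster]
        mult = spec.cluster_amplitude[cluster]
        pose = _static_pose(spec, stature[subj.subject_id])
        data = np.tile(pose, (n_samples, 1))
        for part, side in MARKERS.sources:
            if part == "com":
                continue
            amp = spec.marker_amplitude_mm[part] * mult
            if (
                spec.hemiplegia_ratio != 1.0
                and subj.hemiplegia in ("left", "right")
                and side == subj.hemiplegia[0].upper()
            ):
                amp *= spec.hemiplegia_ratio
            cols = MARKERS.source_columns(part, side)
            for a, axis in enumerate(AXES):
                # independent phase per channel: within-cluster differences
                # spread over all 30 marker channels instead of lying on a
                # single low-dimensional phase arc
                phase = rng.uniform(0, 2 * np.pi)
                sway = (
                    amp
                    * spec.axis_factors[axis]
                    * np.sin(2 * np.pi * freq * tgrid + phase)
                )
                noise = rng.normal(0.0, 1.0, n_samples)
                if spec.noise_sd_mm > 0:
                    noise = signal.sosfiltfilt(sos, noise)
                    noise *= spec.noise_sd_mm / max(noise.std(), 1e-12)
                else:
                    noise = np.zeros(n_samples)
                data[:, cols.start + a] += sway + noise
        _fill_com(data, spec.com_weights)
        recordings.append(
            Recording(
                subject_id=subj.subject_id,
                disease=subj.disease,
                age=subj.age,
                days_after_onset=day,
                hemiplegia=subj.hemiplegia,
                rate=spec.rate,
                data=data,
            )
        )
    truth = GroundTruth(
        recording_labels=labels.copy(),
        session_keys=[(subj.subject_id, day) for subj, day in sessions],
    )
    return recordings, truth
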