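"""Standardise raw recordings into fixed-length, dimensionless data slots.

The pipeline is: offset so the ankle-pair midpoint is the origin, rescale by
the summed shoulder-hip-knee-ankle segment lengths (removing anthropometric
differences between subjects), low-pass filter (double-pass 2nd-order
Butterworth, 12 Hz cutoff), then slice the recording into consecutive
non-overlapping t-second slots — the units that are clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import AXES, MARKERS, Recording


@dataclass(frozen=True)
class SegmentLengths:
    """Mean shoulder-hip (l1), hip-knee (l2) and knee-ankle (l3) distances.

    Means are over all samples and both body sides, in the recording's
    units.  Their sum is the height proxy used for scaling.
    """

    l1: float
    l2: float
    l3: float

    def __post_init__(self) -> None:
        if min(self.l1, self.l2, self.l3) <= 0:
            raise ValueError("segment lengths must be positive")

    @property
    def total(self) -> float:
        return self.l1 + self.l2 + self.l3


@dataclass
class Slot:
    """One t-second window of a preprocessed recording.

    ``data`` has shape (rate*t, 33), dimensionless after scaling.
    """

    source_id: str
    data: np.ndarray
    rate: float
    recording_index: int
    slot_index: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 33:
            raise ValueError("slot data must have 33 columns")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def variable(self, index: int) -> np.ndarray:
        return self.data[:, index]


@dataclass(frozen=True)
class PreprocessConfig:
    slot_seconds: float = 5.0
    filter_cutoff_hz: float = 12.0
    filter_order: int = 2
    interpolate_gaps: int = 0


def offset_by_ankle_midpoint(rec: Recording) -> Recording:
    """Subtract the time-averaged left/right ankle midpoint from every source.

    One constant 3-vector per recording is removed (per axis), so the sway
    of every marker — the ankles included — is preserved; only the
    coordinate origin moves to the stance point.
    """
    mid = 0.5 * (rec.source("ankle", "L") + rec.source("ankle", "R"))
    shift = mid.mean(axis=0)  # (3,) one offset per axis
    data = rec.data - np.tile(shift, 11)
    return rec.replace(data=data)


def compute_segment_lengths(rec: Recording) -> SegmentLengths:
    """Per-sample 3D distances of the three marker pairs, averaged over
    time and over the left/right sides."""
    pairs = (("shoulder", "hip"), ("hip", "knee"), ("knee", "ankle"))
    values = []
    for upper, lower in pairs:
        dists = []
        for side in ("L", "R"):
            diff = rec.source(upper, side) - rec.source(lower, side)
            dists.append(np.linalg.norm(diff, axis=1).mean())
        value = float(np.mean(dists))
        if value <= 0:
            raise ValueError(f"degenerate geometry: {upper}-{lower} length is 0")
        values.append(value)
    return SegmentLengths(*values)


def scale_by_height(rec: Recording, seg: SegmentLengths) -> Recording:
    """Divide every coordinate by l1+l2+l3; output is dimensionless."""
    if seg.total <= 0:
        raise ValueError("sum of segment lengths must be positive")
    return rec.replace(data=rec.data / seg.total, scaled=True)


def lowpass_filter(
    rec: Recording, cutoff: float = 12.0, order: int = 2
) -> Recording:
    """Zero-phase (forward-backward) Butterworth low-pass, per column.

    The double pass squares the magnitude response and cancels phase
    distortion; edge transients use filtfilt's default odd-extension
    padding.
    """
    nyquist = rec.rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyquist} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=rec.rate, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=0)
    return rec.replace(data=np.ascontiguousarray(data))


def slice_slots(rec: Recording, t: float, recording_index: int = 0) -> list[Slot]:
    """Cut a recording into consecutive non-overlapping t-second slots.

    The number of slots is floor(duration / t); a trailing remainder
    shorter than t is discarded.
    """
    if t <= 0:
        raise ValueError("slot length must be positive")
    samples_f = rec.rate * t
    n_per = int(round(samples_f))
    if abs(samples_f - n_per) > 1e-9:
        raise ValueError(f"rate*t = {samples_f} is not an integral sample count")
    if n_per > rec.n_samples:
        raise ValueError(
            f"slot length {t} s exceeds recording duration {rec.duration} s"
        )
    n_slots = rec.n_samples // n_per
    meta = rec.metadata()
    return [
        Slot(
            source_id=f"{rec.subject_id}/d{rec.days_after_onset}#{k}",
            data=rec.data[k * n_per : (k + 1) * n_per].copy(),
            rate=rec.rate,
            recording_index=recording_index,
            slot_index=k,
            metadata=meta,
        )
        for k in range(n_slots)
    ]


def preprocess_recording(
    rec: Recording,
    t: float,
    config: PreprocessConfig | None = None,
    recording_index: int = 0,
) -> list[Slot]:
    """Offset -> segment lengths -> scale -> filter -> slice, in order."""
    config = config or PreprocessConfig()
    seg = compute_segment_lengths(rec)
    rec = offset_by_ankle_midpoint(rec)
    rec = scale_by_height(rec, seg)
    rec = lowpass_filter(rec, config.filter_cutoff_hz, config.filter_order)
    return slice_slots(rec, t, recording_index=recording_index)


def preprocess_cohort(
    recordings: list[Recording],
    t: float,
    config: PreprocessConfig | None = None,
) -> list[Slot]:
    """Preprocess every recording independently and pool the slots.

    There is no cross-recording coupling, so the result is equivariant
    under permutation of the cohort.
    """
    slots: list[Slot] = []
    for i, rec in enumerate(recordings):
        slots.extend(preprocess_recording(rec, t, config, recording_index=i))
    return slots
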