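"""Marker-trajectory I/O and the canonical recording data model.

A quiet-standing recording tracks 11 signal sources — the whole-body centre
of mass (COM) plus ten reflective markers placed symmetrically on the
shoulders, hips, knees, ankles and toes — each with X (medial-lateral),
Y (anterior-posterior) and Z (vertical) displacement, for 33 kinematic
variables in total.  Files are plain CSV with a ``time_s`` column followed
by one column per variable; subject metadata travels in a YAML sidecar.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

AXES = ("X", "Y", "Z")

#: Signal sources in canonical order: COM first, then markers top-to-bottom,
#: left before right.  ``None`` side means the source has no side (COM).
SOURCES: tuple[tuple[str, str | None], ...] = (
    ("com", None),
    ("shoulder", "L"),
    ("shoulder", "R"),
    ("hip", "L"),
    ("hip", "R"),
    ("knee", "L"),
    ("knee", "R"),
    ("ankle", "L"),
    ("ankle", "R"),
    ("toe", "L"),
    ("toe", "R"),
)

DISEASES = ("CH", "CI", "other")
HEMIPLEGIA_SIDES = ("left", "right", "either", "unknown")


def _column_name(part: str, side: str | None, axis: str) -> str:
    return f"{part}_{side or ''}_{axis}"


@dataclass(frozen=True)
class MarkerSet:
    """The fixed set of 11 sources x 3 axes = 33 kinematic variables."""

    sources: tuple[tuple[str, str | None], ...] = SOURCES
    axes: tuple[str, ...] = AXES

    def __post_init__(self) -> None:
        names = [f"{p}_{s or ''}" for p, s in self.sources]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        sided = {}
        for part, side in self.sources:
            if side is not None:
                sided.setdefault(part, set()).add(side)
        for part, sides in sided.items():
            if sides != {"L", "R"}:
                raise ValueError(f"marker {part!r} must appear on both sides")
        if len(self.sources) * len(self.axes) != 33:
            raise ValueError("a MarkerSet must define exactly 33 variables")

    @property
    def column_names(self) -> list[str]:
        """Canonical 33 column names, e.g. ``com__X``, ``shoulder_L_Y``."""
        return [
            _column_name(p, s, ax) for p, s in self.sources for ax in self.axes
        ]

    def column_index(self, part: str, side: str | None, axis: str) -> int:
        name = _column_name(part, side, axis)
        try:
            return self.column_names.index(name)
        except ValueError:
            raise KeyError(f"unknown kinematic variable {name!r}") from None

    def source_columns(self, part: str, side: str | None) -> slice:
        """Column slice of the three axes of one source."""
        i = self.column_index(part, side, self.axes[0])
        return slice(i, i + len(self.axes))


MARKERS = MarkerSet()
COLUMNS = MARKERS.column_names


@dataclass
class Recording:
    """One 30-s multivariate trajectory plus subject metadata.

    ``data`` is a (samples, 33) float array in canonical column order,
    millimetres for raw marker data (dimensionless after height scaling).
    """

    subject_id: str
    data: np.ndarray
    disease: str = "other"
    age: float = float("nan")
    days_after_onset: int = -1
    hemiplegia: str = "unknown"
    rate: float = 60.0
    scaled: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 33:
            raise ValueError(
                f"recording data must have 33 columns, got shape {self.data.shape}"
            )
        if self.data.shape[0] == 0:
            raise ValueError("recording has no samples")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite values")
        if self.disease not in DISEASES:
            raise ValueError(f"disease must be one of {DISEASES}")
        if self.hemiplegia not in HEMIPLEGIA_SIDES:
            raise ValueError(f"hemiplegia must be one of {HEMIPLEGIA_SIDES}")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def source(self, part: str, side: str | None = None) -> np.ndarray:
        """(samples, 3) view of one source's X/Y/Z trajectory."""
        return self.data[:, MARKERS.source_columns(part, side)]

    def replace(self, **changes) -> "Recording":
        return dataclasses.replace(self, **changes)

    def metadata(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "disease": self.disease,
            "age": self.age,
            "days_after_onset": self.days_after_onset,
            "hemiplegia": self.hemiplegia,
            "rate": self.rate,
        }


def _interpolate_gaps(frame: pd.DataFrame, max_gap: int) -> pd.DataFrame:
    """Linearly fill NaN runs of length <= max_gap; longer runs stay NaN."""
    filled = frame.interpolate(method="linear", limit=max_gap, limit_area="inside")
    for col in frame.columns:
        isna = frame[col].isna().to_numpy()
        if not isna.any():
            continue
        # identify runs longer than max_gap and restore their NaNs
        edges = np.flatnonzero(np.diff(np.concatenate(([0], isna.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start > max_gap:
                filled.iloc[start:stop, filled.columns.get_loc(col)] = np.nan
    return filled


def read_recording(
    path: str | os.PathLike,
    metadata: dict | None = None,
    rate: float = 60.0,
    duration: float | None = None,
    interpolate_gaps: int = 0,
) -> Recording:
    """Read one trajectory CSV into a Recording.

    The file must carry a header naming all 33 canonical variable columns
    (any order; extra columns such as ``time_s`` are ignored).  ``metadata``
    supplies the subject fields; ``duration``, when given, is validated
    against the row count.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"column {missing[0]} absent from {path}")
    frame = frame[COLUMNS]
    bad = frame.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    nonnum = bad.isna() & ~frame.isna()
    if nonnum.to_numpy().any():
        row = int(np.argwhere(nonnum.to_numpy())[0, 0])
        raise ValueError(f"non-numeric cell at data row {row} in {path}")
    frame = bad
    if frame.isna().to_numpy().any():
        if interpolate_gaps > 0:
            frame = _interpolate_gaps(frame, interpolate_gaps)
        if frame.isna().to_numpy().any():
            row = int(np.argwhere(frame.isna().to_numpy())[0, 0])
            raise ValueError(
                f"missing sample at row {row} in {path} "
                f"(gap longer than {interpolate_gaps} samples)"
            )
    meta = dict(metadata or {})
    meta.setdefault("rate", rate)
    if duration is not None:
        expected = int(round(meta["rate"] * duration))
        if len(frame) != expected:
            raise ValueError(
                f"{path}: expected {expected} rows for {duration} s at "
                f"{meta['rate']} Hz, found {len(frame)}"
            )
    meta.setdefault("subject_id", os.path.splitext(os.path.basename(path))[0])
    return Recording(data=frame.to_numpy(dtype=float), **meta)


def write_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write a Recording as CSV: ``time_s`` then the 33 canonical columns.

    Values are written with full float precision, so write -> read
    round-trips bit-identically.
    """
    frame = pd.DataFrame(rec.data, columns=COLUMNS)
    frame.insert(0, "time_s", np.arange(rec.n_samples) / rec.rate)
    frame.to_csv(path, index=False)


def write_cohort(
    recordings: Sequence[Recording], directory: str | os.PathLike
) -> None:
    """Write recordings as ``rec_<i>.csv`` plus a ``metadata.yaml`` sidecar."""
    os.makedirs(directory, exist_ok=True)
    entries = []
    for i, rec in enumerate(recordings):
        fname = f"rec_{i:03d}.csv"
        write_recording(rec, os.path.join(directory, fname))
        entries.append({"file": fname, **rec.metadata()})
    with open(os.path.join(directory, "metadata.yaml"), "w") as fh:
        yaml.safe_dump({"recordings": entries}, fh, sort_keys=False)


def read_cohort(
    directory: str | os.PathLike, interpolate_gaps: int = 0
) -> list[Recording]:
    """Read a cohort directory written by :func:`write_cohort`."""
    with open(os.path.join(directory, "metadata.yaml")) as fh:
        sidecar = yaml.safe_load(fh)
    recordings = []
    for entry in sidecar["recordings"]:
        entry = dict(entry)
        fname = entry.pop("file")
        recordings.append(
            read_recording(
                os.path.join(directory, fname),
                metadata=entry,
                interpolate_gaps=interpolate_gaps,
            )
        )
    return recordings


def read_trc(
    path: str | os.PathLike,
    name_map: dict[str, tuple[str, str | None]],
    metadata: dict | None = None,
) -> Recording:
    """Read a TRC motion-capture file into the same Recording contract.

    TRC files name markers in their own convention; ``name_map`` maps each
    TRC marker name to a canonical ``(part, side)`` pair and must cover all
    11 sources (COM included — many pipelines export a computed COM marker).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise ValueError(f"{path} is not a TRC file")
    header = lines[2].split("\t")
    info = dict(zip(lines[1].split("\t"), header))
    rate = float(info.get("DataRate", 60.0))
    marker_names = [n for n in lines[3].split("\t")[2:] if n]
    data_rows = [ln.split("\t") for ln in lines[5:] if ln.strip()]
    raw = np.array(
        [[float(v) if v else np.nan for v in row[2:]] for row in data_rows]
    )
    if raw.shape[1] < 3 * len(marker_names):
        raise ValueError(f"{path}: truncated TRC data block")
    out = np.full((raw.shape[0], 33), np.nan)
    seen = set()
    for k, trc_name in enumerate(marker_names):
        if trc_name not in name_map:
            continue
        part, side = name_map[trc_name]
        out[:, MARKERS.source_columns(part, side)] = raw[:, 3 * k : 3 * k + 3]
        seen.add((part, side))
    missing = [s for s in SOURCES if s not in seen]
    if missing:
        raise ValueError(f"{path}: no TRC marker mapped to source {missing[0]}")
    meta = dict(metadata or {})
    meta.setdefault("rate", rate)
    meta.setdefault("subject_id", os.path.splitext(os.path.basename(path))[0])
    return Recording(data=out, **meta)
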