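"""Per-slot sway parameters: amplitude, standard deviation, peak frequency.

For each of the 33 kinematic variables of each data slot we compute the
peak-to-peak amplitude (max - min), the sample standard deviation, and the
sway frequency — the frequency of the largest magnitude bin of the FFT
spectrum after mean removal, DC excluded.  Frequency resolution is
rate/length (0.2 Hz for a 5-s slot at 60 Hz).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cluster import ClusterSolution
from .io import AXES, SOURCES
from .preprocess import Slot

PARAMETERS = ("amplitude", "sd", "frequency")


def amplitude(x: np.ndarray) -> float:
    """Peak-to-peak range of one variable within one slot."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return float(x.max() - x.min())


def sd(x: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    return float(x.std(ddof=1))


def sway_frequency(
    x: np.ndarray, rate: float, method: str = "peak"
) -> float:
    """Dominant sway frequency of one variable within one slot, in Hz.

    ``peak`` (default) returns the global maximum of the magnitude spectrum
    excluding DC — deterministic and parameter-free.  ``prominent`` returns
    the first local maximum whose prominence exceeds half the largest
    prominence, for spectra with a low-frequency shoulder.  A constant
    series has no sway frequency and returns NaN.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError("series too short for a frequency estimate")
    centered = x - x.mean()
    if np.allclose(centered, 0.0):
        return float("nan")
    mag = np.abs(np.fft.rfft(centered))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    if method == "peak":
        return float(freqs[1:][np.argmax(mag[1:])])
    if method == "prominent":
        from scipy.signal import find_peaks

        peaks, props = find_peaks(mag[1:], prominence=0.0)
        if peaks.size == 0:
            return float(freqs[1:][np.argmax(mag[1:])])
        keep = props["prominences"] >= 0.5 * props["prominences"].max()
        return float(freqs[1:][peaks[keep][0]])
    raise ValueError(f"unknown method {method!r}")


def variable_table() -> pd.DataFrame:
    """The 33 kinematic variables in canonical order (1-based index)."""
    rows = []
    i = 1
    for part, side in SOURCES:
        for axis in AXES:
            rows.append(
                {
                    "index": i,
                    "part": part,
                    "side": {"L": "Left", "R": "Right", None: "None"}[side],
                    "axis": axis,
                }
            )
            i += 1
    return pd.DataFrame(rows)


def featurize(
    slots: list[Slot],
    solution: ClusterSolution | None = None,
    frequency_method: str = "peak",
) -> pd.DataFrame:
    """Sway parameters for every (slot, variable) pair, in long form.

    Returns one row per slot and variable with columns ``slot_id``,
    ``cluster`` (1-based, 0 when no solution is given), the subject
    metadata, the variable descriptors and the three parameters.
    """
    if solution is not None and len(slots) != solution.n:
        raise ValueError("slot list and solution size differ")
    vt = variable_table()
    frames = []
    for s_idx, slot in enumerate(slots):
        block = vt.copy()
        block.insert(0, "slot_id", slot.source_id)
        block.insert(
            1,
            "cluster",
            int(solution.labels[s_idx]) + 1 if solution is not None else 0,
        )
        block["subject_id"] = slot.metadata.get("subject_id", "")
        block["disease"] = slot.metadata.get("disease", "other")
        block["age"] = slot.metadata.get("age", float("nan"))
        block["days_after_onset"] = slot.metadata.get("days_after_onset", -1)
        block["amplitude"] = [amplitude(slot.data[:, v]) for v in range(33)]
        block["sd"] = [sd(slot.data[:, v]) for v in range(33)]
        block["frequency"] = [
            sway_frequency(slot.data[:, v], slot.rate, method=frequency_method)
            for v in range(33)
        ]
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def to_tidy(features: pd.DataFrame) -> pd.DataFrame:
    """Melt the wide feature frame into (..., parameter, value) rows."""
    ids = [c for c in features.columns if c not in PARAMETERS]
    return features.melt(
        id_vars=ids, value_vars=list(PARAMETERS), var_name="parameter"
    )
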