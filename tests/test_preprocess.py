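import numpy as np
import pytest
from scipy import signal

from conftest import standing_recording
from swayclust.io import MARKERS
from swayclust.preprocess import (
    PreprocessConfig,
    SegmentLengths,
    compute_segment_lengths,
    lowpass_filter,
    offset_by_ankle_midpoint,
    preprocess_cohort,
    preprocess_recording,
    scale_by_height,
    slice_slots,
)


def _set_source(rec, part, side, xyz):
    rec.data[:, MARKERS.source_columns(part, side)] = xyz
    return rec


class TestOffset:
    def test_subtracts_mean_ankle_midpoint_per_axis(self, static_rec):
        rec = static_rec
        _set_source(rec, "ankle", "L", (0.0, 10.0, 40.0))
        _set_source(rec, "ankle", "R", (20.0, 30.0, 20.0))
        out = offset_by_ankle_midpoint(rec)
        # midpoint mean is (10, 20, 30): every column shifts by that vector
        expected = rec.data - np.tile([10.0, 20.0, 30.0], 11)
        assert np.allclose(out.data, expected)
        mid = 0.5 * (out.source("ankle", "L") + out.source("ankle", "R"))
        assert np.allclose(mid.mean(axis=0), 0.0, atol=1e-12)

    def test_idempotent_on_centered_recording(self, static_rec):
        once = offset_by_ankle_midpoint(static_rec)
        twice = offset_by_ankle_midpoint(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_constant_recording_stays_constant(self, static_rec):
        out = offset_by_ankle_midpoint(static_rec)
        assert np.allclose(out.data, out.data[0], atol=1e-12)


class TestSegmentLengths:
    def test_constant_pose_distances(self, static_rec):
        seg = compute_segment_lengths(static_rec)
        # fixture heights: shoulder 1400, hip 900, knee 500, ankle 80
        assert seg.l1 == pytest.approx(500.0)
        assert seg.l2 == pytest.approx(400.0)
        assert seg.l3 == pytest.approx(420.0)

    def test_sides_are_averaged(self, static_rec):
        rec = static_rec
        _set_source(rec, "hip", "L", (-120.0, 0.0, 900.0))
        _set_source(rec, "knee", "L", (-120.0, 0.0, 500.0))  # left l2 = 400
        _set_source(rec, "hip", "R", (120.0, 0.0, 1100.0))
        _set_source(rec, "knee", "R", (120.0, 0.0, 500.0))  # right l2 = 600
        assert compute_segment_lengths(rec).l2 == pytest.approx(500.0)

    def test_matches_per_sample_brute_force_on_jittered_pose(self):
        rec = standing_recording(n_samples=200, jitter=5.0, seed=7)
        seg = compute_segment_lengths(rec)
        for attr, (upper, lower) in zip(
            ("l1", "l2", "l3"), (("shoulder", "hip"), ("hip", "knee"), ("knee", "ankle"))
        ):
            per_sample = []
            for side in ("L", "R"):
                a = rec.source(upper, side)
                b = rec.source(lower, side)
                per_sample.append(
                    np.mean([np.sqrt(((a[i] - b[i]) ** 2).sum()) for i in range(200)])
                )
            assert getattr(seg, attr) == pytest.approx(np.mean(per_sample), rel=1e-12)

    def test_degenerate_geometry_rejected(self, static_rec):
        rec = static_rec
        _set_source(rec, "knee", "L", (-120.0, 0.0, 80.0))
        _set_source(rec, "knee", "R", (120.0, 0.0, 80.0))
        _set_source(rec, "ankle", "L", (-120.0, 0.0, 80.0))
        _set_source(rec, "ankle", "R", (120.0, 0.0, 80.0))
        with pytest.raises(ValueError):
            SegmentLengths(500.0, 400.0, 0.0)
        with pytest.raises(ValueError, match="knee-ankle"):
            compute_segment_lengths(rec)


class TestScale:
    def test_divides_by_summed_lengths(self, static_rec):
        rec = static_rec
        rec.data[:] = 6.0
        out = scale_by_height(rec, SegmentLengths(1.0, 1.0, 1.0))
        assert np.allclose(out.data, 2.0)
        assert out.scaled

    def test_geometrically_similar_recordings_collapse(self):
        rec = standing_recording(n_samples=100, jitter=3.0, seed=2)
        double = rec.replace(data=rec.data * 2.0)
        a = scale_by_height(rec, compute_segment_lengths(rec))
        b = scale_by_height(double, compute_segment_lengths(double))
        assert np.allclose(a.data, b.data, atol=1e-12)


class TestLowpass:
    def _sine_rec(self, freq, rate=60.0, n=600):
        t = np.arange(n) / rate
        rec = standing_recording(n_samples=n, rate=rate)
        rec.data = rec.data + np.sin(2 * np.pi * freq * t)[:, None]
        return rec

    def test_passband_sinusoid_preserved(self):
        rec = self._sine_rec(1.0)
        out = lowpass_filter(rec)
        x = rec.data[:, 0] - rec.data[:, 0].mean()
        y = out.data[:, 0] - out.data[:, 0].mean()
        assert np.sqrt((y**2).mean()) == pytest.approx(np.sqrt((x**2).mean()), rel=0.01)

    def test_stopband_sinusoid_attenuated_per_butterworth_magnitude(self):
        rec = self._sine_rec(25.0)
        out = lowpass_filter(rec)
        core = slice(100, 500)  # avoid filtfilt edge transients
        x = rec.data[core, 0] - rec.data[:, 0].mean()
        y = out.data[core, 0] - out.data[core, 0].mean()
        gain = np.sqrt((y**2).mean() / (x**2).mean())
        assert gain < 0.1
        # oracle: digital magnitude response at 25 Hz, squared for the
        # forward-backward double pass
        sos = signal.butter(2, 12.0, btype="low", fs=60.0, output="sos")
        _, h = signal.sosfreqz(sos, worN=[25.0], fs=60.0)
        assert gain == pytest.approx(np.abs(h[0]) ** 2, rel=0.05)

    def test_constant_signal_unchanged(self, static_rec):
        out = lowpass_filter(static_rec)
        assert np.allclose(out.data, static_rec.data, atol=1e-9)

    def test_cutoff_at_or_above_nyquist_rejected(self, static_rec):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(static_rec, cutoff=30.0)

    def test_zero_phase(self):
        rec = self._sine_rec(2.0)
        out = lowpass_filter(rec)
        x = rec.data[:, 0] - rec.data[:, 0].mean()
        y = out.data[:, 0] - out.data[:, 0].mean()
        lags = signal.correlation_lags(len(x), len(y))
        assert lags[np.argmax(signal.correlate(x, y))] == 0


class TestSlots:
    def test_thirty_seconds_at_t5_gives_six_slots(self):
        rec = standing_recording(n_samples=1800)
        slots = slice_slots(rec, 5.0)
        assert len(slots) == 6
        assert all(s.n_samples == 300 for s in slots)

    @pytest.mark.parametrize("t,expected", [(10.0, 3), (6.0, 5), (3.0, 10)])
    def test_slot_counts(self, t, expected):
        slots = slice_slots(standing_recording(n_samples=1800), t)
        assert len(slots) == expected

    def test_trailing_remainder_dropped(self):
        slots = slice_slots(standing_recording(n_samples=1850), 5.0)
        assert len(slots) == 6

    def test_slot_longer_than_recording_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            slice_slots(standing_recording(n_samples=120), 5.0)

    def test_non_integral_sample_count_rejected(self):
        rec = standing_recording(n_samples=1800, rate=59.7)
        with pytest.raises(ValueError, match="integral"):
            slice_slots(rec, 5.0)

    def test_concatenated_slots_reproduce_signal_prefix(self):
        rec = standing_recording(n_samples=1850, jitter=2.0, seed=5)
        slots = slice_slots(rec, 5.0)
        cat = np.vstack([s.data for s in slots])
        assert np.array_equal(cat, rec.data[: len(cat)])


class TestCohortPipeline:
    def test_full_cohort_slot_count(self, small_cohort):
        recs, _ = small_cohort  # 6 recordings x 15 s
        slots = preprocess_cohort(recs, 5.0)
        assert len(slots) == 18
        assert all(s.data.shape == (300, 33) for s in slots)
        assert all(s.metadata["subject_id"] in ("A1", "A2") for s in slots)

    def test_single_recording_t3(self):
        rec = standing_recording(n_samples=1800, jitter=1.0)
        assert len(preprocess_recording(rec, 3.0)) == 10

    def test_permutation_equivariance(self, small_cohort):
        recs, _ = small_cohort
        fwd = preprocess_cohort(recs, 5.0)
        rev = preprocess_cohort(recs[::-1], 5.0)
        fwd_by_id = {s.source_id: s.data for s in fwd}
        for s in rev:
            assert np.array_equal(s.data, fwd_by_id[s.source_id])

    def test_scaling_invariance_end_to_end(self, small_cohort):
        recs, _ = small_cohort
        rec = recs[0]
        double = rec.replace(data=rec.data * 2.0)
        a = preprocess_recording(rec, 5.0)
        b = preprocess_recording(double, 5.0)
        for sa, sb in zip(a, b):
            assert np.allclose(sa.data, sb.data, atol=1e-12)
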