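"""Orientation histograms, velocity conversion, ROI estimation, pairing."""

import math

import numpy as np
import pytest

import glidekymo as gk
from glidekymo.velocimetry import summarize_pairs

from conftest import render_trace_kymograph

PX, DT = 0.13, 0.1


def _line_pattern(angle_deg: float, n: int = 96, spacing: float = 12.0) -> np.ndarray:
    """Parallel lines at ``angle_deg`` from the x axis (image convention)."""
    yy, xx = np.mgrid[0:n, 0:n]
    th = math.radians(angle_deg)
    # coordinate across the lines
    u = -xx * math.sin(th) + yy * math.cos(th)
    return 1.0 + np.cos(2 * np.pi * u / spacing)


class TestOrientationHistogram:
    def test_vertical_lines_peak_at_90(self):
        hist = gk.orientation_histogram(_line_pattern(90.0))
        assert abs(hist.peak_deg - 90.0) <= 2.0
        assert hist.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rotation_shifts_peak(self):
        base = gk.orientation_histogram(_line_pattern(40.0))
        rot = gk.orientation_histogram(_line_pattern(60.0))
        shift = (rot.fit[0] - base.fit[0]) % 180.0
        shift = min(shift, 180.0 - shift)
        assert shift == pytest.approx(20.0, abs=2.0)

    def test_isotropic_noise_is_flat_with_poor_fit(self):
        rng = np.random.default_rng(8)
        hist = gk.orientation_histogram(rng.normal(size=(128, 128)))
        assert hist.weights.max() < 3.0 / hist.n_bins
        assert hist.fit[4] < 0.5

    def test_rejects_tiny_or_empty_rois(self):
        with pytest.raises(ValueError):
            gk.orientation_histogram(np.ones((8, 8)))
        with pytest.raises(ValueError, match="no signal"):
            gk.orientation_histogram(np.zeros((32, 32)))


class TestOrientationToVelocity:
    @pytest.mark.parametrize(
        "alpha,expected",
        [(90.0, 0.0), (45.0, 1.3), (135.0, -1.3)],
    )
    def test_reference_angles(self, alpha, expected):
        assert gk.orientation_to_velocity(alpha, PX, DT) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("alpha", [1.0, 179.5])
    def test_near_horizontal_is_unresolvable(self, alpha):
        with pytest.raises(ValueError, match="too fast"):
            gk.orientation_to_velocity(alpha, PX, DT)

    def test_agrees_with_segment_measurement(self):
        kymo = gk.Kymograph(np.zeros((64, 64)), PX, DT)
        rng = np.random.default_rng(1)
        for _ in range(25):
            p0 = rng.uniform(5, 25, 2)
            p1 = p0 + rng.uniform([-15, 5], [15, 30])
            seg = gk.measure_segment(kymo, tuple(p0), tuple(p1))
            alpha = math.degrees(math.atan2(p1[1] - p0[1], p1[0] - p0[0])) % 180.0
            v = gk.orientation_to_velocity(alpha, PX, DT)
            assert seg.myosin_speed_um_s == pytest.approx(v, rel=1e-9, abs=1e-12)


class TestMeasureSegment:
    def test_unit_diagonal(self):
        kymo = gk.Kymograph(np.zeros((32, 32)), PX, DT)
        m = gk.measure_segment(kymo, (0, 0), (10, 10))
        assert m.myosin_speed_um_s == pytest.approx(1.3)
        assert m.method == "manual-segment"

    def test_vertical_segment_is_stationary(self):
        kymo = gk.Kymograph(np.zeros((32, 32)), PX, DT)
        assert gk.measure_segment(kymo, (5, 0), (5, 20)).myosin_speed_um_s == 0.0

    def test_high_magnification_calibration(self):
        kymo = gk.Kymograph(np.zeros((32, 32)), 0.086, DT)
        m = gk.measure_segment(kymo, (0, 0), (10, 10))
        assert m.myosin_speed_um_s == pytest.approx(0.86)

    def test_equal_rows_rejected(self):
        kymo = gk.Kymograph(np.zeros((32, 32)), PX, DT)
        with pytest.raises(ValueError, match="infinite"):
            gk.measure_segment(kymo, (0, 5), (10, 5))


class TestBatchVelocity:
    @pytest.mark.parametrize("v", [0.5, 1.0, 2.0, 4.0, 8.0, 12.0])
    def test_slope_recovery_within_ten_percent(self, v):
        kymo = render_trace_kymograph(v, seed=17)
        roi = gk.RoiSpec((0.0, 9.9), (0, kymo.width - 1))
        m = gk.estimate_batch_velocity(kymo, roi)
        assert m.myosin_speed_um_s == pytest.approx(v, rel=0.10)

    def test_negative_velocity_recovers_sign(self):
        kymo = render_trace_kymograph(-6.0, seed=23)
        m = gk.estimate_batch_velocity(kymo, gk.RoiSpec((0.0, 9.9), (0, kymo.width - 1)))
        assert m.myosin_speed_um_s == pytest.approx(-6.0, rel=0.10)

    def test_heavy_clutter_falls_back_to_local_max(self):
        rng = np.random.default_rng(3)
        kymo = render_trace_kymograph(-4.0, seed=3, amplitude=6.0, noise_sd=0.5)
        kymo.data += rng.normal(0, 4.0, kymo.data.shape)  # clutter degrades the fit
        m = gk.estimate_batch_velocity(kymo, gk.RoiSpec((0.0, 9.9), (0, kymo.width - 1)))
        assert m.myosin_speed_um_s < 0.0

    def test_roi_duration_bounds_enforced(self):
        with pytest.raises(ValueError, match="5-15"):
            gk.RoiSpec((0.0, 4.0), (0, 100))
        with pytest.raises(ValueError, match="5-15"):
            gk.RoiSpec((0.0, 20.0), (0, 100))

    def test_static_only_roi_has_no_moving_traces(self):
        rng = np.random.default_rng(9)
        static = np.tile(
            10.0 * np.exp(-((np.arange(128) - 64.0) ** 2) / 50.0), (100, 1)
        ) + rng.normal(0, 0.5, (100, 128))
        kymo = gk.Kymograph(static, PX, DT)
        with pytest.raises(ValueError, match="no moving traces"):
            gk.estimate_batch_velocity(kymo, gk.RoiSpec((0.0, 9.9), (0, 127)))


class TestGlidingWindows:
    def _trace(self, speeds):
        arr = np.asarray(speeds, dtype=float)
        return gk.VelocityTrace(arr, arr, window=1, frame_interval=0.1)

    def test_sustained_gliding_is_one_full_window(self):
        trace = self._trace(np.full(251, 2.0))
        assert gk.select_gliding_windows(trace) == [(0.0, 25.0)]

    def test_slow_trace_yields_nothing(self):
        assert gk.select_gliding_windows(self._trace(np.full(100, 0.3))) == []

    def test_matches_run_length_oracle(self):
        rng = np.random.default_rng(12)
        speeds = np.where(rng.random(400) < 0.5, 2.0, 0.1)
        # widen runs so some exceed 5 s
        speeds = np.convolve(speeds, np.ones(40) / 40, mode="same")
        trace = self._trace(speeds)
        got = gk.select_gliding_windows(trace, v_min=0.5, t_min=5.0)
        above = speeds > 0.5
        oracle = []
        i = 0
        while i < len(above):
            if above[i]:
                j = i
                while j + 1 < len(above) and above[j + 1]:
                    j += 1
                if (j - i) * 0.1 >= 5.0:
                    oracle.append((i * 0.1, j * 0.1))
                i = j + 1
            else:
                i += 1
        assert got == oracle
        assert len(got) > 0


class TestPairing:
    def test_ratio_and_summary(self):
        trace = gk.VelocityTrace(
            np.full(301, 3.0), np.full(301, 3.0), window=1, frame_interval=0.1
        )
        roi = gk.RoiSpec((5.0, 15.0), (0, 50))
        ms = [gk.VelocityMeasurement(roi, "gaussian-peak", -6.0)]
        pairs = gk.pair_with_cell_velocity(ms, trace)
        assert pairs.loc[0, "ratio_myosin_over_cell"] == pytest.approx(2.0)
        assert pairs.loc[0, "cell_speed_um_s"] == pytest.approx(3.0)
        summary = summarize_pairs(pairs)
        assert summary.loc[0, "n"] == 1
        assert summary.loc[0, "myosin_mean"] == pytest.approx(6.0)

    def test_window_outside_trace_rejected(self):
        trace = gk.VelocityTrace(np.ones(50), np.ones(50), window=1, frame_interval=0.1)
        roi = gk.RoiSpec((1.0, 8.0), (0, 10))
        with pytest.raises(ValueError):
            gk.pair_with_cell_velocity([gk.VelocityMeasurement(roi, "local-max", 1.0)], trace)
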