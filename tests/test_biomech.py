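"""Centerline extraction, depth tracking, displacement, force and stiffness."""

import numpy as np
import pytest

from octstiff.biomech import (AirJetProtocol, DepthTrace, TrackingError,
                              UndefinedStiffnessError, composite_profile,
                              displacement, extract_centerline, force,
                              quantify_series, stiffness, track_depth)
from octstiff.preprocess import BScanSeries


class TestExtractCenterline:
    def test_odd_width_takes_middle_column(self):
        frame = np.tile(np.arange(7), (5, 1))
        np.testing.assert_array_equal(extract_centerline(frame), [3] * 5)

    def test_even_width_takes_left_of_center(self):
        frame = np.tile(np.arange(6), (4, 1))
        np.testing.assert_array_equal(extract_centerline(frame), [2] * 4)

    def test_997_wide_frame_uses_column_498(self):
        frame = np.zeros((4, 997))
        frame[:, 498] = 7.0
        np.testing.assert_array_equal(extract_centerline(frame), [7.0] * 4)

    def test_single_column_frame_is_identity(self):
        col = np.arange(5.0)[:, None]
        np.testing.assert_array_equal(extract_centerline(col), np.arange(5.0))

    def test_empty_frame_raises(self):
        with pytest.raises(ValueError):
            extract_centerline(np.empty((0, 0)))


class TestCompositeProfile:
    def _series(self, frames):
        return BScanSeries(frames=np.asarray(frames, dtype=np.float32), fps=10,
                           axial_pitch_um=7.5, lateral_pitch_um=10)

    def test_identical_frames_give_single_centerline(self, rng):
        f = rng.random((8, 9), dtype=np.float32)
        s = self._series([f, f, f])
        np.testing.assert_allclose(composite_profile(s), extract_centerline(f))

    def test_linearity(self, rng):
        p = rng.random((8, 9), dtype=np.float32)
        c = 0.8
        s = self._series([p, -p + c])
        np.testing.assert_allclose(composite_profile(s),
                                   np.full(8, c / 2), atol=1e-6)

    def test_single_frame_window(self, rng):
        frames = rng.random((3, 8, 9), dtype=np.float32)
        s = self._series(frames)
        np.testing.assert_allclose(composite_profile(s, [1]),
                                   extract_centerline(frames[1]))

    def test_empty_window_raises(self, rng):
        s = self._series(rng.random((3, 8, 9), dtype=np.float32))
        with pytest.raises(ValueError):
            composite_profile(s, [])


class TestTrackDepth:
    def _series_and_masks(self, n=5, h=40, w=40, band=(10, 14)):
        frames = np.zeros((n, h, w), dtype=np.float32)
        masks = np.zeros((n, h, w), dtype=np.uint8)
        masks[:, band[0]:band[1], :] = 1
        series = BScanSeries(frames=frames, fps=10, axial_pitch_um=10,
                             lateral_pitch_um=10)
        return series, masks

    def test_constant_masks_give_constant_trace(self):
        series, masks = self._series_and_masks()
        trace = track_depth(series, masks)
        assert np.ptp(trace.depth_mm) == 0
        # centroid of rows 10..13 is 11.5 -> (11.5 + 0.5) * 10 um
        assert trace.depth_mm[0] == pytest.approx(0.12)

    def test_top_boundary_landmark(self):
        series, masks = self._series_and_masks()
        trace = track_depth(series, masks, landmark="top_boundary")
        assert trace.depth_mm[0] == pytest.approx((10 + 0.5) * 10 / 1000)

    def test_empty_central_band_names_the_frame(self):
        series, masks = self._series_and_masks()
        masks[3] = 0
        with pytest.raises(TrackingError, match="frame 3"):
            track_depth(series, masks)

    def test_phantom_truth_masks_track_analytic_boundary(self, small_series):
        series, truth = small_series
        trace = track_depth(series, truth.masks, landmark="top_boundary")
        pitch_mm = series.axial_pitch_um / 1000.0
        np.testing.assert_allclose(trace.depth_mm, truth.boundary_depth_mm,
                                   atol=pitch_mm)


class TestDisplacement:
    PROTO = AirJetProtocol()

    def _trace(self, depths, fps=10.0):
        t = np.arange(len(depths)) / fps
        return DepthTrace(t_s=t, depth_mm=np.asarray(depths, dtype=float))

    def test_constant_trace_has_zero_displacement(self):
        base, peak, dd = displacement(self._trace([0.4] * 150), self.PROTO)
        assert base == pytest.approx(0.4)
        assert peak == pytest.approx(0.4)
        assert dd == pytest.approx(0.0, abs=1e-12)

    def test_step_plateau_recovered(self):
        d = np.array([0.4] * 50 + [0.9] * 50 + [0.4] * 50)
        base, peak, dd = displacement(self._trace(d), self.PROTO)
        assert dd == pytest.approx(0.5)

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            displacement(self._trace([0.4] * 30), self.PROTO)

    def test_noisy_plateau_bias_is_bounded(self):
        # max-over-window on a noisy plateau inflates delta_d by the expected
        # maximum of ~50 gaussians: ~2.2 sd. With sd = 1 px and a 50 px
        # plateau the estimate must stay within 3 px of truth.
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(1000):
            d = np.array([0.0] * 50 + [50.0] * 50 + [0.0] * 50)
            d = d + rng.normal(0, 1.0, d.size)
            _, _, dd = displacement(self._trace(d), self.PROTO)
            errs.append(dd - 50.0)
        assert abs(np.median(errs)) < 3.0
        assert np.mean(np.abs(errs)) < 3.0


class TestForceAndStiffness:
    def test_force_arithmetic_100kpa_2mm(self):
        proto = AirJetProtocol(pressure_pa=100_000.0, nozzle_diameter_mm=2.0)
        assert force(proto) == pytest.approx(0.31416, abs=5e-5)

    def test_zero_pressure_zero_force(self):
        assert force(AirJetProtocol(pressure_pa=0.0)) == 0.0

    def test_force_linear_in_pressure(self):
        f1 = force(AirJetProtocol(pressure_pa=50_000.0))
        f2 = force(AirJetProtocol(pressure_pa=100_000.0))
        assert f2 == pytest.approx(2 * f1)

    @pytest.mark.parametrize("f,dd,k", [(0.5, 0.5, 1.0), (1.0, 0.25, 4.0)])
    def test_stiffness_ratio(self, f, dd, k):
        assert stiffness(f, dd).k_n_per_mm == pytest.approx(k)

    def test_zero_displacement_is_undefined_not_infinite(self):
        with pytest.raises(UndefinedStiffnessError):
            stiffness(0.5, 0.0)


class TestEndToEndRecovery:
    def test_truth_mask_recovery_within_quantization(self, small_series,
                                                     sweep_protocol):
        series, truth = small_series
        res = quantify_series(series, truth.masks, sweep_protocol)
        assert res.delta_d_mm == pytest.approx(truth.delta_d_true_mm,
                                               abs=series.axial_pitch_um / 1000)
        assert res.k_n_per_mm == pytest.approx(truth.k_true_n_per_mm, rel=0.05)

    def test_pressure_scale_equivariance(self, sweep_protocol):
        # doubling pressure doubles F and delta_d; K is nearly unchanged
        from conftest import small_phantom_config
        from octstiff.phantom import generate_series

        double = AirJetProtocol(pressure_pa=2 * sweep_protocol.pressure_pa)
        cfg = small_phantom_config(k_true=2.0, seed=3)
        s1, t1 = generate_series(cfg, sweep_protocol)
        s2, t2 = generate_series(cfg, double)
        assert force(double) == pytest.approx(2 * force(sweep_protocol))
        r1 = quantify_series(s1, t1.masks, sweep_protocol)
        r2 = quantify_series(s2, t2.masks, double)
        assert r2.delta_d_mm == pytest.approx(2 * r1.delta_d_mm, rel=0.05)
        assert r2.k_n_per_mm == pytest.approx(r1.k_n_per_mm, rel=0.05)
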