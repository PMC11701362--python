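"""Trace extraction, smoothing, gradients, endpoints, induction, AUC."""

import numpy as np
import pytest

import wellkinetics as wk
from wellkinetics.colour import srgb_to_lab_array, srgb_to_hsv_array

from conftest import make_plate_spec


def trace_from_delta_e(times, delta_e, label="A1"):
    """Build a trace whose ΔE profile is given directly (colour channels inert)."""
    n = len(times)
    return wk.ColourTrace(
        label=label,
        times=np.asarray(times, float),
        rgb=np.full((n, 3), 128.0),
        lab=np.full((n, 3), 50.0),
        hsv=np.zeros((n, 3)),
        delta_e=np.asarray(delta_e, float),
    )


def trace_from_rgb(times, rgb, label="A1", reference_index=0):
    rgb = np.asarray(rgb, float)
    lab = srgb_to_lab_array(rgb)
    return wk.ColourTrace(
        label=label,
        times=np.asarray(times, float),
        rgb=rgb,
        lab=lab,
        hsv=srgb_to_hsv_array(rgb),
        delta_e=np.linalg.norm(lab - lab[reference_index], axis=1),
    )


class TestExtractTraces:
    def test_constant_video_has_zero_delta_e(self, small_plate_masks, small_plate_spec):
        img = np.full((small_plate_spec.height, small_plate_spec.width, 3), 90, dtype=np.uint8)
        frames = [wk.FrameRecord(i, i / 5.0, img) for i in range(8)]
        traces = wk.extract_traces(frames, small_plate_masks)
        for t in traces:
            assert np.all(t.delta_e == 0.0)

    def test_two_wells_report_their_own_colours(self, small_plate_masks, small_plate_spec):
        img = np.zeros((small_plate_spec.height, small_plate_spec.width, 3), dtype=np.uint8)
        img[:] = (10, 20, 30)
        a1, a2 = small_plate_masks
        img[a1.rows, a1.cols] = (200, 50, 60)
        img[a2.rows, a2.cols] = (15, 220, 90)
        frames = [wk.FrameRecord(i, float(i), img) for i in range(3)]
        t1, t2 = wk.extract_traces(frames, small_plate_masks)
        assert np.all(t1.rgb == (200, 50, 60))
        assert np.all(t2.rgb == (15, 220, 90))

    def test_step_from_white_to_black_well(self, small_plate_masks, small_plate_spec):
        h, w = small_plate_spec.height, small_plate_spec.width
        white = np.full((h, w, 3), 255, dtype=np.uint8)
        black = np.zeros((h, w, 3), dtype=np.uint8)
        k = 4
        frames = [
            wk.FrameRecord(i, float(i), white if i < k else black) for i in range(8)
        ]
        trace = wk.extract_traces(frames, small_plate_masks)[0]
        assert np.all(trace.delta_e[:k] == 0.0)
        assert trace.delta_e[k:] == pytest.approx(100.0)

    def test_delta_e_invariant_to_pixel_order(self, small_plate_frames, small_plate_masks):
        m = small_plate_masks[0]
        perm = np.random.default_rng(0).permutation(len(m))
        shuffled = wk.ROIMask(m.label, m.centre, m.radius, m.pixels[perm])
        a = wk.extract_traces(small_plate_frames, [m])[0]
        b = wk.extract_traces(small_plate_frames, [shuffled])[0]
        np.testing.assert_array_equal(a.delta_e, b.delta_e)

    def test_mask_outside_frame_rejected(self, small_plate_frames):
        bad = wk.ROIMask("Z9", (500, 500), 2, np.array([[500, 500]]))
        with pytest.raises(ValueError, match="Z9"):
            wk.extract_traces(small_plate_frames, [bad])

    def test_unknown_channel_name_rejected(self, small_plate_traces):
        with pytest.raises(KeyError):
            small_plate_traces[0].channel("X")


class TestSmooth:
    def test_constant_unchanged(self):
        assert wk.smooth(np.full(10, 3.0), 5) == pytest.approx([3.0] * 10)

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=20)
        np.testing.assert_array_equal(wk.smooth(x, 1), x)

    def test_affine_series_unchanged(self):
        x = 2.0 * np.arange(30) + 1.0
        np.testing.assert_allclose(wk.smooth(x, 7), x)

    @pytest.mark.parametrize("window", [0, 4, 31])
    def test_bad_windows_rejected(self, window):
        with pytest.raises(ValueError):
            wk.smooth(np.zeros(21), window)


class TestGradient:
    def test_linear_profile_constant_gradient(self):
        t = np.arange(11, dtype=float)
        assert wk.gradient(2.0 * t, t) == pytest.approx([2.0] * 11)

    def test_constant_profile_zero_gradient(self):
        t = np.arange(5, dtype=float)
        assert wk.gradient(np.full(5, 7.0), t) == pytest.approx([0.0] * 5)

    def test_quadratic_exact_in_interior(self):
        t = np.linspace(0, 10, 11)
        g = wk.gradient(t**2, t)
        assert g[1:-1] == pytest.approx(2 * t[1:-1])  # central diff exact for quadratics

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            wk.gradient(np.array([1.0]), np.array([0.0]))


class TestDetectEndpoint:
    CFG = wk.EndpointConfig(gradient_threshold=0.05, smoothing_window=5, persistence_s=5.0)

    def test_constant_trace_never_activates(self):
        t = np.arange(0, 60, 0.5)
        trace = trace_from_delta_e(t, np.zeros_like(t))
        assert wk.detect_endpoint(trace, self.CFG) is None

    def test_monotone_ramp_never_settles(self):
        t = np.arange(0, 60, 0.5)
        trace = trace_from_delta_e(t, 2.0 * t)
        assert wk.detect_endpoint(trace, self.CFG) is None

    def test_persistence_rejects_momentary_dip(self):
        # gradient dips below threshold for 2 s mid-rise, then resumes
        t = np.arange(0, 100, 0.5)
        g = np.where((t > 40) & (t < 42), 0.0, 1.0)
        g[t > 80] = 0.0  # true plateau at 80 s
        trace = trace_from_delta_e(t, np.cumsum(g) * 0.5)
        ep = wk.detect_endpoint(trace, wk.EndpointConfig(0.05, 5, 5.0))
        assert ep == pytest.approx(80.0, abs=2.0)

    def test_logistic_profile_matches_analytic_crossing(self):
        # ΔE(t) = A / (1 + exp(-s(t - t0))): derivative falls below θ at
        # a closed-form time; detector must land within 2 samples of it.
        A, s, t0, theta = 40.0, 0.2, 50.0, 0.05
        t = np.arange(0, 120, 0.2)
        de = A / (1.0 + np.exp(-s * (t - t0)))
        trace = trace_from_delta_e(t, de)
        # solve A*s*sig*(1-sig) = theta for the late crossing
        q = theta / (A * s)
        sig = (1 + np.sqrt(1 - 4 * q)) / 2
        t_star = t0 - np.log(1 / sig - 1) / s
        cfg = wk.EndpointConfig(theta, 5, 10.0)
        assert wk.detect_endpoint(trace, cfg) == pytest.approx(t_star, abs=2 * 0.2)

    def test_trace_shorter_than_window_rejected(self):
        trace = trace_from_delta_e(np.arange(3.0), np.zeros(3))
        with pytest.raises(ValueError):
            wk.detect_endpoint(trace, wk.EndpointConfig(0.05, 25, 1.0))


class TestInductionTime:
    def test_logistic_peak_rate_at_midpoint(self):
        t = np.arange(0, 100, 0.2)
        de = 30.0 / (1.0 + np.exp(-0.3 * (t - 42.0)))
        trace = trace_from_delta_e(t, de)
        assert wk.induction_time(trace, "deltaE", 5) == pytest.approx(42.0, abs=0.4)

    def test_constant_series_is_none(self):
        t = np.arange(0, 30, 0.5)
        trace = trace_from_delta_e(t, np.full_like(t, 5.0))
        assert wk.induction_time(trace, "deltaE", 5) is None

    def test_step_located_at_step_time(self):
        t = np.arange(0, 30, 0.5)
        trace = trace_from_delta_e(t, np.where(t < 12, 0.0, 20.0))
        assert wk.induction_time(trace, "deltaE", 5) == pytest.approx(12.0, abs=1.0)

    def test_threshold_method_first_crossing(self):
        t = np.arange(0, 100, 0.5)
        de = 30.0 / (1.0 + np.exp(-0.3 * (t - 42.0)))
        early = wk.induction_time(trace_from_delta_e(t, de), "deltaE", 5,
                                  method="threshold", threshold=0.05)
        peak = wk.induction_time(trace_from_delta_e(t, de), "deltaE", 5)
        assert early < peak

    def test_unknown_channel_rejected(self, small_plate_traces):
        with pytest.raises(KeyError):
            wk.induction_time(small_plate_traces[0], "Q")


class TestAuc:
    def test_zero_profile(self):
        t = np.linspace(0, 10, 21)
        assert wk.auc(trace_from_delta_e(t, np.zeros_like(t))) == 0.0

    def test_triangle(self):
        t = np.linspace(0, 10, 101)
        assert wk.auc(trace_from_delta_e(t, t)) == pytest.approx(50.0)

    def test_rectangle(self):
        t = np.linspace(0, 20, 41)
        assert wk.auc(trace_from_delta_e(t, np.full_like(t, 5.0))) == pytest.approx(100.0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            wk.auc(trace_from_delta_e([0.0], [0.0]))


class TestSummarise:
    def test_summary_fields_consistent(self, small_plate_traces):
        cfg = wk.EndpointConfig(0.05, 5, 5.0)
        summaries = wk.summarise(small_plate_traces, cfg)
        assert [s.label for s in summaries] == [t.label for t in small_plate_traces]
        for s, t in zip(summaries, small_plate_traces):
            assert s.complete == (s.endpoint_s is not None)
            assert s.auc == pytest.approx(wk.auc(t))
            assert s.auc >= 0

    def test_frame_serialises_none_as_empty(self, small_plate_traces, tmp_path):
        cfg = wk.EndpointConfig(0.05, 5, 5.0)
        df = wk.kinetics.summaries_to_frame(wk.summarise(small_plate_traces, cfg))
        path = tmp_path / "summary.csv"
        df.to_csv(path, index=False)
        lines = path.read_text().splitlines()
        # the constant well never activates: empty endpoint cell, complete False
        row = [l for l in lines if l.startswith("A2")][0]
        assert row.split(",")[1] == ""


class TestEndpointRateOrdering:
    def test_faster_rates_give_earlier_endpoints(self):
        # parallel dye-decay wells: endpoint order must invert rate order
        rates = [0.05, 0.1, 0.2, 0.4]
        spec = make_plate_spec(
            n_cols=4, models=("exponential_decay",), fps=5.0, duration_s=120.0,
            quantise="none",
        )
        wells = {
            lab: wk.WellKineticSpec(
                "exponential_decay", (110, 45, 150), (215, 215, 210), rate=r
            )
            for lab, r in zip(spec.grid.labels(), rates)
        }
        spec = wk.PlateVideoSpec(
            grid=spec.grid, wells=wells, height=spec.height, width=spec.width,
            fps=spec.fps, duration_s=spec.duration_s, quantise="none",
        )
        masks = wk.build_masks(spec.grid, spec.height, spec.width)
        traces = wk.extract_traces(wk.iter_render(spec), masks)
        cfg = wk.EndpointConfig(0.05, 5, 10.0)
        endpoints = [wk.detect_endpoint(t, cfg) for t in traces]
        assert all(e is not None for e in endpoints)
        assert endpoints == sorted(endpoints, reverse=True)

    def test_endpoint_stable_under_doubled_sampling_rate(self):
        wells = {
            "A1": wk.WellKineticSpec(
                "exponential_decay", (110, 45, 150), (215, 215, 210), rate=0.15
            )
        }
        grid = wk.GridSpec(1, 1, (14, 14), 1, 1, 20)
        endpoints = {}
        for fps, window in ((5.0, 5), (10.0, 9)):
            spec = wk.PlateVideoSpec(
                grid=grid, wells=wells, height=28, width=28, fps=fps,
                duration_s=120.0, quantise="none",
            )
            masks = wk.build_masks(grid, 28, 28)
            trace = wk.extract_traces(wk.iter_render(spec), masks)[0]
            cfg = wk.EndpointConfig(0.05, window, 10.0)
            endpoints[fps] = wk.detect_endpoint(trace, cfg)
        assert abs(endpoints[10.0] - endpoints[5.0]) < 1 / 5.0  # one coarse interval
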