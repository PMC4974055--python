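"""ΔF/F₀ normalization, event detection, nerve-trace processing, ROI extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import respnet
from respnet.synth import _calcium_kernel
from respnet.traces import TraceSet, NormalizedTraceSet


def _ts(values, dt=1.0):
    return TraceSet(values=np.atleast_2d(np.asarray(values, float)),
                    frame_interval=dt)


class TestNormalizeDff:
    def test_constant_trace_maps_to_zero(self):
        norm = respnet.normalize_dff(_ts(np.full(100, 5.0)))
        np.testing.assert_allclose(norm.values, 0.0)

    def test_multiplicative_gain_invariance(self):
        rng = np.random.default_rng(0)
        x = 100 + rng.normal(0, 3, size=(1, 200))
        a = respnet.normalize_dff(_ts(x))
        b = respnet.normalize_dff(_ts(3 * x))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_additive_offset_changes_output(self):
        rng = np.random.default_rng(1)
        x = 100 + rng.normal(0, 3, size=(1, 200))
        a = respnet.normalize_dff(_ts(x))
        b = respnet.normalize_dff(_ts(x + 50))
        assert not np.allclose(a.values, b.values)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(gain=st.floats(0.1, 50), seed=st.integers(0, 10**6))
    def test_gain_invariance_property(self, gain, seed):
        rng = np.random.default_rng(seed)
        x = 50 + rng.random((2, 120)) * 10
        a = respnet.normalize_dff(_ts(x))
        b = respnet.normalize_dff(_ts(gain * x))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_rectangular_pulse_matches_window_mean_oracle(self):
        # baseline c with one pulse of height 2c; check mid-pulse frame against
        # a brute-force mean over the +/-30 s window
        c, dt = 10.0, 1.0
        x = np.full(200, c)
        x[100:105] = 2 * c
        norm = respnet.normalize_dff(_ts(x, dt), window_half_width=30.0)
        t = 102
        window = x[max(0, t - 30):t + 31]
        f0 = window.mean()
        assert norm.values[0, t] == pytest.approx((2 * c - f0) / f0, abs=1e-12)

    def test_edge_truncation_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        x = 80 + rng.normal(0, 5, size=150)
        norm = respnet.normalize_dff(_ts(x, dt=2.0), window_half_width=30.0)
        for t in (0, 1, 149, 75):
            lo, hi = max(0, t - 15), min(149, t + 15)
            f0 = x[lo:hi + 1].mean()
            assert norm.values[0, t] == pytest.approx((x[t] - f0) / f0, abs=1e-12)

    def test_nonpositive_baseline_flags_cell(self):
        x = np.vstack([np.full(100, 5.0), np.full(100, -1.0)])
        with pytest.warns(UserWarning, match="non-positive baseline"):
            norm = respnet.normalize_dff(_ts(x))
        assert list(norm.invalid) == [False, True]
        assert np.all(np.isnan(norm.values[1]))


def _kernel_train(n_events, peak, dt=0.5, spacing=30.0, rise=0.3, decay=2.0):
    dur = spacing * (n_events + 1)
    t = np.arange(int(dur / dt)) * dt
    x = np.zeros_like(t)
    times = spacing * (np.arange(n_events) + 1)
    for te in times:
        x += peak * _calcium_kernel(t - te, rise, decay)
    return NormalizedTraceSet(values=x[None, :], frame_interval=dt,
                              roi_ids=["c0"]), times


class TestDetectEvents:
    def test_silent_trace_has_no_events(self):
        norm = NormalizedTraceSet(values=np.zeros((1, 200)), frame_interval=0.5,
                                  roi_ids=["c0"])
        ev = respnet.detect_events(norm)
        assert len(ev.times[0]) == 0
        assert not ev.active[0]

    def test_noiseless_train_at_half_amplitude_counted_exactly(self):
        norm, truth = _kernel_train(10, peak=0.5)
        ev = respnet.detect_events(norm)
        assert len(ev.times[0]) == 10
        # detected peak within one frame of the kernel maximum
        t_peak = 0.3 * 2.0 / (2.0 - 0.3) * np.log(2.0 / 0.3)
        np.testing.assert_allclose(ev.times[0], truth + t_peak, atol=1.0)

    def test_subthreshold_train_yields_no_events(self):
        norm, _ = _kernel_train(10, peak=0.1)
        ev = respnet.detect_events(norm)
        assert len(ev.times[0]) == 0

    def test_event_count_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(7)
        norm, _ = _kernel_train(10, peak=0.5)
        norm.values += rng.normal(0, 0.05, norm.values.shape)
        counts = [len(respnet.detect_events(norm, threshold_frac=f).times[0])
                  for f in (0.1, 0.2, 0.3, 0.5, 0.8)]
        assert counts == sorted(counts, reverse=True)

    def test_noiseless_pipeline_recovers_truth_counts(self):
        """Full normalize+detect chain on a clean simulation matches truth."""
        g = respnet.generate_network(
            respnet.NetworkSpec(n_cells=10, k=2, rewire_p=0.1, seed=2))
        dyn = respnet.DynamicsSpec(noise_sd=0.0, drift_amplitude=0.0,
                                   duration=400.0)
        rec = respnet.simulate_recording(g, dyn, seed=9)
        ev = respnet.detect_events(respnet.normalize_dff(rec.traces))
        for i in range(10):
            assert len(ev.times[i]) == len(rec.truth_events[i])


class TestRectifySmooth:
    def test_zero_in_zero_out(self):
        out = respnet.rectify_smooth(np.zeros(500), frame_interval=0.1)
        np.testing.assert_allclose(out, 0.0)

    def test_dc_passes_lowpass_and_rectifies(self):
        out = respnet.rectify_smooth(np.full(2000, 3.0), frame_interval=0.1,
                                     mode="lowpass")
        np.testing.assert_allclose(out, 3.0, rtol=1e-6)

    def test_rectified_sine_mean_is_two_over_pi(self):
        dt = 0.01
        t = np.arange(0, 60, dt)
        x = np.sin(2 * np.pi * 5 * t)
        out = respnet.rectify_smooth(x, frame_interval=dt, mode="highpass")
        assert out.mean() == pytest.approx(2 / np.pi, rel=0.05)

    def test_smooth_window_below_frame_interval_rejected(self):
        with pytest.raises(ValueError):
            respnet.rectify_smooth(np.zeros(100), frame_interval=1.0,
                                   smooth_window=0.5)


class TestRoiExtraction:
    def test_constant_stack_has_no_rois(self):
        with pytest.warns(UserWarning):
            ts = respnet.extract_rois_and_traces(np.full((5, 32, 32), 7.0))
        assert ts.n_cells == 0

    def test_rendered_cells_recovered_with_accurate_centroids(self):
        import networkx as nx
        from respnet import synth

        dyn = respnet.DynamicsSpec(noise_sd=0.0, drift_amplitude=0.0,
                                   pacemaker_fraction=1.0, duration=300.0)
        rec = respnet.simulate_recording(nx.empty_graph(5), dyn, seed=3)
        pos = np.array([[10., 10.], [10., 40.], [30., 25.], [50., 10.], [50., 40.]])
        stack = respnet.render_stack(rec, pos, radii=2.0, shape=(64, 56))
        ts = respnet.extract_rois_and_traces(stack, min_area=4, max_area=500)
        assert ts.n_cells == 5
        # match recovered ROIs to the rendered geometry
        order = [int(np.argmin(np.linalg.norm(ts.roi_centroids - p, axis=1)))
                 for p in pos]
        assert sorted(order) == list(range(5))
        for truth_i, roi_i in enumerate(order):
            assert np.linalg.norm(ts.roi_centroids[roi_i] - pos[truth_i]) < 2.0
            r = np.corrcoef(ts.values[roi_i], rec.traces.values[truth_i])[0, 1]
            assert r > 0.99

    def test_label_image_import_path(self):
        stack = np.zeros((6, 16, 16))
        stack[:, 2:5, 2:5] = np.arange(6)[:, None, None]
        labels = np.zeros((16, 16), dtype=int)
        labels[2:5, 2:5] = 1
        ts = respnet.extract_traces_from_labels(stack, labels)
        assert ts.n_cells == 1
        np.testing.assert_allclose(ts.values[0], np.arange(6))
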