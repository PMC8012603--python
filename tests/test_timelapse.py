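"""ROI traces, baseline correction, response metrics, and clustering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcfret import (
    CellTrace,
    PcfretError,
    cluster_responses,
    extract_roi_traces,
    fit_baseline,
    max_response,
    onset_time,
    percent_increase,
    planted_response_classes,
    synthetic_response_trace,
)
from pcfret.timelapse import ONSET_FRACTION


def make_stack(t=6, h=16, w=16, value=50.0, bg=10.0):
    stack = np.full((t, h, w), bg)
    rois = np.zeros((h, w), dtype=int)
    rois[4:8, 4:8] = 1
    stack[:, 4:8, 4:8] = value
    background = np.zeros((h, w), dtype=bool)
    background[0:2, :] = True
    return stack, rois, background


class TestRoiExtraction:
    def test_uniform_image_minus_background(self):
        stack, rois, bg = make_stack(value=50.0, bg=10.0)
        traces = extract_roi_traces(stack, rois, bg)
        assert np.allclose(traces[1].values, 40.0)

    def test_background_equals_signal_gives_zero(self):
        stack, rois, bg = make_stack(value=10.0, bg=10.0)
        traces = extract_roi_traces(stack, rois, bg)
        assert np.allclose(traces[1].values, 0.0)

    def test_known_per_roi_means_recovered(self):
        rng = np.random.default_rng(0)
        stack, rois, bg = make_stack()
        rois[10:14, 10:14] = 2
        means = {1: 33.0, 2: 77.0}
        for label, mean in means.items():
            stack[:, rois == label] = mean
        traces = extract_roi_traces(stack, rois, bg)
        for label, mean in means.items():
            assert np.allclose(traces[label].values, mean - 10.0)

    def test_negative_floored_and_flagged(self):
        stack, rois, bg = make_stack(value=5.0, bg=10.0)
        traces = extract_roi_traces(stack, rois, bg)
        assert np.all(traces[1].values == 0.0)
        assert traces[1].flags.all()

    def test_overlapping_background_rejected(self):
        stack, rois, bg = make_stack()
        bg_bad = rois > 0
        with pytest.raises(PcfretError):
            extract_roi_traces(stack, rois, bg_bad)

    def test_nonfinite_frames_rejected(self):
        stack, rois, bg = make_stack()
        stack[2] = np.nan
        with pytest.raises(PcfretError):
            extract_roi_traces(stack, rois, bg)


class TestBaselineFit:
    times = np.arange(0.0, 1800.0, 10.0)

    def test_flat_trace_baseline_is_constant(self):
        trace = CellTrace(self.times, np.full(self.times.size, 0.25))
        fit = fit_baseline(trace, kind="sigmoid_exp")
        assert fit(self.times) == pytest.approx(
            np.full(self.times.size, 0.25), rel=1e-3
        )

    def test_parameter_recovery_with_noise(self):
        truth = dict(tau=1e4, b=0.2, amplitude=0.1, t0=600.0, r=30.0)
        trace = synthetic_response_trace(self.times, noise=0.01, seed=0, **truth)
        fit = fit_baseline(trace, kind="sigmoid_exp")
        for key, name in [("tau", "tau"), ("b", "b"), ("amplitude", "A"),
                          ("t0", "t0"), ("r", "r")]:
            assert fit.params[name] == pytest.approx(truth[key], rel=0.05), name

    def test_zero_amplitude_reduces_to_pure_decay(self):
        trace = synthetic_response_trace(self.times, tau=5e3, b=0.3, amplitude=0.0)
        fit = fit_baseline(trace, kind="sigmoid_exp")
        assert fit(self.times) == pytest.approx(
            0.3 * np.exp(-self.times / 5e3), rel=1e-3
        )

    def test_biexponential_on_quiet_intervals(self):
        t = self.times
        base = 100.0 * np.exp(-t / 4e3) + 40.0 * np.exp(-t / 600.0)
        signal = base.copy()
        bump = (t >= 600) & (t < 900)
        signal[bump] += 80.0  # elevated transient to be excluded
        trace = CellTrace(t, signal)
        fit = fit_baseline(trace, kind="biexponential",
                           quiet_intervals=[(0, 600), (900, 1800)])
        assert fit(t) == pytest.approx(base, rel=0.02)

    def test_biexponential_requires_quiet_intervals(self):
        trace = CellTrace(self.times, np.ones(self.times.size))
        with pytest.raises(PcfretError):
            fit_baseline(trace, kind="biexponential")

    def test_too_short_trace_rejected(self):
        with pytest.raises(PcfretError):
            fit_baseline(CellTrace(np.arange(5.0), np.ones(5)))


class TestPercentIncrease:
    def test_signal_equal_baseline_is_zero(self):
        t = np.arange(10.0)
        trace = CellTrace(t, np.full(10, 3.0))
        resp = percent_increase(trace, lambda tt: np.full(len(tt), 3.0))
        assert np.allclose(resp.values, 0.0)

    def test_fifty_percent(self):
        t = np.arange(10.0)
        trace = CellTrace(t, np.full(10, 4.5))
        resp = percent_increase(trace, lambda tt: np.full(len(tt), 3.0))
        assert np.allclose(resp.values, 50.0)

    def test_nonpositive_baseline_rejected(self):
        t = np.arange(10.0)
        trace = CellTrace(t, np.ones(10))
        with pytest.raises(PcfretError):
            percent_increase(trace, lambda tt: np.zeros(len(tt)))

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=50, derandomize=True)
    def test_invariant_to_common_rescaling(self, scale):
        t = np.arange(20.0)
        signal = 2.0 + np.sin(t / 3.0)
        base = np.full(20, 1.5)
        r1 = percent_increase(CellTrace(t, signal), lambda tt: base)
        r2 = percent_increase(CellTrace(t, scale * signal),
                              lambda tt: scale * base)
        assert np.allclose(r1.values, r2.values)


class TestResponseMetrics:
    def test_max_of_monotone_ramp(self):
        t = np.arange(0.0, 100.0, 10.0)
        resp = CellTrace(t, np.linspace(0, 30, t.size))
        assert max_response(resp, (0, 100)) == pytest.approx(30.0)
        # half-open: endpoint value excluded
        assert max_response(resp, (0, 90)) == pytest.approx(
            np.linspace(0, 30, t.size)[-2]
        )

    def test_all_negative_response_keeps_sign(self):
        t = np.arange(0.0, 50.0, 10.0)
        resp = CellTrace(t, np.array([-5.0, -3.0, -8.0, -4.0, -6.0]))
        assert max_response(resp, (0, 50)) == pytest.approx(-3.0)

    def test_interval_outside_domain(self):
        resp = CellTrace(np.arange(5.0), np.ones(5))
        with pytest.raises(PcfretError):
            max_response(resp, (100, 200))


class TestOnsetTime:
    def test_analytic_sigmoid_inversion(self):
        t = np.arange(0.0, 300.0, 2.0)
        y = 40.0 / (1.0 + np.exp((100.0 - t) / 10.0))
        onset = onset_time(CellTrace(t, y), method="sigmoid_7p6")
        expected = 100.0 - 10.0 * math.log(1.0 / ONSET_FRACTION - 1.0)
        assert expected == pytest.approx(75.0, abs=0.05)  # ~75.0 s
        assert onset == pytest.approx(expected, abs=1.0)  # < 0.5 sample dt

    @pytest.mark.parametrize("method", ["sigmoid_7p6", "second_derivative"])
    def test_time_shift_equivariance(self, method):
        t = np.arange(0.0, 300.0, 2.0)
        y = 40.0 / (1.0 + np.exp((100.0 - t) / 10.0))
        o1 = onset_time(CellTrace(t, y), method=method)
        o2 = onset_time(CellTrace(t + 37.0, y), method=method)
        assert o2 - o1 == pytest.approx(37.0, abs=1e-6)

    def test_flat_trace_has_no_onset(self):
        t = np.arange(0.0, 100.0, 5.0)
        assert onset_time(CellTrace(t, np.full(t.size, 2.0))) is None
        assert onset_time(CellTrace(t, np.full(t.size, 2.0)),
                          method="second_derivative") is None

    def test_second_derivative_locates_transient_foot(self):
        t = np.arange(0.0, 200.0, 2.0)
        y = 30.0 / (1.0 + np.exp((120.0 - t) / 6.0))
        onset = onset_time(CellTrace(t, y), method="second_derivative")
        # max curvature of a sigmoid sits just before the half-rise point
        assert 100.0 < onset < 120.0


class TestClustering:
    def test_planted_three_blobs_recovered(self):
        feats, truth = planted_response_classes(n_per_class=20, seed=0)
        labels = cluster_responses(feats, k=3, seed=0)
        # perfect recovery up to permutation
        mapping = {}
        for lab, tru in zip(labels, truth):
            mapping.setdefault(lab, tru)
            assert mapping[lab] == tru
        assert len(mapping) == 3

    def test_identical_features_single_effective_cluster(self):
        feats = np.ones((6, 3))
        labels = cluster_responses(feats, k=2, seed=0)
        assert set(labels) <= {1, 2}
        assert labels.shape == (6,)

    def test_k_one_labels_everything_one(self):
        feats = np.random.default_rng(0).normal(size=(5, 2))
        assert np.all(cluster_responses(feats, k=1) == 1)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(PcfretError):
            cluster_responses(np.ones((3, 2)), k=4)

    def test_labels_canonical_by_descending_size(self):
        feats, _ = planted_response_classes(n_per_class=10, seed=0)
        feats = np.vstack([feats, feats[:10]])  # enlarge class 1
        labels = cluster_responses(feats, k=3, seed=0)
        sizes = np.bincount(labels)[1:]
        assert np.all(np.diff(sizes) <= 0)
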