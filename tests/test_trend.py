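"""Sliding trends, gap policy, surge detection and event timing."""

import numpy as np
import pytest

from openqct import (
    ComplexityState,
    EventAnnotation,
    TrendPoint,
    detect_surge,
    lead_time,
    reference_events,
    sliding_trend,
    trend_arrays,
)
from openqct.exceptions import (
    InsufficientBaselineError,
    InsufficientDataError,
    InvalidInputError,
)

RNG = np.random.default_rng(99)
THREE = ("a", "b", "c")


def three_col_data(m=260):
    """Small 3-variable record: one dependent pair, one noise column."""
    x = RNG.normal(size=m)
    data = np.column_stack([x, x + 0.2 * RNG.normal(size=m), RNG.normal(size=m)])
    times = np.arange(m, dtype=float)
    return data, times


def fast_trend(data, times, mask=None, window=100, step=10, **kw):
    kw.setdefault("n_surrogates", 50)
    return sliding_trend(data, mask, times, window=window, step=step,
                         variable_names=THREE, seed=5, **kw)


def synthetic_trend(c_values, dt=1.0):
    """Wrap a bare complexity series into TrendPoints for detector tests."""
    return [TrendPoint(window_end_time=i * dt, window_index=i,
                       state=ComplexityState(C=float(c), C_min=0.0, C_critical=np.inf,
                                             matrices=None, profile=np.array([100.0])),
                       n_beats_used=100)
            for i, c in enumerate(c_values)]


class TestSlidingTrend:
    def test_point_count(self):
        data, times = three_col_data(260)
        assert len(fast_trend(data, times, step=1, n_surrogates=25)) == 161
        assert len(fast_trend(data, times, step=10)) == 17

    def test_narrower_window_more_points(self):
        data, times = three_col_data(200)
        n50 = len(fast_trend(data, times, window=50, step=1, n_surrogates=25))
        n125 = len(fast_trend(data, times, window=125, step=1, n_surrogates=25))
        assert n50 > n125

    def test_record_shorter_than_window(self):
        data, times = three_col_data(50)
        with pytest.raises(InsufficientDataError):
            fast_trend(data, times, window=100)

    def test_constant_data_zero_complexity(self):
        data = np.ones((150, 3))
        tr = fast_trend(data, np.arange(150.0))
        assert all(p.state.C == 0.0 for p in tr)

    def test_determinism(self):
        data, times = three_col_data(180)
        a = trend_arrays(fast_trend(data, times))["C"]
        b = trend_arrays(fast_trend(data, times))["C"]
        np.testing.assert_array_equal(a, b)

    def test_causal_timestamps(self):
        data, times = three_col_data(180)
        tr = fast_trend(data, times, step=7)
        ends = [p.window_end_time for p in tr]
        assert all(t2 >= t1 for t1, t2 in zip(ends, ends[1:]))
        # point w covers beats [w*step, w*step + window): stamp = last beat
        assert ends[0] == times[99]
        assert ends[1] == times[106]

    def test_gap_policy_isolates_fully_masked_channel(self):
        data, times = three_col_data(120)
        mask = np.zeros_like(data, dtype=bool)
        mask[:, 2] = True
        tr = fast_trend(data, times, mask=mask, step=50)
        for p in tr:
            S = p.state.matrices.S
            assert S[2, :2].sum() == 0
            assert p.state.matrices.E[2, 2] == 0.0

    def test_partial_gaps_keep_pair_detectable(self):
        data, times = three_col_data(160)
        mask = np.zeros_like(data, dtype=bool)
        mask[::10, 1] = True  # 10% gaps in the dependent channel
        tr = fast_trend(data, times, mask=mask, step=60, window=150)
        assert tr[0].state.matrices.S[0, 1] == 1


class TestDetectSurge:
    def test_flat_trend_no_alert(self):
        assert detect_surge(synthetic_trend(np.full(100, 5.0)), baseline_span=30) is None

    def test_step_increase_alerts_promptly(self):
        c = np.full(300, 4.0) + 0.01 * np.sin(np.arange(300))
        c[200:] = 40.0
        alert = detect_surge(synthetic_trend(c), baseline_span=100)
        assert alert is not None
        assert alert.kind == "presyncope_alert"
        assert 200 <= alert.time <= 205

    def test_sustain_requirement_filters_single_spikes(self):
        c = np.full(200, 4.0) + 0.01 * np.cos(np.arange(200))
        c[100] = 50.0  # one-point glitch
        assert detect_surge(synthetic_trend(c), baseline_span=80) is None

    def test_short_baseline_rejected(self):
        with pytest.raises(InsufficientBaselineError):
            detect_surge(synthetic_trend(np.full(50, 4.0)), baseline_span=5)

    def test_start_time_rebaselines(self):
        # early spike before start_time must not poison the baseline
        c = np.concatenate([np.full(50, 4.0), [60.0] * 10, np.full(140, 4.0)])
        c += 0.01 * np.sin(np.arange(c.size))
        alert = detect_surge(synthetic_trend(c), baseline_span=60, start_time=70.0)
        assert alert is None


class TestReferenceEvents:
    def _record(self, mbp, hr):
        m = len(mbp)
        data = np.column_stack([np.asarray(hr, float), np.asarray(mbp, float)])
        return data, np.arange(m, dtype=float), ("hr", "mbp")

    def test_flat_record_no_events(self):
        data, t, names = self._record(np.full(200, 95.0), np.full(200, 70.0))
        assert reference_events(data, t, names, baseline_span=100) == []

    def test_ramp_fires_at_sustained_crossing(self):
        mbp = np.concatenate([np.full(150, 100.0), np.linspace(100, 60, 100)])
        data, t, names = self._record(mbp, np.full(250, 70.0))
        evs = reference_events(data, t, names, baseline_span=100)
        assert [e.kind for e in evs] == ["mbp_drop"]
        # threshold 100 - 20 = 80, crossed at index 200 on the ramp
        assert evs[0].time == pytest.approx(201.0, abs=2.0)

    def test_mixed_type_ordering(self):
        mbp = np.concatenate([np.full(150, 100.0), np.linspace(100, 55, 150)])
        hr = np.concatenate([np.full(220, 70.0), np.linspace(70, 40, 80)])
        data, t, names = self._record(mbp, hr)
        evs = {e.kind: e.time for e in reference_events(data, t, names, baseline_span=100)}
        assert evs["mbp_drop"] < evs["hr_drop"]


def test_plot_trend_writes_figure(tmp_path):
    import matplotlib.pyplot as plt

    from openqct.plotting import plot_trend

    data, times = three_col_data(160)
    tr = fast_trend(data, times, step=20)
    out = tmp_path / "trend.png"
    fig = plot_trend(tr, data, times, THREE,
                     events=[EventAnnotation("tilt", 100.0)], path=out)
    plt.close(fig)
    assert out.stat().st_size > 0


class TestLeadTime:
    def test_sign_convention(self):
        alert = EventAnnotation("presyncope_alert", 200.0)
        drop = EventAnnotation("mbp_drop", 280.0)
        assert lead_time(alert, drop) == 80.0
        assert lead_time(drop, alert) == -80.0
        assert lead_time(alert, alert) == 0.0

    def test_missing_annotation(self):
        with pytest.raises(InvalidInputError):
            lead_time(None, EventAnnotation("mbp_drop", 1.0))
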