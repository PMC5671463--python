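"""Performance metrics: per-sprint power, the percent-decrement fatigue
index, total work, task-failure detection, rolling 30-s peaks."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sprintnirs import (
    SprintSegment,
    detect_exhaustion,
    detect_sprints,
    fatigue_index,
    per_sprint_power,
    percent_change,
    preprocess_session,
    rolling_peak,
    stream_min,
    summarize_performance,
    total_work,
)

positive_powers = st.lists(
    st.floats(1.0, 2000.0, allow_nan=False), min_size=1, max_size=40
)


def power_frame(t, p):
    return pd.DataFrame({"time_s": t, "power_w": p})


class TestPerSprintPower:
    def test_constant_power(self):
        t = np.arange(0, 100, 0.1)
        seg = [SprintSegment(1, 20.0, 30.0)]
        assert per_sprint_power(power_frame(t, np.full(t.size, 500.0)), seg) == [500.0]

    def test_linear_ramp_means_midpoint(self):
        t = np.arange(0, 10.1, 0.1)
        p = 80.0 * t  # 0 -> 800 W
        seg = [SprintSegment(1, 0.0, 10.0)]
        (mean,) = per_sprint_power(power_frame(t, p), seg)
        assert mean == pytest.approx(400.0, rel=1e-6)

    def test_noiseless_generator_closed_form(self, noiseless_session):
        segs = [
            SprintSegment(k + 1, t0, t0 + 10.0)
            for k, t0 in enumerate(noiseless_session.truth["sprint_onsets_s"])
        ]
        means = per_sprint_power(noiseless_session.power, segs)
        np.testing.assert_allclose(
            means, noiseless_session.truth["sprint_power_w"], rtol=1e-3
        )

    def test_empty_window_rejected(self):
        t = np.arange(0, 5, 0.1)
        with pytest.raises(ValueError, match="no power samples"):
            per_sprint_power(
                power_frame(t, np.ones(t.size)), [SprintSegment(1, 50.0, 60.0)]
            )


class TestFatigueIndex:
    def test_equal_sprints_zero(self):
        assert fatigue_index([600.0, 600.0, 600.0]) == 0.0

    def test_worked_example(self):
        # 1 - 2100 / (800 * 3) = 0.125
        assert fatigue_index([800.0, 700.0, 600.0]) == pytest.approx(12.5)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(positive_powers, st.floats(0.01, 100.0))
    def test_scale_invariance_and_permutation(self, powers, c):
        base = fatigue_index(powers)
        assert fatigue_index([c * p for p in powers]) == pytest.approx(
            base, abs=1e-9
        )
        assert fatigue_index(sorted(powers)) == pytest.approx(base, abs=1e-9)
        assert 0.0 <= base < 100.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fatigue_index([])
        with pytest.raises(ValueError):
            fatigue_index([500.0, -1.0])


class TestTotalWork:
    def test_constant_blocks(self):
        t = np.arange(0, 400, 0.1)
        p = np.full(t.size, 500.0)
        segs = [SprintSegment(k + 1, 30.0 * k, 30.0 * k + 10.0) for k in range(10)]
        assert total_work(power_frame(t, p), segs) == pytest.approx(50.0, rel=1e-3)

    def test_zero_power(self):
        t = np.arange(0, 100, 0.1)
        segs = [SprintSegment(1, 0.0, 10.0)]
        assert total_work(power_frame(t, np.zeros(t.size)), segs) == 0.0

    def test_consistent_with_per_sprint_means(self, noiseless_session):
        segs = [
            SprintSegment(k + 1, t0, t0 + 10.0)
            for k, t0 in enumerate(noiseless_session.truth["sprint_onsets_s"])
        ]
        work = total_work(noiseless_session.power, segs)
        means = per_sprint_power(noiseless_session.power, segs)
        assert work == pytest.approx(sum(m * 10.0 for m in means) / 1000.0, rel=1e-3)

    def test_additivity_over_segments(self, noiseless_session):
        segs = [
            SprintSegment(k + 1, t0, t0 + 10.0)
            for k, t0 in enumerate(noiseless_session.truth["sprint_onsets_s"])
        ]
        whole = total_work(noiseless_session.power, segs)
        parts = sum(total_work(noiseless_session.power, [s]) for s in segs)
        assert whole == pytest.approx(parts, rel=1e-12)


class TestExhaustion:
    def _cadence(self, t, values):
        return pd.DataFrame({"time_s": t, "cadence_rpm": values})

    def test_no_failure(self):
        t = np.arange(0, 100, 0.2)
        segs = [SprintSegment(1, 0.0, 10.0), SprintSegment(2, 30.0, 40.0)]
        assert detect_exhaustion(self._cadence(t, np.full(t.size, 85.0)), segs) is None

    def test_single_dip(self):
        t = np.arange(0, 300, 0.2)
        c = np.full(t.size, 85.0)
        segs = [SprintSegment(k + 1, 30.0 * k, 30.0 * k + 10.0) for k in range(9)]
        c[(t >= 182) & (t <= 184)] = 65.0  # inside sprint 7
        assert detect_exhaustion(self._cadence(t, c), segs) == 7

    def test_generator_truth_recovered(self, noiseless_session):
        segs = [
            SprintSegment(k + 1, t0, t0 + 10.0)
            for k, t0 in enumerate(noiseless_session.truth["sprint_onsets_s"])
        ]
        assert detect_exhaustion(noiseless_session.cadence, segs) == len(segs)


class TestRollingPeak:
    def test_constant(self):
        t = np.arange(0, 120, 1.0)
        assert rolling_peak(t, np.full(t.size, 40.0)) == pytest.approx(40.0)

    def test_step_long_plateaus(self):
        t = np.arange(0, 200, 1.0)
        y = np.where(t < 100, 30.0, 50.0)
        assert rolling_peak(t, y) == pytest.approx(50.0)

    def test_triangular_against_brute_force(self):
        t = np.arange(0, 300, 0.7)
        y = 45.0 - np.abs(t - 150.0) / 10.0
        got = rolling_peak(t, y, window_s=30.0)
        # exhaustive scan over candidate windows on a dense grid
        best = -np.inf
        dense = np.arange(0, 270, 0.01)
        for s in dense:
            tt = np.linspace(s, s + 30.0, 400)
            yy = np.interp(tt, t, y)
            best = max(best, np.trapezoid(yy, tt) / 30.0)
        assert got == pytest.approx(best, abs=1e-2)
        assert y.min() <= got <= y.max()

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="shorter than window"):
            rolling_peak(np.array([0.0, 5.0]), np.array([1.0, 2.0]))


class TestScalars:
    def test_stream_min(self):
        assert stream_min(np.array([98.0, 92.0, 95.0])) == 92.0
        assert stream_min(np.full(10, 90.0)) == 90.0
        with pytest.raises(ValueError):
            stream_min(np.array([]))

    @pytest.mark.parametrize(
        "pre, post, expected",
        [(400.0, 684.0, 71.0), (100.0, 100.0, 0.0), (100.0, 50.0, -50.0)],
    )
    def test_percent_change(self, pre, post, expected):
        assert percent_change(pre, post) == pytest.approx(expected)

    def test_percent_change_zero_pre(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 10.0)


class TestSummary:
    def test_noiseless_session_summary(self, noiseless_session):
        cs = preprocess_session(noiseless_session)["muscle"]
        segments = detect_sprints(cs, noiseless_session.protocol)
        summary = summarize_performance(noiseless_session, segments)
        assert summary.n_sprints == 10
        assert summary.pacing_ok  # sprints 1-2 within 5% of warm-up best
        assert 0.0 <= summary.s_dec_pct < 100.0
        assert summary.total_work_kj > 0
        assert summary.exhaustion_sprint == 10
        assert summary.spo2_min_pct == pytest.approx(94.0, abs=0.5)
        assert summary.vo2_peak30_mlkgmin <= 40.0 + 1e-6
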