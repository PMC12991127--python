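"""Swim-event detection, labeling, and quality-control tests."""

import numpy as np
import pandas as pd
import pytest

from swimddm import (QCThresholds, detect_swims, gen_orientation_trace,
                     label_event, qc_filter, rolling_variance)
from swimddm.event_processing import extract_events, unwrap_orientation


def flat_trace(n=900, fs=90.0, value=0.0):
    return pd.DataFrame({"time_s": np.arange(n) / fs,
                         "orientation_deg": np.full(n, value)})


class TestRollingVariance:
    def test_constant_trace_zero_variance(self):
        var = rolling_variance(flat_trace())
        assert np.all(var == 0.0)

    def test_alternating_signal_matches_windowed_oracle(self):
        tr = flat_trace()
        o = np.where(np.arange(len(tr)) % 2 == 0, 1.0, -1.0)
        tr["orientation_deg"] = o
        var = rolling_variance(tr, window=0.05)
        # direct centered-window population-variance oracle (5 frames at
        # 90 Hz: 50 ms rounds up from 4.5 frames)
        n = 5
        half = n // 2
        oracle = np.array([np.var(o[max(i - half, 0):i + half + 1])
                           for i in range(len(o))])
        np.testing.assert_allclose(var, oracle, atol=1e-12)
        # interior hand value: population variance of 5 alternating +-1
        assert var[10] == pytest.approx(0.96)

    def test_iid_noise_variance_estimate(self):
        rng = np.random.default_rng(1)
        tr = flat_trace(n=100_000)
        tr["orientation_deg"] = rng.normal(0, 2.0, size=len(tr))
        var = rolling_variance(tr)
        # population variance over n=5 frames has expectation
        # sigma^2 * (n-1)/n = 4 * 0.8
        assert np.mean(var) == pytest.approx(3.2, rel=0.05)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            rolling_variance(flat_trace(n=0))


class TestDetectSwims:
    def test_constant_trace_no_events(self):
        assert len(detect_swims(flat_trace())) == 0

    def test_single_step_recovered(self):
        tr = gen_orientation_trace([(2.0, 20.0, 0.1)], duration=5.0,
                                   noise_sd=0.1, seed=0)
        sw = detect_swims(tr)
        assert len(sw) == 1
        assert sw["orientation_change_deg"].iloc[0] == pytest.approx(20.0, abs=1.0)

    def test_too_brief_excursion_ignored(self):
        # a one-frame spike: variance crosses 1 deg^2 for ~ one frame (11 ms),
        # shorter than the required 20 ms sustained start
        tr = flat_trace()
        tr.loc[450, "orientation_deg"] = 1.6
        var = rolling_variance(tr)
        above = var > 1.0
        # hand-check the construction: excursion shorter than 2 frames
        runs = np.diff(np.flatnonzero(np.diff(np.concatenate(
            ([0], above.astype(int), [0])))).reshape(-1, 2), axis=1)
        assert runs.max(initial=0) < 2
        assert len(detect_swims(tr)) == 0

    def test_isi_between_consecutive_events(self):
        tr = gen_orientation_trace([(1.0, 25.0, 0.1), (3.0, 25.0, 0.1)],
                                   duration=5.0, seed=1)
        sw = detect_swims(tr)
        assert len(sw) == 2
        assert np.isnan(sw["isi_s"].iloc[0])
        gap = sw["start_s"].iloc[1] - sw["end_s"].iloc[0]
        assert sw["isi_s"].iloc[1] == pytest.approx(gap)
        assert 1.5 < sw["isi_s"].iloc[1] < 2.1

    def test_round_trip_many_bouts(self):
        """Known bout schedules are recovered exactly when bouts are
        separated by more than 200 ms."""
        rng = np.random.default_rng(7)
        for rep in range(20):
            n_bouts = rng.integers(3, 10)
            starts = np.cumsum(rng.uniform(0.5, 1.5, size=n_bouts))
            angles = rng.uniform(8, 40, size=n_bouts) * rng.choice([-1, 1], n_bouts)
            bouts = [(float(s), float(a), 0.12) for s, a in zip(starts, angles)]
            tr = gen_orientation_trace(bouts, duration=float(starts[-1] + 1.0),
                                       noise_sd=0.1, seed=int(rep))
            sw = detect_swims(tr)
            assert len(sw) == n_bouts
            np.testing.assert_allclose(sw["orientation_change_deg"], angles,
                                       atol=1.0)


class TestLabeling:
    @pytest.mark.parametrize("change,direction,expected", [
        (20.0, "left", "correct"),
        (-20.0, "left", "incorrect"),
        (20.0, "right", "incorrect"),
        (-20.0, "right", "correct"),
        (2.0, "left", "forward-excluded"),
        (-3.0, "right", "forward-excluded"),
        (-3.01, "right", "correct"),
        (3.01, "right", "incorrect"),
    ])
    def test_label_rules(self, change, direction, expected):
        assert label_event(change, direction) == expected

    def test_missing_direction_rejected(self):
        with pytest.raises(ValueError):
            label_event(10.0, "up")

    def test_every_stimulus_event_gets_one_label(self):
        tr = gen_orientation_trace(
            [(0.5 + i, (-1) ** i * (2 + 3 * i), 0.1) for i in range(8)],
            duration=10.0, seed=3)
        events, report = extract_events(tr)
        assert events["label"].isin(
            ["correct", "incorrect", "forward-excluded"]).all()

    def test_unwrap_helper(self):
        wrapped = np.array([170.0, 179.0, -179.0, -170.0])
        un = unwrap_orientation(wrapped)
        assert np.all(np.abs(np.diff(un)) < 180)


def qc_fixture():
    """200 events with a hand-enumerated set of QC violations."""
    n = 200
    events = pd.DataFrame({
        "start_s": np.arange(n, dtype=float),
        "end_s": np.arange(n) + 0.2,
        "isi_s": np.full(n, 0.8),
        "mean_speed_cm_s": np.full(n, 1.0),
        "area_px": np.full(n, 900.0),
        "orientation_change_deg": np.full(n, 25.0),
        "trial_id": np.repeat(np.arange(4), 50),
    })
    events.loc[3, "isi_s"] = 31.0        # long ISI           (trial 0)
    events.loc[60, "mean_speed_cm_s"] = 6.5   # tracking jump  (trial 1)
    events.loc[110, "area_px"] = 2500.0  # rim contour        (trial 2)
    events.loc[120, "orientation_change_deg"] = 160.0  # head/tail swap (trial 2)
    # trial 3: 4 flagged events of 50 -> 8% > 5% -> trial dropped
    events.loc[[150, 160, 170, 180], "orientation_change_deg"] = 155.0
    return events


class TestQCFilter:
    def test_hand_enumerated_retained_set(self):
        events = qc_fixture()
        kept, report = qc_filter(events, session_duration_s=200.0)
        # trial 3 dropped entirely (50 events); flagged events 3, 60, 110,
        # 120 dropped from trials 0-2 -> 200 - 50 - 4 = 146 retained
        assert report.dropped_trials == [3]
        assert len(kept) == 146
        assert report.flags == {"long_isi": 1, "fast_swim": 1,
                                "big_area": 1, "big_turn": 5}
        assert not report.fish_dropped
        assert report.fish_swim_rate == pytest.approx(1.0)

    @pytest.mark.parametrize("isi,flagged", [(29.9, 0), (31.0, 1)])
    def test_isi_threshold_boundary(self, isi, flagged):
        events = qc_fixture().iloc[:50].copy()
        events.loc[3, "isi_s"] = isi
        _, report = qc_filter(events, session_duration_s=50.0)
        assert report.flags["long_isi"] == flagged

    def test_fish_dropped_below_rate_floor(self):
        events = qc_fixture().iloc[:60].copy()
        kept, report = qc_filter(events, session_duration_s=200.0)
        assert report.fish_swim_rate == pytest.approx(0.3)
        assert report.fish_dropped
        assert len(kept) == 0

    def test_fish_retained_above_rate_floor(self):
        events = qc_fixture().iloc[:80].copy()  # 0.4 swims/s over 200 s
        kept, report = qc_filter(events, session_duration_s=200.0)
        assert not report.fish_dropped

    def test_missing_columns_skip_criteria(self):
        events = qc_fixture().drop(columns=["mean_speed_cm_s", "area_px"])
        _, report = qc_filter(events, session_duration_s=200.0)
        assert "fast_swim" in report.skipped_criteria
        assert "big_area" in report.skipped_criteria

    def test_qc_monotone_in_thresholds(self):
        events = qc_fixture()
        base_kept, _ = qc_filter(events, session_duration_s=200.0)
        tighter = QCThresholds(max_isi_s=20.0, max_speed_cm_s=4.0,
                               max_area_px=1000.0, max_turn_deg=100.0,
                               max_flagged_fraction=0.02,
                               min_swim_rate_hz=0.5)
        tight_kept, _ = qc_filter(events, tighter, session_duration_s=200.0)
        assert len(tight_kept) <= len(base_kept)
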