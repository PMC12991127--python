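"""Swim-event extraction and quality control for orientation traces.

Larval zebrafish swim in discrete bouts; each bout shows up as a
transient rise in the variance of the heading-orientation trace.
Events are detected with a two-threshold hysteresis on a 50 ms rolling
variance: a bout starts when the variance stays above 1 deg^2 for at
least 20 ms and ends once it stays below 0.5 deg^2 for at least 50 ms.
The signed orientation change of a bout, relative to the direction of
coherent motion, labels it correct, incorrect, or forward-excluded
(|change| <= 3 deg).  Tracking artefacts are removed by six
quality-control criteria operating on events, trials, and whole fish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "QCReport",
    "unwrap_orientation",
    "rolling_variance",
    "detect_swims",
    "label_event",
    "qc_filter",
    "extract_events",
]

FORWARD_BAND_DEG = 3.0


@dataclass(frozen=True)
class QCThresholds:
    """Event/trial/fish rejection thresholds for tracking-error control."""

    max_isi_s: float = 30.0
    max_speed_cm_s: float = 6.0
    max_area_px: float = 2000.0
    max_turn_deg: float = 150.0
    max_flagged_fraction: float = 0.05   # per trial
    min_swim_rate_hz: float = 0.375      # per fish


@dataclass
class QCReport:
    """Outcome of the quality-control pass."""

    n_events: int = 0
    flags: dict[str, int] = field(default_factory=dict)
    dropped_trials: list = field(default_factory=list)
    fish_dropped: bool = False
    fish_swim_rate: float = float("nan")
    skipped_criteria: list[str] = field(default_factory=list)
    n_forward_excluded: int = 0

    def flag_rate(self, name: str) -> float:
        return self.flags.get(name, 0) / self.n_events if self.n_events else 0.0


def unwrap_orientation(orientation_deg: np.ndarray) -> np.ndarray:
    """Remove modulo-360 wrap jumps (> 180 deg between frames)."""
    return np.degrees(np.unwrap(np.radians(np.asarray(orientation_deg, float))))


def rolling_variance(trace: pd.DataFrame, window: float = 0.05) -> np.ndarray:
    """Centered rolling population variance of orientation, in deg^2.

    ``trace`` needs columns ``time_s`` and ``orientation_deg``.  The
    window spans ``window`` seconds of frames (at least 2); edges use
    truncated windows.  Population variance (divide by n) is used — the
    detection thresholds are empirical, so the estimator choice merely
    rescales them slightly.
    """
    if len(trace) == 0:
        raise ValueError("empty orientation trace")
    t = trace["time_s"].to_numpy(float)
    if len(t) > 1:
        fs = 1.0 / np.median(np.diff(t))
    else:
        fs = 0.0
    # half-frame ties round up: a 50 ms window at 90 Hz (4.5 frames)
    # becomes an odd, naturally centered 5-frame window
    w = window * fs
    n = max(2, int(w) + (1 if w - int(w) >= 0.5 - 1e-9 else 0))
    if n > len(trace):
        n = len(trace)
    if n < 2:
        raise ValueError("variance window must span at least 2 frames")
    var = (trace["orientation_deg"]
           .rolling(n, center=True, min_periods=2)
           .var(ddof=0)
           .to_numpy(float))
    return np.nan_to_num(var, nan=0.0)


def _sustained_runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Start indices of runs of True of length >= min_len."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return starts[(ends - starts) >= min_len]


def detect_swims(trace: pd.DataFrame, window: float = 0.05,
                 start_threshold: float = 1.0, end_threshold: float = 0.5,
                 min_start_s: float = 0.02, min_end_s: float = 0.05,
                 ) -> pd.DataFrame:
    """Hysteresis bout detection on the rolling orientation variance.

    Returns a table with columns start_s, end_s, orientation_change_deg,
    isi_s (end of previous bout to this start; NaN for the first), plus
    any per-frame annotation columns (coherence, direction, phase,
    trial_id) sampled at the bout start, and mean_speed_cm_s if x_cm /
    y_cm columns are present.
    """
    if len(trace) == 0:
        return _empty_swim_table()
    var = rolling_variance(trace, window=window)
    t = trace["time_s"].to_numpy(float)
    fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 90.0
    min_start_frames = max(1, int(math.ceil(min_start_s * fs)))
    min_end_frames = max(1, int(math.ceil(min_end_s * fs)))

    above = var > start_threshold
    below = var < end_threshold
    start_candidates = _sustained_runs(above, min_start_frames)
    end_candidates = _sustained_runs(below, min_end_frames)

    orientation = trace["orientation_deg"].to_numpy(float)
    rows = []
    prev_end_t = None
    margin = 2  # frames: read orientation just outside the variance interval
    for s_idx in start_candidates:
        if rows and s_idx <= rows[-1]["_end_idx"]:
            continue  # still inside the previous bout
        later_ends = end_candidates[end_candidates > s_idx]
        e_idx = int(later_ends[0]) if len(later_ends) else len(t) - 1
        o0 = orientation[max(s_idx - margin, 0)]
        o1 = orientation[min(e_idx + margin, len(t) - 1)]
        row = {
            "start_s": t[s_idx],
            "end_s": t[e_idx],
            "orientation_change_deg": o1 - o0,
            "isi_s": t[s_idx] - prev_end_t if prev_end_t is not None else np.nan,
            "_start_idx": int(s_idx),
            "_end_idx": int(e_idx),
        }
        for col in ("coherence", "direction", "phase", "trial_id"):
            if col in trace.columns:
                row[col] = trace[col].iloc[s_idx]
        if "x_cm" in trace.columns and "y_cm" in trace.columns:
            seg = trace.iloc[s_idx:e_idx + 1]
            path = float(np.sum(np.hypot(np.diff(seg["x_cm"].to_numpy(float)),
                                         np.diff(seg["y_cm"].to_numpy(float)))))
            dur = t[e_idx] - t[s_idx]
            row["mean_speed_cm_s"] = path / dur if dur > 0 else 0.0
        prev_end_t = t[e_idx]
        rows.append(row)
        cursor = e_idx
    if not rows:
        return _empty_swim_table()
    df = pd.DataFrame(rows).drop(columns=["_start_idx", "_end_idx"])
    return df


def _empty_swim_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["start_s", "end_s", "orientation_change_deg",
                                 "isi_s"])


def label_event(orientation_change_deg: float, stimulus_direction: str,
                forward_band: float = FORWARD_BAND_DEG) -> str:
    """Classify one bout as correct / incorrect / forward-excluded.

    Convention: positive orientation change is a leftward
    (counter-clockwise) turn, so it follows a ``left`` stimulus.  Bouts
    with |change| <= ``forward_band`` degrees are straight swims and are
    excluded from the binary statistics.  During 0%-coherence trials the
    caller passes the trial's nominal (counterbalanced) direction.
    """
    if stimulus_direction not in ("left", "right"):
        raise ValueError(f"unknown stimulus direction {stimulus_direction!r}")
    if abs(orientation_change_deg) <= forward_band:
        return "forward-excluded"
    toward = (orientation_change_deg > 0) == (stimulus_direction == "left")
    return "correct" if toward else "incorrect"


def qc_filter(events: pd.DataFrame,
              thresholds: QCThresholds = QCThresholds(),
              session_duration_s: float | None = None,
              ) -> tuple[pd.DataFrame, QCReport]:
    """Apply the six tracking-error criteria; return retained events.

    Event-level flags: ISI at or above 30 s, mean swim speed at or above
    6 cm/s, contour area at or above 2000 px, turn magnitude above
    150 deg.  Any trial in which more than 5% of swims are flagged is
    dropped entirely.  The whole fish is dropped when its mean swim rate
    falls below 0.375 swims/s (computed over ``session_duration_s``, or
    the event time span when not given).  Criteria whose input columns
    are absent are skipped and recorded in the report.
    """
    report = QCReport(n_events=len(events))
    if len(events) == 0:
        report.fish_dropped = True
        report.fish_swim_rate = 0.0
        return events.copy(), report

    flagged = np.zeros(len(events), bool)

    def apply(name: str, column: str, bad: np.ndarray | None) -> None:
        nonlocal flagged
        if bad is None:
            report.skipped_criteria.append(name)
            return
        report.flags[name] = int(np.nansum(bad))
        flagged |= np.asarray(bad, bool)

    isi = events["isi_s"].to_numpy(float) if "isi_s" in events else None
    apply("long_isi", "isi_s",
          None if isi is None else np.nan_to_num(isi) >= thresholds.max_isi_s)
    if "mean_speed_cm_s" in events:
        speed = events["mean_speed_cm_s"].to_numpy(float)
        apply("fast_swim", "mean_speed_cm_s", speed >= thresholds.max_speed_cm_s)
    else:
        apply("fast_swim", "mean_speed_cm_s", None)
    if "area_px" in events:
        area = events["area_px"].to_numpy(float)
        apply("big_area", "area_px", area >= thresholds.max_area_px)
    else:
        apply("big_area", "area_px", None)
    turn = events["orientation_change_deg"].to_numpy(float)
    apply("big_turn", "orientation_change_deg",
          np.abs(turn) > thresholds.max_turn_deg)

    kept = events[~flagged].copy()

    if "trial_id" in events.columns:
        for tid, grp in events.groupby("trial_id"):
            frac = flagged[grp.index.to_numpy()].mean()
            if frac > thresholds.max_flagged_fraction:
                report.dropped_trials.append(tid)
        if report.dropped_trials:
            kept = kept[~kept["trial_id"].isin(report.dropped_trials)]

    if session_duration_s is None:
        t0 = float(events["start_s"].min()) if "start_s" in events else 0.0
        t1 = float(events["end_s"].max()) if "end_s" in events else 0.0
        session_duration_s = max(t1 - t0, 0.0)
    rate = len(events) / session_duration_s if session_duration_s > 0 else 0.0
    report.fish_swim_rate = rate
    if rate < thresholds.min_swim_rate_hz:
        report.fish_dropped = True
        kept = kept.iloc[0:0]
    return kept.reset_index(drop=True), report


def extract_events(trace: pd.DataFrame,
                   thresholds: QCThresholds = QCThresholds(),
                   ) -> tuple[pd.DataFrame, QCReport]:
    """Full front-end: detect bouts, label them, apply quality control.

    The trace needs time_s and orientation_deg columns; direction /
    coherence / phase / trial_id / position columns are used when
    present.  Forward swims are labeled but retained in the returned
    table (the excluded-forward tally is in the report); downstream
    histogram construction ignores them by label.
    """
    swims = detect_swims(trace)
    if len(swims) and "direction" in swims.columns:
        swims["label"] = [
            label_event(dc, d) for dc, d in
            zip(swims["orientation_change_deg"], swims["direction"])]
    elif len(swims):
        swims["label"] = "forward-excluded"
    duration = (float(trace["time_s"].iloc[-1] - trace["time_s"].iloc[0])
                if len(trace) else 0.0)
    kept, report = qc_filter(swims, thresholds, session_duration_s=duration)
    if "label" in kept.columns:
        report.n_forward_excluded = int((kept["label"] == "forward-excluded").sum())
    return kept, report
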