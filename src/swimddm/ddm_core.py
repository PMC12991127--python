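"""Bounded Ornstein-Uhlenbeck decision model and its event simulator.

The decision variable ``x`` integrates a transformed stimulus drive with
leak and diffusion::

    dx = (mu * f(I) - lam * x) dt + sigma dW,      f(I) = sqrt(I)

between absorbing bounds at ``+-B`` (``B = 1`` in all fitting contexts).
A bound hit emits a decision event (``correct`` for ``+B``, ``incorrect``
for ``-B``), after which ``x`` is partially reset to ``r * sign(x) * B``
and frozen for a refractory delay ``delta``.  Forward-Euler integration
with a fixed time step; the Wiener increment has standard deviation
``sigma * sqrt(dt)`` so event statistics are invariant to the choice of
``dt``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "DDMParameters",
    "StimulusProtocol",
    "SimulationConfig",
    "EventSeries",
    "SimulationDivergenceError",
    "input_transform",
    "step",
    "simulate",
]

DEFAULT_COHERENCES = (0.0, 0.25, 0.5, 1.0)

# phase codes used in the compiled kernel
_PHASE_REST = 0
_PHASE_STIM = 1
_PHASE_NAMES = np.array(["rest", "stimulus"])


class SimulationDivergenceError(RuntimeError):
    """Raised when the integrator state leaves the divergence guard band."""


@dataclass(frozen=True)
class DDMParameters:
    """The five free latent parameters plus the fixed decision bound.

    Units assume the bound as the unit of evidence: ``sigma`` in
    bound-units/sqrt(s), ``mu`` in bound-units/s, ``lam`` in 1/s
    (negative values are self-reinforcing), ``r`` dimensionless in
    [0, 1], ``delta`` in s.  ``bound`` is fixed at 1 for fitting; it is
    exposed only because it is redundant with (sigma, mu) and scaling
    all three together must not change event statistics.
    """

    sigma: float
    mu: float
    lam: float
    r: float
    delta: float
    bound: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"reset fraction r must be in [0, 1], got {self.r}")
        if self.delta < 0:
            raise ValueError(f"delay delta must be >= 0, got {self.delta}")
        if self.bound <= 0:
            raise ValueError(f"bound must be > 0, got {self.bound}")

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma": self.sigma,
            "mu": self.mu,
            "lam": self.lam,
            "r": self.r,
            "delta": self.delta,
            "bound": self.bound,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DDMParameters":
        return cls(
            sigma=float(d["sigma"]),
            mu=float(d["mu"]),
            lam=float(d["lam"]),
            r=float(d["r"]),
            delta=float(d["delta"]),
            bound=float(d.get("bound", 1.0)),
        )

    def replace(self, **kw) -> "DDMParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulation schedule of a random-dot-motion session.

    ``continuous`` mode presents each coherence as one uninterrupted
    stimulation segment; ``trial`` mode repeats the classical
    rest / stimulus / rest trial structure per coherence.  The first
    ``exclusion_window`` seconds after each stimulus onset are excluded
    from fitting histograms (onset adaptation).
    """

    mode: str = "continuous"  # {"continuous", "trial"}
    coherence_levels: tuple[float, ...] = DEFAULT_COHERENCES
    rest_pre: float = 10.0
    stim_dur: float = 30.0
    rest_post: float = 10.0
    exclusion_window: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "trial"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        for c in self.coherence_levels:
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coherence {c} outside [0, 1]")
        if min(self.rest_pre, self.stim_dur, self.rest_post) < 0:
            raise ValueError("durations must be >= 0")
        if not self.exclusion_window < self.stim_dur:
            raise ValueError("exclusion_window must be smaller than stim_dur")

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "coherences": list(self.coherence_levels),
            "rest_pre": self.rest_pre,
            "stim_dur": self.stim_dur,
            "rest_post": self.rest_post,
            "exclusion_window": self.exclusion_window,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            mode=d.get("mode", "continuous"),
            coherence_levels=tuple(d.get("coherences", DEFAULT_COHERENCES)),
            rest_pre=float(d.get("rest_pre", 10.0)),
            stim_dur=float(d.get("stim_dur", 30.0)),
            rest_post=float(d.get("rest_post", 10.0)),
            exclusion_window=float(d.get("exclusion_window", 2.0)),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings of one simulation run.

    Exactly one of ``duration`` (stimulation seconds per coherence,
    continuous mode) or ``n_trials`` (trials per coherence, trial mode)
    is used depending on the protocol mode.
    """

    dt: float = 0.01
    seed: int = 0
    duration: float | None = None
    n_trials: int | None = None
    x0: float = 0.0
    divergence_guard: float = 10.0  # in units of the bound

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration is not None and self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass
class EventSeries:
    """Ordered decision events of one simulated or recorded session.

    ``events`` columns: time_s (since session start, one session per
    coherence), isi_s, label {correct, incorrect}, coherence, trial_id,
    phase {rest, stimulus}, t_in_segment_s (since current segment
    onset), first_in_session (bool; its isi_s is measured from the
    session start and is excluded from fitting histograms).
    ``stim_time`` maps coherence -> total stimulation seconds.
    """

    events: pd.DataFrame
    protocol: StimulusProtocol
    stim_time: dict[float, float]
    dt: float = 0.01

    def __len__(self) -> int:
        return len(self.events)

    def to_csv(self, path) -> None:
        cols = ["time_s", "isi_s", "label", "coherence", "trial_id", "phase",
                "t_in_segment_s", "first_in_session"]
        self.events[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, protocol: StimulusProtocol,
                 stim_time: dict[float, float], dt: float = 0.01,
                 ) -> "EventSeries":
        """Load an event table; ``stim_time`` gives the total stimulation
        seconds per coherence (not recoverable from the events alone).
        Missing bookkeeping columns get permissive defaults so swim
        tables from the experimental front-end can be used directly."""
        df = pd.read_csv(path)
        if "time_s" not in df.columns and "start_s" in df.columns:
            df = df.rename(columns={"start_s": "time_s"})
        if "phase" not in df.columns:
            df["phase"] = "stimulus"
        if "t_in_segment_s" not in df.columns:
            df["t_in_segment_s"] = np.inf  # assume steady state
        if "first_in_session" not in df.columns:
            df["first_in_session"] = False
        if "trial_id" not in df.columns:
            df["trial_id"] = 0
        return cls(events=df, protocol=protocol, stim_time=dict(stim_time),
                   dt=dt)


def input_transform(I: float | np.ndarray) -> float | np.ndarray:
    """Sublinear (Weber-law) stimulus transform ``f(I) = sqrt(I)``.

    ``I`` is the motion coherence in [0, 1]; the exponent is fixed at
    0.5 (leaving it free makes the fit non-identifiable).
    """
    arr = np.asarray(I, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"stimulus strength must lie in [0, 1], got {I}")
    out = np.sqrt(arr)
    return float(out) if np.isscalar(I) or arr.ndim == 0 else out


def step(x: float, params: DDMParameters, I: float, dt: float,
         noise_draw: float) -> float:
    """One forward-Euler update of the decision variable (no bound check)."""
    drive = params.mu * input_transform(I)
    return x + (drive - params.lam * x) * dt + params.sigma * math.sqrt(dt) * noise_draw


@njit(cache=True)
def _run_session(seg_nsteps, seg_drive, seg_phase, seg_trial, seg_coh,
                 lam, sig_sdt, r, bound, dt, n_delay, x0, guard, noise):
    """Euler loop over one session (a sequence of constant-drive segments).

    Returns (event global step index, event sign, event segment index,
    n_events, diverged_flag).  Bound hits are tested at the end of each
    step; the state is frozen for ``n_delay`` steps after a hit, during
    which noise draws are still consumed so that matched seeds stay
    aligned under bound rescaling.
    """
    n_total = noise.shape[0]
    ev_step = np.empty(n_total, np.int64)
    ev_sign = np.empty(n_total, np.int8)
    ev_seg = np.empty(n_total, np.int64)
    x = x0
    k = 0
    delay_left = 0
    g = 0
    for s in range(seg_nsteps.shape[0]):
        a = seg_drive[s]
        for _ in range(seg_nsteps[s]):
            z = noise[g]
            if delay_left > 0:
                delay_left -= 1
            else:
                x = x + (a - lam * x) * dt + sig_sdt * z
                ax = x if x >= 0 else -x
                if ax >= bound:
                    sgn = 1 if x > 0 else -1
                    ev_step[k] = g
                    ev_sign[k] = sgn
                    ev_seg[k] = s
                    k += 1
                    x = r * sgn * bound
                    delay_left = n_delay
                elif ax > guard or not np.isfinite(x):
                    return ev_step[:k], ev_sign[:k], ev_seg[:k], k, True
            g += 1
    return ev_step[:k], ev_sign[:k], ev_seg[:k], k, False


def _session_segments(protocol: StimulusProtocol, config: SimulationConfig,
                      coherence: float, trial_offset: int):
    """Segment arrays (nsteps, drive-coefficient f(I), phase, trial, coh)."""
    dt = config.dt
    if protocol.mode == "continuous":
        if config.duration is None:
            raise ValueError("continuous mode requires SimulationConfig.duration")
        nsteps = [int(round(config.duration / dt))]
        fI = [input_transform(coherence)]
        phase = [_PHASE_STIM]
        trial = [trial_offset]
        coh = [coherence]
    else:
        if config.n_trials is None:
            raise ValueError("trial mode requires SimulationConfig.n_trials")
        nsteps, fI, phase, trial, coh = [], [], [], [], []
        n_rest_pre = int(round(protocol.rest_pre / dt))
        n_stim = int(round(protocol.stim_dur / dt))
        n_rest_post = int(round(protocol.rest_post / dt))
        for t in range(config.n_trials):
            tid = trial_offset + t
            for n, ph, c in ((n_rest_pre, _PHASE_REST, 0.0),
                             (n_stim, _PHASE_STIM, coherence),
                             (n_rest_post, _PHASE_REST, 0.0)):
                if n > 0:
                    nsteps.append(n)
                    fI.append(input_transform(c))
                    phase.append(ph)
                    trial.append(tid)
                    coh.append(coherence)
    return (np.asarray(nsteps, np.int64), np.asarray(fI, float),
            np.asarray(phase, np.int8), np.asarray(trial, np.int64),
            np.asarray(coh, float))


def _simulate_sessions(params: DDMParameters, protocol: StimulusProtocol,
                       config: SimulationConfig):
    """Run all per-coherence sessions; yield raw event arrays.

    Returns (records, stim_time) where each record is a dict of numpy
    arrays (t, sign, isi, t_in_segment, phase, trial, first) for one
    coherence session.  This is the allocation-light core shared by the
    user-facing `simulate` and the fast histogram path used inside
    optimization loops.
    """
    dt = config.dt
    n_delay = int(math.ceil(params.delta / dt - 1e-12)) if params.delta > 0 else 0
    sig_sdt = params.sigma * math.sqrt(dt)
    guard = config.divergence_guard * params.bound

    records = []
    stim_time: dict[float, float] = {}
    children = np.random.SeedSequence(config.seed).spawn(
        len(protocol.coherence_levels))
    trial_offset = 0
    for ci, coherence in enumerate(protocol.coherence_levels):
        seg_nsteps, seg_fI, seg_phase, seg_trial, seg_coh = _session_segments(
            protocol, config, coherence, trial_offset)
        trial_offset = int(seg_trial.max()) + 1 if len(seg_trial) else trial_offset
        n_total = int(seg_nsteps.sum())
        stim_time[coherence] = float(
            seg_nsteps[seg_phase == _PHASE_STIM].sum() * dt)
        if n_total == 0:
            continue
        rng = np.random.default_rng(children[ci])
        noise = rng.standard_normal(n_total)
        ev_step, ev_sign, ev_seg, k, diverged = _run_session(
            seg_nsteps, params.mu * seg_fI, seg_phase, seg_trial, seg_coh,
            params.lam, sig_sdt, params.r, params.bound, dt, n_delay,
            config.x0, guard, noise)
        if diverged:
            raise SimulationDivergenceError(
                f"integrator state left +-{guard:g} with parameters "
                f"{params.as_dict()} at coherence {coherence}")
        t = (ev_step[:k] + 1) * dt
        seg_start = np.concatenate(([0], np.cumsum(seg_nsteps)))[:-1] * dt
        isi = np.empty(k)
        if k:
            isi[0] = t[0]
            isi[1:] = np.diff(t)
        first = np.zeros(k, bool)
        if k:
            first[0] = True
        ev_seg = ev_seg[:k]
        records.append({
            "coherence": coherence,
            "t": t,
            "sign": ev_sign[:k],
            "isi": isi,
            "t_in_segment": t - seg_start[ev_seg],
            "phase": seg_phase[ev_seg],
            "trial": seg_trial[ev_seg],
            "coh_attr": seg_coh[ev_seg],
            "first": first,
        })
    return records, stim_time


def simulate(params: DDMParameters, protocol: StimulusProtocol,
             config: SimulationConfig) -> EventSeries:
    """Simulate the decision process over all protocol coherences.

    One independent session per coherence level, each started at
    ``x0`` with its own noise stream spawned from ``config.seed``; in
    trial mode the state carries over across trials within a session.
    Events emitted during rest phases are recorded with phase ``rest``
    and excluded from fitting histograms downstream.
    """
    records, stim_time = _simulate_sessions(params, protocol, config)
    frames = []
    for rec in records:
        frames.append(pd.DataFrame({
            "time_s": rec["t"],
            "isi_s": rec["isi"],
            "label": np.where(rec["sign"] > 0, "correct", "incorrect"),
            "coherence": rec["coh_attr"],
            "trial_id": rec["trial"],
            "phase": _PHASE_NAMES[rec["phase"].astype(int)],
            "t_in_segment_s": rec["t_in_segment"],
            "first_in_session": rec["first"],
        }))
    if frames:
        events = pd.concat(frames, ignore_index=True)
    else:
        events = pd.DataFrame(columns=[
            "time_s", "isi_s", "label", "coherence", "trial_id", "phase",
            "t_in_segment_s", "first_in_session"])
    return EventSeries(events=events, protocol=protocol,
                       stim_time=stim_time, dt=config.dt)
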