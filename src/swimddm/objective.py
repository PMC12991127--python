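"""Time-normalized labeled ISI histograms and the weighted-KL fitting loss.

Inter-swim intervals of correct and incorrect decisions are binned per
coherence level into 40 half-open bins covering [0, 2) s (bin width
0.05 s, five simulation steps) and normalized by the total stimulation
time.  Only steady-state events — at least 2 s after stimulus onset —
enter the histograms.

The fitting loss compares target and model histograms with a weighted
Kullback-Leibler divergence::

    DKL*(P0, P1, P2) = sum_n P0(n) P1(n) ln(P1(n) / P2(n))

evaluated in both orientations, d0 = DKL*(Pt, Pt, Pm) and
d1 = DKL*(Pt, Pm, Pt); the larger of the two is the distance of one
histogram pair, and the mean over the eight (coherence, label) pairs is
the total loss.  Weighting each bin by the target height makes errors
at the histogram peak dominate errors in the flat tail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .ddm_core import (DDMParameters, EventSeries, SimulationConfig,
                       StimulusProtocol, _PHASE_STIM, _simulate_sessions)

__all__ = [
    "BIN_EDGES",
    "LabeledISIHistograms",
    "isi_histograms",
    "simulate_histograms",
    "dkl",
    "dkl_star",
    "pair_distance",
    "total_loss",
]

ISI_MAX = 2.0
BIN_WIDTH = 0.05
BIN_EDGES = np.round(np.arange(0.0, ISI_MAX + BIN_WIDTH / 2, BIN_WIDTH), 10)
LABELS = ("correct", "incorrect")


@dataclass
class LabeledISIHistograms:
    """Eight time-normalized ISI histograms (4 coherences x 2 labels).

    ``heights[(coherence, label)]`` holds the 40 bin heights.  Under the
    default ``density`` convention a height is events per second of
    stimulation per second of ISI (count / (T * bin_width)); under
    ``per_bin`` it is count / T.  The area A(c, label) = integral of the
    histogram is the in-range event rate (events/s) and is identical
    under both conventions.
    """

    bin_edges: np.ndarray
    heights: dict[tuple[float, str], np.ndarray]
    total_time: dict[float, float]
    convention: str = "density"
    n_retained: dict[tuple[float, str], int] = field(default_factory=dict)
    n_excluded: int = 0
    clip_fraction: float = 0.0  # fraction of bins clipped at 0 by noise injection

    @property
    def coherences(self) -> tuple[float, ...]:
        return tuple(sorted(self.total_time))

    def area(self, coherence: float, label: str) -> float:
        """In-range event rate (events/s) for one histogram."""
        h = self.heights[(coherence, label)]
        if self.convention == "density":
            return float(np.sum(h) * BIN_WIDTH)
        return float(np.sum(h))

    def per_bin_heights(self, coherence: float, label: str) -> np.ndarray:
        """Heights in count/T units regardless of storage convention."""
        h = self.heights[(coherence, label)]
        return h * BIN_WIDTH if self.convention == "density" else h.copy()

    def pairs(self):
        for c in self.coherences:
            for label in LABELS:
                yield (c, label)

    def to_json(self, path) -> None:
        doc = {
            "bin_edges": self.bin_edges.tolist(),
            "convention": self.convention,
            "total_time": {str(c): t for c, t in self.total_time.items()},
            "heights": {f"{c}:{label}": self.heights[(c, label)].tolist()
                        for (c, label) in self.pairs()},
            "n_retained": {f"{c}:{label}": self.n_retained.get((c, label), 0)
                           for (c, label) in self.pairs()},
            "n_excluded": self.n_excluded,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "LabeledISIHistograms":
        with open(path) as fh:
            doc = json.load(fh)
        heights = {}
        retained = {}
        for key, arr in doc["heights"].items():
            c, label = key.rsplit(":", 1)
            heights[(float(c), label)] = np.asarray(arr, float)
        for key, n in doc.get("n_retained", {}).items():
            c, label = key.rsplit(":", 1)
            retained[(float(c), label)] = int(n)
        return cls(
            bin_edges=np.asarray(doc["bin_edges"], float),
            heights=heights,
            total_time={float(c): float(t)
                        for c, t in doc["total_time"].items()},
            convention=doc.get("convention", "density"),
            n_retained=retained,
            n_excluded=int(doc.get("n_excluded", 0)),
        )


def isi_histograms(events: EventSeries, protocol: StimulusProtocol | None = None,
                   convention: str = "density") -> LabeledISIHistograms:
    """Bin labeled steady-state ISIs into time-normalized histograms.

    Retained events: stimulus phase, at least ``exclusion_window``
    seconds after segment onset, label correct/incorrect, not the first
    event of a session, ISI in [0, 2) s.  Heights are normalized by the
    total stimulation time of the event's coherence level.
    """
    if convention not in ("density", "per_bin"):
        raise ValueError(f"unknown height convention {convention!r}")
    protocol = protocol or events.protocol
    df = events.events
    known = set(protocol.coherence_levels)
    if len(df) and not set(df["coherence"].unique()) <= known:
        unknown = set(df["coherence"].unique()) - known
        raise ValueError(f"events carry coherence levels {unknown} "
                         f"absent from the protocol")
    mask = np.ones(len(df), bool)
    if len(df):
        mask &= (df["phase"] == "stimulus").to_numpy()
        mask &= (df["t_in_segment_s"] >= protocol.exclusion_window).to_numpy()
        mask &= df["label"].isin(LABELS).to_numpy()
        if "first_in_session" in df:
            mask &= ~df["first_in_session"].to_numpy(dtype=bool)
    kept = df[mask] if len(df) else df
    in_range = ((kept["isi_s"] >= 0) & (kept["isi_s"] < ISI_MAX)
                if len(kept) else np.zeros(0, bool))
    n_excluded = int(len(kept) - in_range.sum()) if len(kept) else 0
    kept = kept[in_range] if len(kept) else kept

    heights: dict[tuple[float, str], np.ndarray] = {}
    retained: dict[tuple[float, str], int] = {}
    for c in protocol.coherence_levels:
        T = events.stim_time.get(c, 0.0)
        for label in LABELS:
            if len(kept):
                sel = kept[(kept["coherence"] == c) & (kept["label"] == label)]
                counts, _ = np.histogram(sel["isi_s"].to_numpy(), bins=BIN_EDGES)
            else:
                counts = np.zeros(len(BIN_EDGES) - 1)
            retained[(c, label)] = int(counts.sum())
            if T > 0:
                h = counts / T
                if convention == "density":
                    h = h / BIN_WIDTH
            else:
                h = np.zeros_like(counts, dtype=float)
            heights[(c, label)] = h.astype(float)
    return LabeledISIHistograms(
        bin_edges=BIN_EDGES.copy(), heights=heights,
        total_time={c: events.stim_time.get(c, 0.0)
                    for c in protocol.coherence_levels},
        convention=convention, n_retained=retained, n_excluded=n_excluded)


def simulate_histograms(params: DDMParameters, protocol: StimulusProtocol,
                        config: SimulationConfig,
                        convention: str = "density") -> LabeledISIHistograms:
    """Simulate and histogram in one pass on raw event arrays.

    Produces bit-identical histograms to
    ``isi_histograms(simulate(params, protocol, config))`` (tested)
    while skipping the event-table construction — the hot path inside
    optimization and validation loops, where only the histograms are
    needed.
    """
    if convention not in ("density", "per_bin"):
        raise ValueError(f"unknown height convention {convention!r}")
    records, stim_time = _simulate_sessions(params, protocol, config)
    heights: dict[tuple[float, str], np.ndarray] = {}
    retained: dict[tuple[float, str], int] = {}
    n_bins = len(BIN_EDGES) - 1
    n_excluded = 0
    by_coh = {rec["coherence"]: rec for rec in records}
    for c in protocol.coherence_levels:
        T = stim_time.get(c, 0.0)
        counts = {label: np.zeros(n_bins) for label in LABELS}
        rec = by_coh.get(c)
        if rec is not None and len(rec["t"]):
            keep = ((rec["phase"] == _PHASE_STIM)
                    & (rec["t_in_segment"] >= protocol.exclusion_window)
                    & ~rec["first"])
            isi = rec["isi"][keep]
            sign = rec["sign"][keep]
            in_range = (isi >= 0) & (isi < ISI_MAX)
            n_excluded += int(keep.sum() - in_range.sum())
            for label, s in (("correct", 1), ("incorrect", -1)):
                counts[label], _ = np.histogram(
                    isi[in_range & (sign == s)], bins=BIN_EDGES)
        for label in LABELS:
            retained[(c, label)] = int(counts[label].sum())
            if T > 0:
                h = counts[label] / T
                if convention == "density":
                    h = h / BIN_WIDTH
            else:
                h = np.zeros(n_bins)
            heights[(c, label)] = h.astype(float)
    return LabeledISIHistograms(
        bin_edges=BIN_EDGES.copy(), heights=heights,
        total_time={c: stim_time.get(c, 0.0)
                    for c in protocol.coherence_levels},
        convention=convention, n_retained=retained, n_excluded=n_excluded)


def _check_hist_vector(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, float)
    if np.any(p < 0):
        raise ValueError(f"{name} has negative bins")
    return p


def _smoothed_log_ratio(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """ln(P1/P2) with zero denominator bins clamped at a small epsilon.

    The clamp is eps = 1e-6 * max(1, max(P1)), which keeps the
    zero-at-equality property (equal vectors never hit the clamp) while
    bounding the contribution of any single undefined bin.
    """
    eps = 1e-6 * max(1.0, float(np.max(p1, initial=0.0)))
    denom = np.maximum(p2, eps)
    num = np.maximum(p1, eps)  # irrelevant where the 0*ln(.) := 0 rule applies
    return np.log(num / denom)


def dkl(p1, p2) -> float:
    """Kullback-Leibler divergence sum P1 ln(P1/P2) over histogram bins.

    Bins with P1 = 0 contribute 0; zero P2 bins are epsilon-clamped.
    """
    p1 = _check_hist_vector(p1, "P1")
    p2 = _check_hist_vector(p2, "P2")
    if p1.shape != p2.shape:
        raise ValueError("histogram vectors must have equal length")
    log_ratio = _smoothed_log_ratio(p1, p2)
    return float(np.sum(np.where(p1 > 0, p1 * log_ratio, 0.0)))


def dkl_star(p0, p1, p2) -> float:
    """Weighted KL divergence sum P0 P1 ln(P1/P2).

    ``p0`` acts as a bin-wise weight (in practice the target histogram),
    so disagreement at tall target bins dominates the loss.
    """
    p0 = _check_hist_vector(p0, "P0")
    p1 = _check_hist_vector(p1, "P1")
    p2 = _check_hist_vector(p2, "P2")
    if not p0.shape == p1.shape == p2.shape:
        raise ValueError("histogram vectors must have equal length")
    log_ratio = _smoothed_log_ratio(p1, p2)
    w = p0 * p1
    return float(np.sum(np.where(w > 0, w * log_ratio, 0.0)))


def pair_distance(p_target, p_model, metric: str = "dkl_star") -> float:
    """Symmetrized distance of one histogram pair: max of both orientations."""
    if metric == "dkl_star":
        d0 = dkl_star(p_target, p_target, p_model)
        d1 = dkl_star(p_target, p_model, p_target)
    elif metric == "dkl":
        d0 = dkl(p_target, p_model)
        d1 = dkl(p_model, p_target)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return max(d0, d1)


def total_loss(target: LabeledISIHistograms, model: LabeledISIHistograms,
               metric: str = "dkl_star") -> float:
    """Mean pair distance over the eight (coherence, label) histograms.

    Pairs that are empty in both sets contribute 0 (they carry no
    information either way).  Raises if the two sets were built over
    different coherence levels.
    """
    if target.coherences != model.coherences:
        raise ValueError(
            f"coherence sets differ: {target.coherences} vs {model.coherences}")
    total = 0.0
    n_pairs = 0
    for key in target.pairs():
        pt = target.heights[key]
        pm = model.heights[key]
        n_pairs += 1
        if not np.any(pt) and not np.any(pm):
            continue
        total += pair_distance(pt, pm, metric=metric)
    return total / n_pairs if n_pairs else 0.0
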