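"""Rejection sampling of biologically plausible target models.

Random parameter sets drawn uniformly over the search space are mostly
useless as validation targets — many never cross a bound or produce
machine-gun event trains.  A candidate is accepted only if the labeled
ISI histograms it generates satisfy the acceptability criteria:
minimum event rates that scale with coherence, enough activity at full
coherence, performance that grows with coherence (in either the
correct- or incorrect-dominant direction), and no histogram bin
exceeding a ceiling that would indicate unnaturally regular swimming.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .ddm_core import (DEFAULT_COHERENCES, DDMParameters, SimulationConfig,
                       SimulationDivergenceError, StimulusProtocol, simulate)
from .objective import (BIN_WIDTH, LabeledISIHistograms, isi_histograms,
                        simulate_histograms)

__all__ = [
    "SearchSpace",
    "ModelLibrary",
    "sample_parameters",
    "check_acceptability",
    "build_library",
]

PARAM_NAMES = ("sigma", "mu", "lam", "r", "delta")


@dataclass(frozen=True)
class SearchSpace:
    """Closed per-parameter intervals searched by sampling and fitting.

    Defaults admit event rates of roughly 0.1-3 swims/s at the tested
    coherences with B = 1 — the experimentally observed regime — without
    pinning the reset or delay at their limits.
    """

    sigma: tuple[float, float] = (0.05, 3.0)
    mu: tuple[float, float] = (0.0, 8.0)
    lam: tuple[float, float] = (-8.0, 8.0)
    r: tuple[float, float] = (0.0, 1.0)
    delta: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} interval must have m_min < m_max")
        if self.sigma[0] < 0:
            raise ValueError("sigma interval must lie in [0, inf)")
        if self.delta[0] < 0:
            raise ValueError("delta interval must lie in [0, inf)")
        if not (0.0 <= self.r[0] and self.r[1] <= 1.0):
            raise ValueError("r interval must lie within [0, 1]")

    def bounds(self, name: str) -> tuple[float, float]:
        return getattr(self, name)

    def width(self, name: str) -> float:
        lo, hi = getattr(self, name)
        return hi - lo

    def contains(self, name: str, value: float) -> bool:
        lo, hi = getattr(self, name)
        return lo <= value <= hi

    def as_dict(self) -> dict:
        return {name: list(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "SearchSpace":
        return cls(**{name: tuple(d[name]) for name in PARAM_NAMES if name in d})


@dataclass
class LibraryEntry:
    params: DDMParameters
    seed: int
    histograms: LabeledISIHistograms


@dataclass
class ModelLibrary:
    """Accepted target models with their seeds and reference histograms."""

    entries: list[LibraryEntry]
    space: SearchSpace
    n_candidates: int
    duration: float
    protocol: StimulusProtocol
    dt: float = 0.01

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def acceptance_rate(self) -> float:
        return len(self.entries) / self.n_candidates if self.n_candidates else 0.0

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps({"params": e.params.as_dict(),
                                     "seed": e.seed}) + "\n")


def sample_parameters(space: SearchSpace, rng: np.random.Generator) -> DDMParameters:
    """Draw each parameter independently and uniformly over its interval."""
    draws = {name: float(rng.uniform(*space.bounds(name))) for name in PARAM_NAMES}
    return DDMParameters(**draws)


def check_acceptability(hists: LabeledISIHistograms,
                        activity_floor: float = 0.005,
                        full_coh_floor: float = 0.01,
                        growth_factor: float = 1.33,
                        dominance_factor: float = 3.33,
                        max_bin_height: float = 0.15,
                        ) -> tuple[bool, list[str]]:
    """Evaluate the seven acceptability inequalities on one histogram set.

    Areas A(c) are in-range event rates (events/s); the bin-height
    ceiling is applied to heights in per-bin count/T units (under the
    density storage convention heights are divided by the bin width
    first), so the verdict does not depend on the storage convention.
    Returns (accepted, list of failed criterion names).
    """
    required = set(DEFAULT_COHERENCES)
    if not required <= set(hists.coherences):
        missing = required - set(hists.coherences)
        raise ValueError(f"histograms missing coherence levels {sorted(missing)}")

    failed: list[str] = []
    a_cor = {c: hists.area(c, "correct") for c in DEFAULT_COHERENCES}
    a_inc = {c: hists.area(c, "incorrect") for c in DEFAULT_COHERENCES}

    for c in DEFAULT_COHERENCES:
        if a_cor[c] < activity_floor * c:
            failed.append(f"A_correct({c}) >= {activity_floor}*c")
        if a_inc[c] < activity_floor * (1.0 - c):
            failed.append(f"A_incorrect({c}) >= {activity_floor}*(1-c)")

    if not (a_cor[1.0] > full_coh_floor or a_inc[1.0] > full_coh_floor):
        failed.append(f"A_correct(1) > {full_coh_floor} or A_incorrect(1) > {full_coh_floor}")

    correct_dominant = (a_cor[1.0] > growth_factor * a_cor[0.0]
                        and a_cor[1.0] > dominance_factor * a_inc[1.0])
    incorrect_dominant = (a_inc[1.0] > growth_factor * a_inc[0.0]
                          and a_inc[1.0] > dominance_factor * a_cor[1.0])
    if not (correct_dominant or incorrect_dominant):
        failed.append("coherence growth with label dominance")

    for c in DEFAULT_COHERENCES:
        for label in ("correct", "incorrect"):
            if np.max(hists.per_bin_heights(c, label), initial=0.0) > max_bin_height:
                failed.append(f"h_{label}(tau,{c}) <= {max_bin_height}")

    return (len(failed) == 0, failed)


def build_library(space: SearchSpace, n_models: int = 100,
                  duration: float = 900.0, seed: int = 0,
                  protocol: StimulusProtocol | None = None,
                  dt: float = 0.01,
                  convention: str = "density",
                  max_candidates: int = 100_000,
                  min_rate_candidates: int = 100_000,
                  ) -> ModelLibrary:
    """Rejection-sample ``n_models`` accepted models (deterministic in seed).

    Candidates are simulated as continuous per-coherence segments of
    ``duration`` seconds each.  Aborts with a failure-mode tally if the
    acceptance rate collapses (a mis-scaled search space).
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    protocol = protocol or StimulusProtocol(mode="continuous")
    root = np.random.SeedSequence(seed)
    sampler = np.random.default_rng(root.spawn(1)[0])
    entries: list[LibraryEntry] = []
    n_candidates = 0
    failure_tally: dict[str, int] = {}
    while len(entries) < n_models:
        n_candidates += 1
        if n_candidates > max_candidates or (
                n_candidates >= min_rate_candidates
                and len(entries) / n_candidates < 1e-4):
            raise RuntimeError(
                "acceptance rate collapsed after "
                f"{n_candidates} candidates; failure tally: {failure_tally}")
        params = sample_parameters(space, sampler)
        sim_seed = int(sampler.integers(0, 2**31 - 1))
        config = SimulationConfig(dt=dt, seed=sim_seed, duration=duration)
        try:
            hists = simulate_histograms(params, protocol, config,
                                        convention=convention)
        except SimulationDivergenceError:
            failure_tally["diverged"] = failure_tally.get("diverged", 0) + 1
            continue
        ok, failed = check_acceptability(hists)
        if ok:
            entries.append(LibraryEntry(params=params, seed=sim_seed,
                                        histograms=hists))
        else:
            for f in failed:
                failure_tally[f] = failure_tally.get(f, 0) + 1
    return ModelLibrary(entries=entries, space=space,
                        n_candidates=n_candidates, duration=duration,
                        protocol=protocol, dt=dt)
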