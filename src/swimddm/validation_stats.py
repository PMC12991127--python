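"""Validation experiments and statistical utilities.

Covers the synthetic-validation suite around the fitting pipeline —
parameter-perturbation sensitivity, dataset-duration sweep, histogram
noise injection — together with the nonparametric statistics used to
compare groups of fitted parameters (pooled bootstrap median test,
bootstrap median confidence interval, coefficient of variation, ordinal
group trend regression) and the synthetic-data generators that emulate
the experimental recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress, mannwhitneyu

from .ddm_core import (DDMParameters, EventSeries, SimulationConfig,
                       StimulusProtocol, simulate)
from .inference import fit, recovery_errors
from .model_library import PARAM_NAMES, ModelLibrary, SearchSpace, sample_parameters
from .objective import (LabeledISIHistograms, isi_histograms,
                        simulate_histograms, total_loss)

__all__ = [
    "PerturbationResult",
    "sensitivity_analysis",
    "significance_onset",
    "duration_sweep",
    "add_histogram_noise",
    "bootstrap_median_test",
    "bootstrap_median_ci",
    "coefficient_of_variation",
    "group_trend",
    "gen_orientation_trace",
    "gen_target_dataset",
    "GroupStats",
    "group_stats",
]

DEFAULT_PERTURBATION_LEVELS = (-0.50, -0.25, -0.10, -0.05,
                               0.05, 0.10, 0.25, 0.50)


def _seed_from(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PerturbationResult:
    """Sensitivity of the loss to perturbing one parameter.

    ``losses[level]`` holds one loss per evaluated model (perturbed
    simulation vs the model's own reference simulation); ``baseline``
    holds the unperturbed re-simulation noise floor.  ``p_values`` are
    two-sided Mann-Whitney U results per signed level against the
    baseline; ``pooled_p_values`` pool the +level and -level samples of
    one magnitude, matching how onsets are reported.
    """

    parameter: str
    levels: tuple[float, ...]
    losses: dict[float, list[float]] = field(default_factory=dict)
    skipped: dict[float, int] = field(default_factory=dict)
    baseline: list[float] = field(default_factory=list)
    p_values: dict[float, float] = field(default_factory=dict)
    pooled_p_values: dict[float, float] = field(default_factory=dict)


def _mwu_p(sample, baseline) -> float:
    if len(sample) == 0 or len(baseline) == 0:
        return float("nan")
    return float(mannwhitneyu(sample, baseline, alternative="two-sided").pvalue)


def sensitivity_analysis(library: ModelLibrary,
                         levels=DEFAULT_PERTURBATION_LEVELS,
                         parameters=PARAM_NAMES,
                         duration: float | None = None,
                         seed: int = 0, dt: float = 0.01,
                         ) -> list[PerturbationResult]:
    """Loss impact of perturbing each parameter independently.

    For each accepted model: simulate a reference dataset and an
    independent unperturbed dataset (their loss is the noise-floor
    baseline); then, for each parameter and signed perturbation level
    (a fraction of that parameter's search-range width), simulate the
    perturbed model and measure its loss against the reference.  Models
    whose perturbed value exits the search space are skipped at that
    level, not clamped.
    """
    if any(abs(l) > 0.5 for l in levels):
        raise ValueError("perturbation levels must lie within +-50%")
    space = library.space
    protocol = library.protocol
    duration = duration if duration is not None else library.duration
    root = np.random.SeedSequence(seed)

    results = [PerturbationResult(parameter=p, levels=tuple(levels))
               for p in parameters]
    for res in results:
        for level in levels:
            res.losses[level] = []
            res.skipped[level] = 0

    for mi, entry in enumerate(library.entries):
        model_seq = np.random.SeedSequence(entropy=root.entropy,
                                           spawn_key=(mi,))
        ref_seed, base_seed = (_seed_from(np.random.SeedSequence(
            entropy=model_seq.entropy, spawn_key=model_seq.spawn_key + (k,)))
            for k in (0, 1))
        ref = simulate_histograms(
            entry.params, protocol,
            SimulationConfig(dt=dt, seed=ref_seed, duration=duration))
        base = simulate_histograms(
            entry.params, protocol,
            SimulationConfig(dt=dt, seed=base_seed, duration=duration))
        baseline_loss = total_loss(ref, base)
        for res in results:
            res.baseline.append(baseline_loss)
            width = space.width(res.parameter)
            value = entry.params.as_dict()[res.parameter]
            for li, level in enumerate(levels):
                perturbed_value = value + level * width
                if not space.contains(res.parameter, perturbed_value):
                    res.skipped[level] += 1
                    continue
                pert_params = entry.params.replace(
                    **{res.parameter: perturbed_value})
                pert_seed = _seed_from(np.random.SeedSequence(
                    entropy=model_seq.entropy,
                    spawn_key=model_seq.spawn_key + (100 + li,
                                                     PARAM_NAMES.index(res.parameter))))
                pert = simulate_histograms(
                    pert_params, protocol,
                    SimulationConfig(dt=dt, seed=pert_seed, duration=duration))
                res.losses[level].append(total_loss(ref, pert))

    for res in results:
        for level in levels:
            res.p_values[level] = _mwu_p(res.losses[level], res.baseline)
        for mag in sorted({abs(l) for l in levels}):
            pooled = res.losses.get(mag, []) + res.losses.get(-mag, [])
            res.pooled_p_values[mag] = _mwu_p(pooled, res.baseline)
    return results


def significance_onset(result: PerturbationResult,
                       alpha: float = 0.05) -> float | None:
    """Smallest perturbation magnitude whose pooled loss distribution
    differs from the noise floor (two-sided Mann-Whitney U, level
    ``alpha``); None if no tested magnitude reaches significance."""
    for mag in sorted(result.pooled_p_values):
        p = result.pooled_p_values[mag]
        if np.isfinite(p) and p < alpha:
            return mag
    return None


def duration_sweep(library: ModelLibrary, durations,
                   seed: int = 0, fit_kwargs: dict | None = None,
                   n_random_per_model: int = 20) -> pd.DataFrame:
    """Recovery quality as a function of dataset duration per coherence.

    For every duration and library model: generate a fresh target of
    that duration, fit it, and record the five per-parameter normalized
    recovery errors; the non-optimized baseline draws a uniform-random
    parameter set per model instead of fitting (expected per-parameter
    error 1/3 under a uniform draw).  Each duration row carries the
    pooled fitted and random error lists (5 values per fit) and the
    two-sided Mann-Whitney U p-value between them; pooling across
    parameters gives the test usable power at small library sizes, and
    the baseline — being free — uses ``n_random_per_model`` draws per
    model so its error distribution is well resolved.
    """
    fit_kwargs = dict(fit_kwargs or {})
    rows = []
    root = np.random.SeedSequence(seed)
    for di, duration in enumerate(durations):
        fitted_errors, random_errors = [], []
        for mi, entry in enumerate(library.entries):
            seq = np.random.SeedSequence(entropy=root.entropy,
                                         spawn_key=(di, mi))
            tgt_seed, fit_seed, rand_seed = (
                _seed_from(np.random.SeedSequence(
                    entropy=seq.entropy, spawn_key=seq.spawn_key + (k,)))
                for k in (0, 1, 2))
            _, target = gen_target_dataset(entry.params, library.protocol,
                                           duration=duration, seed=tgt_seed,
                                           dt=library.dt)
            result = fit(target, library.space, seed=fit_seed,
                         protocol=library.protocol, **fit_kwargs)
            errs = recovery_errors(result.best_params, entry.params,
                                   library.space)
            fitted_errors.extend(float(v) for v in errs.values())
            rand_rng = np.random.default_rng(rand_seed)
            for _ in range(n_random_per_model):
                rand_params = sample_parameters(library.space, rand_rng)
                rerrs = recovery_errors(rand_params, entry.params,
                                        library.space)
                random_errors.extend(float(v) for v in rerrs.values())
        rows.append({
            "duration_s": duration,
            "fitted_errors": fitted_errors,
            "random_errors": random_errors,
            "median_fitted_error": float(np.median(fitted_errors))
            if fitted_errors else float("nan"),
            "median_random_error": float(np.median(random_errors))
            if random_errors else float("nan"),
            "p_fitted_vs_random": _mwu_p(fitted_errors, random_errors),
        })
    return pd.DataFrame(rows)


def add_histogram_noise(hists: LabeledISIHistograms, variance: float,
                        rng: np.random.Generator) -> LabeledISIHistograms:
    """Add i.i.d. Gaussian noise N(0, variance) to every histogram bin.

    Heights are rates and cannot be negative, so noisy bins are clipped
    at 0; the clipped fraction is recorded on the returned object.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    sd = float(np.sqrt(variance))
    new_heights = {}
    n_bins = 0
    n_clipped = 0
    for key, h in hists.heights.items():
        noisy = h + rng.normal(0.0, sd, size=h.shape) if sd > 0 else h.copy()
        n_bins += h.size
        n_clipped += int(np.sum(noisy < 0))
        new_heights[key] = np.maximum(noisy, 0.0)
    return LabeledISIHistograms(
        bin_edges=hists.bin_edges.copy(), heights=new_heights,
        total_time=dict(hists.total_time), convention=hists.convention,
        n_retained=dict(hists.n_retained), n_excluded=hists.n_excluded,
        clip_fraction=n_clipped / n_bins if n_bins else 0.0)


def bootstrap_median_test(group_a, group_b, n_boot: int = 10_000,
                          rng: np.random.Generator | None = None) -> float:
    """Bootstrap test of the median difference between two groups.

    The null of no group difference is imposed by translation: each
    group is centered on its own median, then resampled with
    replacement from itself at its original size.  The p-value is the
    fraction of resample pairs whose absolute median distance matches
    or exceeds the observed one.  (Resampling the pooled data instead
    is badly conservative for medians at small n.)
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    rng = rng or np.random.default_rng()
    observed = abs(np.median(a) - np.median(b))
    a_null = a - np.median(a)
    b_null = b - np.median(b)
    ra = rng.choice(a_null, size=(n_boot, len(a)), replace=True)
    rb = rng.choice(b_null, size=(n_boot, len(b)), replace=True)
    boot = np.abs(np.median(ra, axis=1) - np.median(rb, axis=1))
    return float(np.mean(boot >= observed))


def bootstrap_median_ci(values, n_boot: int = 10_000,
                        rng: np.random.Generator | None = None,
                        lower_q: float = 5.0, upper_q: float = 95.0,
                        ) -> tuple[float, float]:
    """5th-95th percentile interval of the bootstrapped sample median."""
    v = np.asarray(values, float)
    if len(v) == 0:
        raise ValueError("values must be nonempty")
    rng = rng or np.random.default_rng()
    boot = np.median(rng.choice(v, size=(n_boot, len(v)), replace=True), axis=1)
    return (float(np.percentile(boot, lower_q)),
            float(np.percentile(boot, upper_q)))


def coefficient_of_variation(values) -> float:
    """Coefficient of variation, (sample sd / mean) * 100, in percent."""
    v = np.asarray(values, float)
    mean = v.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    sd = v.std(ddof=1) if len(v) > 1 else 0.0
    return float(sd / mean * 100.0)


def group_trend(x, y):
    """OLS trend of parameter estimates over an ordinal group variable.

    Returns the full scipy ``linregress`` result (slope, intercept,
    rvalue, two-sided slope p-value, stderr).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct group values")
    return linregress(x, y)


@dataclass
class GroupStats:
    """Per-group parameter summary with bootstrap CIs and pairwise tests."""

    groups: list
    medians: dict
    intervals: dict  # group -> (5th, 95th) bootstrap median CI
    pairwise_p: dict  # (group_a, group_b) -> p
    bonferroni_alpha: float


def group_stats(samples: dict, n_boot: int = 10_000, alpha: float = 0.05,
                seed: int = 0) -> GroupStats:
    """Bootstrap medians, CIs and Bonferroni-corrected pairwise tests
    over a mapping group-label -> list of per-individual estimates."""
    rng = np.random.default_rng(seed)
    groups = list(samples)
    medians = {g: float(np.median(samples[g])) for g in groups}
    intervals = {g: bootstrap_median_ci(samples[g], n_boot=n_boot, rng=rng)
                 for g in groups}
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    pairwise = {(a, b): bootstrap_median_test(samples[a], samples[b],
                                              n_boot=n_boot, rng=rng)
                for a, b in pairs}
    corrected = alpha / len(pairs) if pairs else alpha
    return GroupStats(groups=groups, medians=medians, intervals=intervals,
                      pairwise_p=pairwise, bonferroni_alpha=corrected)


def gen_orientation_trace(bouts, duration: float, frame_rate: float = 90.0,
                          noise_sd: float = 0.1, seed: int = 0,
                          baseline_deg: float = 0.0,
                          direction: str = "left", coherence: float = 1.0,
                          phase: str = "stimulus", trial_id: int = 0,
                          ) -> pd.DataFrame:
    """Synthesize an orientation trace with known discrete turn bouts.

    ``bouts`` is a list of (start_s, angle_deg, duration_s); each bout
    adds ``angle_deg`` to the heading through a smooth raised-cosine
    ramp.  Per-frame Gaussian jitter of ``noise_sd`` degrees emulates
    tracking noise below the detection threshold.  Bouts must not
    overlap.
    """
    bouts = sorted(bouts, key=lambda b: b[0])
    for (s0, _, d0), (s1, _, _) in zip(bouts, bouts[1:]):
        if s0 + d0 > s1:
            raise ValueError(f"overlapping bouts at {s0:.3f}s and {s1:.3f}s")
    n = int(round(duration * frame_rate))
    t = np.arange(n) / frame_rate
    orientation = np.full(n, baseline_deg, float)
    for start, angle, dur in bouts:
        ramp = (t >= start) & (t < start + dur)
        orientation[ramp] += angle * 0.5 * (
            1 - np.cos(np.pi * (t[ramp] - start) / dur))
        orientation[t >= start + dur] += angle
    rng = np.random.default_rng(seed)
    orientation = orientation + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({
        "time_s": t,
        "orientation_deg": orientation,
        "coherence": coherence,
        "direction": direction,
        "phase": phase,
        "trial_id": trial_id,
    })


def gen_target_dataset(params: DDMParameters,
                       protocol: StimulusProtocol | None = None,
                       duration: float = 900.0, seed: int = 0,
                       dt: float = 0.01, convention: str = "density",
                       ) -> tuple[EventSeries, LabeledISIHistograms]:
    """Simulate one model and histogram it: the canonical entry point
    for recovery experiments (900 s per coherence = 3,600 s total at
    the default four coherence levels)."""
    protocol = protocol or StimulusProtocol(mode="continuous")
    config = SimulationConfig(dt=dt, seed=seed, duration=duration)
    series = simulate(params, protocol, config)
    hists = isi_histograms(series, protocol, convention=convention)
    return series, hists
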