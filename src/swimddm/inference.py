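"""Bayesian-optimization fitting of the decision model to ISI histograms.

The loss surface is an expensive, noisy black box: every evaluation
re-simulates the model at all coherence levels and measures the
weighted-KL distance of the resulting histograms to the target.  A
Gaussian-process surrogate with a Matern(5/2) kernel is fit to all
evaluations after ``n_init`` uniform-random probes; each subsequent
proposal maximizes an acquisition function drawn at random from
{lower confidence bound, expected improvement, probability of
improvement} (a hedged portfolio) over a cloud of random and
best-point-jittered candidates.  Simulation noise is controlled by
deriving one evaluation seed per call index from the master seed, so a
whole fit is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (ConstantKernel, Matern,
                                              WhiteKernel)

from .ddm_core import (DDMParameters, SimulationConfig,
                       SimulationDivergenceError, StimulusProtocol, simulate)
from .model_library import PARAM_NAMES, SearchSpace
from .objective import LabeledISIHistograms, simulate_histograms, total_loss

__all__ = [
    "OptimizationTrace",
    "FitResult",
    "fit",
    "estimation_error",
    "estimation_distance",
    "recovery_errors",
    "repeat_fit",
]

_ACQUISITIONS = ("lcb", "ei", "pi")


@dataclass
class OptimizationTrace:
    """Per-iteration evaluated parameter vectors and losses."""

    params: np.ndarray  # (budget, 5) in native units, PARAM_NAMES order
    losses: np.ndarray  # (budget,)
    n_init: int
    seed: int

    def __len__(self) -> int:
        return len(self.losses)

    @property
    def best_so_far(self) -> np.ndarray:
        return np.minimum.accumulate(self.losses)

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.params, columns=list(PARAM_NAMES))
        df["loss"] = self.losses
        df["best_so_far"] = self.best_so_far
        return df


@dataclass
class FitResult:
    best_params: DDMParameters
    best_loss: float
    trace: OptimizationTrace
    settings: dict = field(default_factory=dict)


def _make_evaluator(target: LabeledISIHistograms, protocol: StimulusProtocol,
                    duration: float | None, n_trials: int | None,
                    dt: float, metric: str, root_seed: int):
    """Build the per-call loss evaluator with seeds derived per call index."""
    seed_seq = np.random.SeedSequence(root_seed)

    def evaluate(vec: np.ndarray, call_index: int) -> float:
        params = DDMParameters(**dict(zip(PARAM_NAMES, (float(v) for v in vec))))
        # common random numbers per call index: re-proposals at the same
        # index see the same noise stream
        call_seed = int(np.random.SeedSequence(
            entropy=seed_seq.entropy, spawn_key=(call_index,)
        ).generate_state(1)[0] % (2**31 - 1))
        config = SimulationConfig(dt=dt, seed=call_seed, duration=duration,
                                  n_trials=n_trials)
        try:
            model_h = simulate_histograms(params, protocol, config,
                                          convention=target.convention)
        except SimulationDivergenceError:
            return math.inf
        return total_loss(target, model_h, metric=metric)

    return evaluate


def _acquisition_values(name: str, mu: np.ndarray, sd: np.ndarray,
                        y_best: float) -> np.ndarray:
    """Larger is better for all three acquisition flavours."""
    sd = np.maximum(sd, 1e-12)
    if name == "lcb":
        return -(mu - 1.96 * sd)
    z = (y_best - mu) / sd
    if name == "ei":
        return sd * (z * norm.cdf(z) + norm.pdf(z))
    return norm.cdf(z)  # pi


def fit(target: LabeledISIHistograms, space: SearchSpace,
        budget: int = 1500, n_init: int = 100,
        trials_per_eval: int = 2000, seed: int = 0,
        protocol: StimulusProtocol | None = None,
        duration_per_eval: float | None = None,
        dt: float = 0.01, metric: str = "dkl_star",
        optimizer: str = "gp", n_candidates: int = 512,
        gp_refit_every: int = 5) -> FitResult:
    """Minimize the histogram loss over the 5-parameter search space.

    Each evaluation simulates ``trials_per_eval`` repetitions of the
    30 s stimulation window per coherence; when the protocol is
    continuous that amounts to ``trials_per_eval * stim_dur`` seconds of
    stimulation per coherence (override with ``duration_per_eval``).
    ``optimizer="random"`` replaces the GP surrogate by pure random
    search at the same budget (a correctness baseline; the GP only buys
    efficiency).
    """
    if budget <= n_init and optimizer == "gp":
        raise ValueError("budget must exceed n_init")
    protocol = protocol or StimulusProtocol(mode="continuous")
    if protocol.mode == "continuous":
        duration = (duration_per_eval if duration_per_eval is not None
                    else trials_per_eval * protocol.stim_dur)
        n_trials = None
    else:
        duration = None
        n_trials = trials_per_eval

    lows = np.array([space.bounds(n)[0] for n in PARAM_NAMES])
    highs = np.array([space.bounds(n)[1] for n in PARAM_NAMES])
    widths = highs - lows

    evaluate = _make_evaluator(target, protocol, duration, n_trials, dt,
                               metric, seed)
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(0xB0,)))

    X = np.empty((budget, 5))  # unit cube
    y = np.full(budget, np.nan)

    def run_one(j: int, unit_vec: np.ndarray) -> None:
        X[j] = unit_vec
        y[j] = evaluate(lows + unit_vec * widths, j)

    n_random = budget if optimizer == "random" else n_init
    for j in range(min(n_random, budget)):
        run_one(j, rng.uniform(size=5))

    if optimizer == "gp":
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * Matern(length_scale=np.full(5, 0.3),
                           length_scale_bounds=(1e-2, 1e2), nu=2.5)
                  + WhiteKernel(1e-2, (1e-8, 1e1)))
        tuned_kernel = None
        for j in range(n_init, budget):
            finite = np.isfinite(y[:j])
            if not finite.any():
                raise RuntimeError("all initial evaluations were non-finite")
            worst = float(y[:j][finite].max())
            y_raw = np.where(finite, y[:j], worst + abs(worst) + 1.0)
            # the loss is positive with a dynamic range of several orders
            # of magnitude; the GP models its log
            y_fit = np.log(np.maximum(y_raw, 1e-12))
            # re-optimize GP hyperparameters only every few iterations;
            # in between, refit with the last tuned kernel held fixed
            retune = tuned_kernel is None or (j - n_init) % gp_refit_every == 0
            gp = GaussianProcessRegressor(
                kernel=kernel if retune else tuned_kernel,
                optimizer="fmin_l_bfgs_b" if retune else None,
                normalize_y=True, alpha=1e-10, n_restarts_optimizer=0,
                random_state=int(rng.integers(2**31 - 1)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(X[:j], y_fit)
            if retune:
                tuned_kernel = gp.kernel_
            # incumbent = best GP-denoised mean at observed points (the raw
            # minimum of a noisy loss is biased low and starves EI/PI)
            mu_obs = gp.predict(X[:j])
            best_x = X[:j][int(np.argmin(mu_obs))]
            cand = [rng.uniform(size=(n_candidates, 5))]
            for scale in (0.02, 0.05, 0.1):
                cand.append(np.clip(
                    best_x + rng.normal(0, scale, size=(n_candidates // 4, 5)),
                    0.0, 1.0))
            cand = np.vstack(cand)
            mu, sd = gp.predict(cand, return_std=True)
            acq = _ACQUISITIONS[rng.integers(len(_ACQUISITIONS))]
            vals = _acquisition_values(acq, mu, sd, float(np.min(mu_obs)))
            run_one(j, cand[int(np.argmax(vals))])
    elif optimizer != "random":
        raise ValueError(f"unknown optimizer {optimizer!r}")

    finite = np.isfinite(y)
    if not finite.any():
        raise RuntimeError("all evaluations were non-finite")
    best_j = int(np.nanargmin(np.where(finite, y, np.nan)))
    best_vec = lows + X[best_j] * widths
    trace = OptimizationTrace(params=lows + X * widths, losses=y,
                              n_init=n_init, seed=seed)
    best = DDMParameters(**dict(zip(PARAM_NAMES, (float(v) for v in best_vec))))
    return FitResult(
        best_params=best, best_loss=float(y[best_j]), trace=trace,
        settings={"budget": budget, "n_init": n_init,
                  "trials_per_eval": trials_per_eval,
                  "duration_per_eval": duration, "dt": dt, "metric": metric,
                  "optimizer": optimizer, "seed": seed,
                  "protocol": protocol.as_dict(),
                  "acquisition": "hedge(lcb,ei,pi)",
                  "kernel": "C*Matern(nu=2.5)+White"})


def estimation_error(p_j: float, p_target: float, space: SearchSpace,
                     name: str) -> float:
    """Normalized recovery error e(j) = |p(j) - p_target| / range width."""
    width = space.width(name)
    if width == 0:
        raise ValueError(f"zero-width search range for {name}")
    return abs(p_j - p_target) / width


def estimation_distance(p_j: float, p_final: float, space: SearchSpace,
                        name: str) -> float:
    """Normalized distance to the final estimate, d(j), for real data."""
    return estimation_error(p_j, p_final, space, name)


def recovery_errors(estimated: DDMParameters, target: DDMParameters,
                    space: SearchSpace) -> dict[str, float]:
    """Per-parameter e(final) of one fit against a known target model."""
    est = estimated.as_dict()
    tgt = target.as_dict()
    return {name: estimation_error(est[name], tgt[name], space, name)
            for name in PARAM_NAMES}


@dataclass
class RepeatFitSummary:
    medians: dict[str, float]
    intervals: dict[str, tuple[float, float]]  # 10th-90th percentile
    results: list[FitResult]


def repeat_fit(target: LabeledISIHistograms, space: SearchSpace,
               n_runs: int = 10, seed: int = 0, **fit_kwargs) -> RepeatFitSummary:
    """Repeated fits with distinct seeds; per-parameter medians and
    10th-90th percentile intervals of the final estimates."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    run_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                 for s in np.random.SeedSequence(seed).spawn(n_runs)]
    results = [fit(target, space, seed=s, **fit_kwargs) for s in run_seeds]
    finals = {name: np.array([r.best_params.as_dict()[name] for r in results])
              for name in PARAM_NAMES}
    medians = {name: float(np.median(v)) for name, v in finals.items()}
    intervals = {name: (float(np.percentile(v, 10)), float(np.percentile(v, 90)))
                 for name, v in finals.items()}
    return RepeatFitSummary(medians=medians, intervals=intervals,
                            results=results)
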