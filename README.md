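# swimddm

Drift-diffusion modelling of larval-zebrafish swim decisions: simulate a
bounded, resetting Ornstein–Uhlenbeck decision process, extract swim
events from heading-orientation traces, and infer the five latent model
parameters of individual animals from labeled inter-swim-interval (ISI)
histograms by Bayesian optimization — together with the synthetic
validation suite (model libraries, parameter recovery, sensitivity,
duration and noise robustness) needed to trust such fits.

## Who this is for

Behavioral neuroscientists running random-dot-motion (optomotor) assays
on freely swimming larvae — or any event-based binary decision assay —
who want per-individual estimates of integration parameters rather than
population summary statistics.

## The model

The decision variable `x` integrates motion evidence between absorbing
bounds at ±B (B ≡ 1):

    dx = (μ·f(I) − λ·x) dt + σ dW,       f(I) = √I

* `σ` — diffusion, the stochastic drive (bound-units·s^−1/2)
* `μ` — drift gain on the transformed coherence `I ∈ [0,1]` (s^−1)
* `λ` — leak; negative values are self-reinforcing (s^−1)
* `r` — reset fraction: after a bound hit, `x ← r·sign(x)·B`
* `δ` — post-decision delay during which `x` is frozen (s)

A bound hit is a decision event: `+B` is a correct (motion-following)
turn, `−B` incorrect. Simulated or experimentally recorded events are
binned into eight time-normalized ISI histograms (4 coherences ×
correct/incorrect, 40 bins over [0, 2) s). Model and target histograms
are compared with a weighted Kullback–Leibler divergence

    DKL*(P0, P1, P2) = Σ_n P0(n)·P1(n)·ln(P1(n)/P2(n)),

evaluated in both orientations with the larger value taken per pair and
averaged over the eight pairs; the weighting makes the histogram peak
dominate the loss. Fitting minimizes this loss over the 5-D search
space with a Gaussian-process surrogate (Matern-5/2 kernel, hedged
LCB/EI/PI acquisition).

## Worked example

Draw a biologically plausible target model, simulate 900 s of
stimulation per coherence from it, and recover its latent parameters
from the event histograms alone:

```python
from swimddm import SearchSpace, build_library, fit, recovery_errors

space = SearchSpace()
library = build_library(space, n_models=1, duration=900.0, seed=7)
entry = library.entries[0]
print("true  ", {k: round(v, 3) for k, v in entry.params.as_dict().items()})
print("rates ", {c: round(entry.histograms.area(c, "correct"), 3)
                 for c in (0.0, 0.25, 0.5, 1.0)})

result = fit(entry.histograms, space, budget=300, n_init=100,
             trials_per_eval=300, seed=100)
print("fitted", {k: round(v, 3) for k, v in result.best_params.as_dict().items()})
print("errors", {k: round(v, 3) for k, v in
                 recovery_errors(result.best_params, entry.params, space).items()})
```

prints (about a minute on one CPU)

```
true   {'sigma': 1.658, 'mu': 3.22, 'lam': 5.183, 'r': 0.059, 'delta': 0.578, 'bound': 1.0}
rates  {0.0: 0.211, 0.25: 0.523, 0.5: 0.674, 1.0: 0.828}
fitted {'sigma': 1.748, 'mu': 3.903, 'lam': 6.491, 'r': 0.146, 'delta': 0.433, 'bound': 1.0}
errors {'sigma': 0.031, 'mu': 0.085, 'lam': 0.082, 'r': 0.087, 'delta': 0.145}
```

The `rates` line says the target model swims 0.2–0.8 times per second
depending on coherence — the experimentally observed regime the
library's acceptability criteria enforce. The last line is each
parameter's recovery error normalized by its search-range width: at
this reduced budget (300 loss evaluations, 300 trials each) all five
land within 3–15% of their range; the full-scale setting (1,500
evaluations × 2,000 trials) tightens this further.

A command-line interface mirrors the library
(`swimddm simulate|extract|hist|loss|library|fit|sensitivity`); run
`swimddm --help`.

## Layout

| module | contents |
|---|---|
| `swimddm.ddm_core` | parameter/protocol types, compiled OU event simulator |
| `swimddm.event_processing` | rolling-variance bout detection, labeling, QC filters |
| `swimddm.objective` | labeled ISI histograms, DKL/DKL*, total loss |
| `swimddm.model_library` | search space, acceptability criteria, rejection sampling |
| `swimddm.inference` | GP Bayesian optimization, recovery error metrics |
| `swimddm.validation_stats` | sensitivity/duration/noise suites, bootstrap statistics, generators |

See `docs/methods.md` for the modelling and numerical choices.
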