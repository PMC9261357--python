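# wormspan

Simulation and censoring-aware analysis of *C. elegans* lifespan
experiments, comparing the two experimental designs in common use:

* **TLM** (traditional longitudinal method): a single cohort is scored
  repeatedly — every day or every few days — with dead animals removed at
  each observation;
* **RSM** (replica set method): an age-synchronized population is split
  across replicate plates prepared at the start, and each plate is scored
  exactly once at its scheduled time, then discarded.  Each animal is
  inspected once, so RSM yields *current-status* data.

The package is aimed at worm biologists planning lifespan assays and at
biostatisticians studying the censoring structure of discretely scored
survival experiments.  It answers, by Monte-Carlo simulation against a
known generating model, questions such as: how large is the bias from
analyzing discretely scored deaths with right censoring?  How do the two
designs respond to experimenter error — mis-scoring a decrepit animal,
or killing a fragile one while prodding it?  How much scoring effort
does each design spend to reach a given precision and statistical power?

## The model

Simulated animals draw death times from a parametric survival model by
inverse-transform sampling.  The reference population is logistic,

    S(t) = 1 / (1 + exp((t − μ)/s)),      T(p) = s·ln(1/p − 1) + μ,

with μ = 20 d (mean = median) and shape s = 2 d, typical of wild-type
(N2) animals at 20 °C.  A two-parameter Gompertz model
(T(p) = ln(1 − (β/α)·ln(1−p))/β) and arbitrary mixtures are available
for distribution-mismatch and contaminated-population scenarios.

Scoring error is modelled per animal-observation: a *mis-score* flips
the recorded status (in TLM a live animal called dead is removed — the
error propagates — while a dead animal called alive is simply re-scored
next time); a *scoring hazard* kills a live animal at the moment of
observation.  The error probability is constant or rises with time
along a logistic curve to a plateau `maxP` (late-life onset:
maxP·F(t); mid-life onset: maxP·F(1.5t), with F the generating CDF).

Estimators: Kaplan–Meier for exact/right-censored records, the Turnbull
NPMLE for interval-censored records (solved exactly by isotonic
regression for current-status data), and parametric logistic maximum
likelihood maximizing Σ wᵢ·ln(S(lᵢ) − S(rᵢ)) over weighted censoring
intervals (lᵢ, rᵢ].  Two-sample comparisons use the Mantel–Cox
log-rank test, a permutation generalized log-rank for interval data,
and label permutation of |μ̂ₐ − μ̂_b|; power is the fraction of
Benjamini–Hochberg-adjusted p-values below α = 0.01.

## Worked example

Simulate 200 trials of each design under a constant 2% mis-scoring
probability and fit each trial with the parametric logistic model:

```python
import numpy as np
from wormspan import (
    ErrorModel, LogisticParams, count_observations, fit_logistic_mle,
    rsm_to_intervals, run_trial_set, summarize_trial_set, tlm_to_intervals,
)

ref = LogisticParams(mu=20.0, s=2.0)
err = ErrorModel(kind="constant", effect="misscore", max_p=0.02)

for design, size in [("TLM", 110), ("RSM", 20)]:
    trials = run_trial_set(design, 200, 42, dist=ref, sample_size=size, error=err)
    if design == "TLM":
        medians = [fit_logistic_mle(tlm_to_intervals(t, "interval")).median
                   for t in trials]
    else:
        medians = [fit_logistic_mle(rsm_to_intervals(t)).median for t in trials]
    obs = [count_observations(t) for t in trials]
    summ = summarize_trial_set(medians, 20.0, observation_counts=obs)
    print(f"{design}: median-of-medians {summ.median_of_medians:.2f} d, "
          f"SE {summ.se_median:.3f}, MSE {summ.mse_median:.2f}, "
          f"median {summ.total_observations_median:.0f} observations/trial")
```

Output:

```
TLM: median-of-medians 16.87 d, SE 0.046, MSE 10.29, median 1936 observations/trial
RSM: median-of-medians 19.88 d, SE 0.024, MSE 0.13, median 640 observations/trial
```

The true median is 20 days.  A 2% chance of mis-calling vital status at
each visit drags the traditional method's estimate down by more than
three days — every live animal falsely called dead is removed, so the
error compounds day after day — while the replica set, which scores each
animal once, loses only ~0.1 day of accuracy, and does so with a third
of the scoring effort.

A command-line interface mirrors the library
(`wormspan simulate|fit|compare|power|summarize`); simulation outputs
are TSV observation tables plus a JSON manifest (config echo, seed,
version) sufficient to regenerate them bit-for-bit.

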