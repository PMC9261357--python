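# Methods

## Generating model

Simulated animals receive i.i.d. death times by inverse-transform
sampling: uniform(0,1) draws are mapped through the quantile function of
the generating distribution.  The reference population is logistic with
location μ = 20 days (mean = median) and shape s = 2 days — values
representative of wild-type *C. elegans* hermaphrodites at 20 °C, where
fitted shape parameters near 2 are typical of plate-based assays.  The
logistic quantile is expressed in terms of survival probability,
T(p) = s·ln(1/p − 1) + μ; because uniform draws are symmetric this is
distributionally identical to sampling through the CDF.

The Gompertz alternative uses the two-parameter form with baseline rate
α and aging rate β (hazard α·e^{βt}); the bundled parameter pair
(α = 3.271342 × 10⁻⁴, β = 0.3271342 d⁻¹) gives a median of exactly
20 days with a slope comparable to the reference logistic, so that
distribution-mismatch effects are isolated from location effects.
Mixtures (e.g. 67% of animals with μ = 20, 33% with μ = 16, the
contaminated-strain scenario) choose a component per animal by weight,
then sample within the component.

The logistic model has support on the whole real line; at the reference
parameters the mass below zero is ~4.5 × 10⁻⁵ and is retained rather
than truncated (a death time below the first scoring simply surfaces at
the first observation).

## Scoring schedules and designs

**TLM.**  One plate of n animals (default 110) is scored at
t = 0, Δ, 2Δ, … for scoring interval Δ ∈ {1, 2, 3} days.  The schedule
deliberately includes a day-0 visit: cohorts are inspected when plated
as day-0 adults.  At each visit every animal still on the plate is
assessed; animals recorded dead are removed and never re-assessed.  The
trial ends when the plate is empty.  A hard cap of 10× the expected
maximum lifespan guards against error configurations under which dead
animals are perpetually called alive; capped trials are flagged
`truncated`.

**RSM.**  The number of plates is planned from the expected maximum
lifespan, taken as the 99%-mortality time T₉₉ of the generating
distribution (29.19 d for the reference logistic; the corresponding
"maximum lifespan ≈ 30 days" round-off is *not* used — the closed form
is): T = ceil(T₉₉/Δ) + 2 plates, each of n animals (default 20), all
drawn up front.  Plate k is scored once at t = kΔ.  Scoring stops when
plates are exhausted, or early after two consecutive observations with
zero recorded-live animals — with the stopping scan active only once
the trailing pair lies at or past T₉₉.  The restriction is a design
choice: an all-dead replicate of 15–20 animals *before* the expected end
of life is within sampling expectation (at t = 27 a 20-animal plate is
fully dead more than half the time under the reference model), and a
scorer following the planned design continues; past the horizon, two
empty consecutive observations confirm the experiment is over.  This
reading also matches the per-trial effort the simulations reproduce
(median 31 plates scored = 620 observations at Δ = 1).  The literal
scan-from-the-start rule remains available via
`run_rsm_trial(..., termination="immediate")`.

**Error models.**  Mis-scoring flips the recorded status of the
assessed animal; a hazard error kills a truly-live animal at the moment
of scoring (dead animals are recorded correctly).  The probability is
`none`, constant (p ∈ {2, 4, 10}% studied), or time-dependent:
late-life onset p(t) = maxP·F(t) with F the logistic CDF of the
generating distribution (the error rises as survival falls), and
mid-life onset p(t) = maxP·F(1.5t), the same curve shifted earlier.
Mis-scoring and hazard are never combined in one trial.  The two error
directions are asymmetric in TLM: a live animal called dead is removed
and its record is permanently wrong, while a dead animal called alive
is re-assessed at the next visit at the current time's error rate.

**RNG discipline.**  Every observation consumes exactly one uniform per
animal on the plate regardless of the error probability, so an
error-free run and a maxP = 0 run with the same seed are bit-identical
— enabling paired comparisons.  Trial sets derive per-trial substreams
from `numpy.random.SeedSequence(master_seed).spawn(...)`, so results
are reproducible and independent of execution order.

## Estimation

Recorded deaths become weighted censoring intervals (l, r]: exact times
(right-censoring convention), (t_prev, t] for interval-censored TLM
analysis (the day-0 visit makes the first possible interval (−Δ, 0],
which the logistic supports), and (0, t] / (t, ∞) current-status
records for RSM.

*Kaplan–Meier* (via lifelines) handles exact/right-censored records
only; current-status data is refused with an explanatory error.

*Turnbull NPMLE*: innermost (Turnbull) intervals are computed from the
endpoint order; masses by self-consistency EM (tolerance 10⁻⁹ on
masses, cap 20,000 iterations).  Pure current-status data — where the
EM is known to converge slowly — is instead solved exactly as the
weighted isotonic regression of the per-time dead fractions (Ayer's
pool-adjacent-violators solution).  Mass inside a Turnbull interval is
unidentified; point summaries use the interval midpoint.

*Logistic MLE* maximizes Σ wᵢ·ln(S(lᵢ) − S(rᵢ)) over (μ, ln s) — the
log-scale keeps s > 0 — by L-BFGS-B with the analytic gradient,
initialized at s₀ = 2 and μ₀ = the time where observed proportional
mortality first crosses one half (midpoint-interpolated), with
perturbed restarts and a Nelder–Mead fallback.  S(0) is evaluated, not
forced to 1.  Data with no observed death, or no animal seen alive
after time zero, cannot identify both parameters and is flagged
`converged=False`.  For the logistic fit median = mean = μ̂ and
q95 = μ̂ + ŝ·ln 19.

*Step-curve summaries*: the median (and 95%-mortality quantile) is the
earliest time the curve drops to or below the level, except that when
the curve sits exactly at the level the quantile is the midpoint of
that time and the next drop — the convention of R's `survival` package.
The alternative "earliest time with S ≤ 0.5" convention degenerates on
discretely scored data: with n = 110 and daily scoring the per-trial KM
median is 20 or 21 with near-equal probability and the across-trial
median becomes an unstable coin flip, whereas the midpoint convention
lands stably on 20.5 and equals the sample median in the uncensored
case.  Means are restricted to the last observed time (inactive for
fully mortal trials); NPMLE means use the midpoint placement.

With these conventions daily right-censored KM medians are biased by
+0.5 d and 3-day means by +1.5 d (half the scoring interval); the
3-day KM *median* is quantized to the scoring grid and lands at +1.0 d.
Interval-censored and parametric analyses of the same trials are
unbiased to within Monte-Carlo noise.

## Two-sample tests and power

Log-rank (Mantel–Cox, via lifelines) serves right-censored analyses.
Interval-censored comparisons use a permutation generalized log-rank:
per-animal scores c = (S(l)·ln S(l) − S(r)·ln S(r))/(S(l) − S(r)) under
the pooled NPMLE, with the group-A score sum permuted over animal
labels.  The parametric comparison permutes animal-level records and
refits both pseudo-groups, using |μ̂ₐ − μ̂_b| — the quantity the
analysis reports — as the statistic; permutation fits reuse the pooled
estimate as a warm start, and the test aborts if more than 1% of
resampled fits fail.  All permutation p-values use the add-one estimate
(b + 1)/(n_perm + 1) and therefore are never zero.

Power grids simulate, per cell, n_trials test-vs-reference comparisons
(a fresh reference trial of the same design and size per comparison,
reference median 20 d), BH-adjust within the cell — mirroring the
per-condition family of 100 comparisons — and report the fraction below
α = 0.01 plus the median per-trial observation count.  The permutation
unit is the animal's event interval (TLM) or its single (time, status)
record (RSM), preserving each design's observation structure under the
null.

At the precision-matched sizes (TLM 110/trial, RSM 20/observation,
sd of fitted medians ≈ 0.3 d for both) the power to detect a 2-day
shift at α = 0.01 is ≈ 0.9 for both designs — per trial the observed
difference sits about 4.7 null standard errors out against the 2.58
needed — and saturates to 1.0 as the sample grows; the replica set
reaches saturation at ≈ 40 animals/observation (~1,160 observations per
trial), less than half the effort the traditional design has already
spent while still short of saturation at 150 animals (~2,900).

## Problem sizes and what the tests show

The test-suite and the acceptance script run every Monte-Carlo summary
at 1,000 trials per condition (2,000 for the daily bias, whose median
estimator is intentionally near a quantization boundary), with
tolerances sized for that scale; permutation tests use n_perm = 199
(minimum attainable p = 0.005, sufficient to reject at α = 0.01), and
the parametric-test null calibration runs 400 trial pairs at a reduced
plate size.  These sizes were chosen so every check completes in
minutes on one core while leaving each tolerance several Monte-Carlo
standard errors wide.

The generator emulates the censoring structure, scoring discreteness,
termination rules and error propagation of real lifespan assays.  It
does not emulate crawl-off/censoring events (all simulated counts have
n_censored = 0; the field exists for real-data I/O), plate-position or
environmental effects, food depletion, progeny production, or
between-batch heterogeneity.  Passing tests therefore validate the
statistical machinery and the relative behavior of the designs under
the stated error models — not the biological realism of any particular
error rate.

## Known limitations

* Parametric fitting is logistic-only (Gompertz is generate-only); no
  Cox, frailty or smoothed-hazard models.
* The NPMLE mean/median depend on the midpoint placement convention
  inside Turnbull intervals; other conventions shift point summaries by
  up to half a scoring interval.
* Under constant 10% mis-scoring the TLM estimate is dominated by the
  false-death geometric process and the logistic model is badly
  mis-specified; fitted values there (≈ 6.4–6.8 d) are
  convention-sensitive.
* The permutation and interval tests are exchangeable-label tests;
  they assume a shared scoring schedule between groups, as in the
  simulated comparisons.
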