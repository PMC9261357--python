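"""Monte-Carlo simulators for TLM and RSM lifespan experiments.

A trial draws true death times from a generating distribution and then
"scores" them on a discrete schedule.

TLM (traditional longitudinal method): one plate of ``n`` animals is
scored at t = 0, interval, 2*interval, ... (the cohort is inspected from
day 0 of adulthood); animals recorded dead are removed and never
re-scored; the trial ends when the plate is empty.

RSM (replica set method): enough plates are prepared up front to cover
two observations past the expected maximum lifespan (the time of 99%
mortality of the generating distribution); plate k is scored once at
t = k*interval.  Scoring stops when the prepared plates are exhausted,
or early — once the experiment has passed the planned maximum-lifespan
horizon — after two consecutive observations with no recorded-live
animals.  (With ``termination="immediate"`` the two-consecutive-dead
rule applies from the first observation instead.)

Experimenter error is modelled per animal-observation:

* ``misscore`` flips the recorded status (a live animal called dead is
  removed/counted dead; a dead animal called live stays on the plate in
  TLM and is re-assessed at the next observation),
* ``hazard`` kills a truly-live animal at the moment of scoring
  (rough-handling death); dead animals are always recorded correctly.

The error probability is constant or rises with time along a logistic
curve (late-life onset: maxP * F(t); mid-life onset: the same curve
evaluated at 1.5*t, which shifts the rise earlier), where F is by
default the CDF of the generating logistic distribution — the rise in
error tracks the decline in survival.

RNG discipline: every observation consumes one uniform per animal on the
plate regardless of the error probability, so an error-free run and a
``max_p = 0`` run with the same seed produce bit-identical trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from wormspan.distributions import (
    LogisticParams,
    MixtureSpec,
    SurvivalDistribution,
    cdf_quantile,
    logistic_cdf,
    sample_death_times,
)

__all__ = [
    "ErrorModel",
    "NO_ERROR",
    "ObservationRecord",
    "TLMTrialResult",
    "RSMTrialResult",
    "error_probability",
    "run_tlm_trial",
    "run_rsm_trial",
    "make_mixture",
    "run_trial_set",
]

_KINDS = ("none", "constant", "late_onset", "mid_onset")
_EFFECTS = ("misscore", "hazard")


@dataclass(frozen=True)
class ErrorModel:
    """Specification of scoring error applied during simulation.

    ``kind`` selects the time course of the error probability and
    ``effect`` what an error does (mis-score vs. accidental kill).
    ``max_p`` is the plateau probability; ``curve_mu``/``curve_s`` are the
    logistic parameters of the rise for the time-dependent kinds (default:
    the generating distribution's own parameters).
    """

    kind: str = "none"
    effect: str = "misscore"
    max_p: float = 0.0
    curve_mu: Optional[float] = None
    curve_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.effect not in _EFFECTS:
            raise ValueError(f"effect must be one of {_EFFECTS}, got {self.effect!r}")
        if not 0.0 <= self.max_p <= 1.0:
            raise ValueError(f"max_p must be in [0, 1], got {self.max_p}")
        if self.kind in ("late_onset", "mid_onset"):
            if self.curve_s is not None and self.curve_s <= 0:
                raise ValueError("curve_s must be > 0")

    def resolved(self, dist: SurvivalDistribution) -> "ErrorModel":
        """Fill unset curve parameters from the generating distribution."""
        if self.kind not in ("late_onset", "mid_onset"):
            return self
        if self.curve_mu is not None and self.curve_s is not None:
            return self
        if isinstance(dist, LogisticParams):
            mu, s = dist.mu, dist.s
        else:
            # non-logistic generators: anchor the curve at the same
            # median / slope surrogate (99%-1% spread mapped to logistic)
            mu = float(cdf_quantile(0.5, dist))
            s = (float(cdf_quantile(0.99, dist)) - mu) / math.log(99.0)
        return replace(
            self,
            curve_mu=self.curve_mu if self.curve_mu is not None else mu,
            curve_s=self.curve_s if self.curve_s is not None else s,
        )


NO_ERROR = ErrorModel()


def error_probability(t, model: ErrorModel):
    """Probability that scoring an animal at time ``t`` goes wrong.

    none -> 0; constant -> max_p; late_onset -> max_p * F(t);
    mid_onset -> max_p * F(1.5 t), with F the logistic CDF of
    (curve_mu, curve_s).  Monotone non-decreasing in t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if model.kind == "none":
        out = np.zeros_like(t)
    elif model.kind == "constant":
        out = np.full_like(t, model.max_p)
    else:
        if model.curve_mu is None or model.curve_s is None:
            raise ValueError(
                "time-dependent error model needs curve_mu and curve_s; "
                "call ErrorModel.resolved(dist) or set them explicitly"
            )
        curve = LogisticParams(model.curve_mu, model.curve_s)
        tt = 1.5 * t if model.kind == "mid_onset" else t
        out = model.max_p * np.asarray(logistic_cdf(tt, curve))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ObservationRecord:
    """Counts recorded at one scoring of one plate."""

    time: float
    n_live: int
    n_dead: int
    n_censored: int = 0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("observation time must be >= 0")
        if min(self.n_live, self.n_dead, self.n_censored) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class TLMTrialResult:
    """One simulated traditional-longitudinal trial."""

    n_start: int
    scoring_interval: float
    true_death_times: np.ndarray
    recorded_death_times: np.ndarray
    observations: List[ObservationRecord]
    truncated: bool = False
    design: str = field(default="TLM", init=False)


@dataclass
class RSMTrialResult:
    """One simulated replica-set trial (each plate scored once)."""

    n_per_plate: int
    scoring_interval: float
    n_plates_prepared: int
    observations: List[ObservationRecord]
    terminated_early: bool
    true_death_times: Optional[np.ndarray] = None
    design: str = field(default="RSM", init=False)


def _expected_max_lifespan(dist: SurvivalDistribution) -> float:
    """Time of 99% mortality of the generating distribution (days)."""
    return float(cdf_quantile(0.99, dist))


def run_tlm_trial(
    n_animals: int,
    dist: SurvivalDistribution,
    interval: float = 1.0,
    error: ErrorModel = NO_ERROR,
    rng: Optional[np.random.Generator] = None,
) -> TLMTrialResult:
    """Simulate one TLM trial of ``n_animals`` scored every ``interval`` days.

    The cohort is scored at t = 0, interval, 2*interval, ...; at each
    observation every animal still on the plate is assessed, and its
    true status (alive iff its death time exceeds the observation time)
    is corrupted according to ``error``.  Animals recorded dead are
    removed.  The trial ends when the plate is empty; pathological
    configurations are cut off after 10x the expected maximum lifespan
    (``truncated``).
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if interval <= 0:
        raise ValueError("scoring interval must be > 0")
    rng = np.random.default_rng() if rng is None else rng
    error = error.resolved(dist)

    deaths = sample_death_times(n_animals, dist, rng)
    max_obs = max(int(math.ceil(10.0 * _expected_max_lifespan(dist) / interval)), 1)

    on_plate = np.ones(n_animals, dtype=bool)
    recorded = np.full(n_animals, np.nan)
    observations: List[ObservationRecord] = []
    truncated = False

    k = -1
    while on_plate.any():
        k += 1
        t = k * interval
        u = rng.random(n_animals)  # one draw per animal regardless of p
        p = error_probability(t, error)
        truly_alive = deaths > t
        if k > max_obs:
            # hard cap: record whatever is left as dead at this time
            recorded_dead = on_plate.copy()
            truncated = True
        elif error.effect == "misscore":
            flip = u < p
            recorded_dead = on_plate & (truly_alive == flip)
        else:  # hazard: only truly-live animals can be (accidentally) killed
            killed = truly_alive & (u < p)
            recorded_dead = on_plate & (~truly_alive | killed)
        n_dead = int(recorded_dead.sum())
        recorded[recorded_dead] = t
        on_plate &= ~recorded_dead
        n_live = int(on_plate.sum())
        observations.append(ObservationRecord(time=t, n_live=n_live, n_dead=n_dead))
        if truncated:
            break

    return TLMTrialResult(
        n_start=n_animals,
        scoring_interval=interval,
        true_death_times=deaths,
        recorded_death_times=recorded,
        observations=observations,
        truncated=truncated,
    )


def run_rsm_trial(
    n_per_plate: int,
    dist: SurvivalDistribution,
    interval: float = 1.0,
    error: ErrorModel = NO_ERROR,
    rng: Optional[np.random.Generator] = None,
    keep_death_times: bool = False,
    termination: str = "planned_horizon",
) -> RSMTrialResult:
    """Simulate one replica-set trial.

    ``ceil(T99 / interval) + 2`` plates of ``n_per_plate`` animals are
    drawn up front (T99 = 99%-mortality time of the generating
    distribution); plate k is scored once at t = k*interval.  Scoring
    stops after two consecutive observations with zero recorded-live
    animals, or when the prepared plates are exhausted.

    By default (``termination="planned_horizon"``) the two-consecutive-
    dead stopping rule only takes effect once the experiment has passed
    the planning horizon T99: an all-dead replicate of 15-20 animals
    before the expected end of life is within sampling expectation and a
    scorer following the planned design keeps scoring, whereas past the
    horizon two empty consecutive observations confirm the experiment is
    over.  ``termination="immediate"`` applies the rule from the first
    observation.
    """
    if n_per_plate < 1:
        raise ValueError("n_per_plate must be >= 1")
    if interval <= 0:
        raise ValueError("scoring interval must be > 0")
    if termination not in ("planned_horizon", "immediate"):
        raise ValueError("termination must be 'planned_horizon' or 'immediate'")
    rng = np.random.default_rng() if rng is None else rng
    error = error.resolved(dist)

    t_max = _expected_max_lifespan(dist)
    n_plates = int(math.ceil(t_max / interval)) + 2
    # all animals drawn up front, plate-major order
    deaths = sample_death_times(n_plates * n_per_plate, dist, rng).reshape(
        n_plates, n_per_plate
    )

    observations: List[ObservationRecord] = []
    consecutive_dead = 0
    terminated_early = False
    for k in range(1, n_plates + 1):
        t = k * interval
        plate = deaths[k - 1]
        u = rng.random(n_per_plate)
        p = error_probability(t, error)
        truly_alive = plate > t
        if error.effect == "misscore":
            recorded_alive = truly_alive != (u < p)
        else:  # hazard
            recorded_alive = truly_alive & ~(u < p)
        n_live = int(recorded_alive.sum())
        observations.append(
            ObservationRecord(time=t, n_live=n_live, n_dead=n_per_plate - n_live)
        )
        consecutive_dead = consecutive_dead + 1 if n_live == 0 else 0
        # time of the first observation of the trailing all-dead pair
        pair_start = t - interval
        scan_active = termination == "immediate" or pair_start >= t_max - 1e-9
        if consecutive_dead >= 2 and scan_active:
            terminated_early = k < n_plates
            break

    return RSMTrialResult(
        n_per_plate=n_per_plate,
        scoring_interval=interval,
        n_plates_prepared=n_plates,
        observations=observations,
        terminated_early=terminated_early,
        true_death_times=deaths if keep_death_times else None,
    )


def make_mixture(
    frac_a: float,
    dist_a: SurvivalDistribution,
    dist_b: SurvivalDistribution,
) -> MixtureSpec:
    """Two-component mixture with weights (frac_a, 1 - frac_a).

    Emulates a contaminated experiment in which a fraction ``1 - frac_a``
    of animals come from a second population (e.g. a shorter-lived
    strain).
    """
    if not 0.0 < frac_a < 1.0:
        raise ValueError("frac_a must lie strictly in (0, 1)")
    return MixtureSpec(components=((frac_a, dist_a), (1.0 - frac_a, dist_b)))


def run_trial_set(
    design: str,
    n_trials: int,
    master_seed,
    *,
    dist: SurvivalDistribution,
    sample_size: int,
    interval: float = 1.0,
    error: ErrorModel = NO_ERROR,
    **kwargs,
) -> list:
    """Run ``n_trials`` independent trials from reproducible substreams.

    Each trial gets its own counter-derived child of
    ``numpy.random.SeedSequence(master_seed)``, so the set is bit-identical
    across reruns and independent of any parallel execution order.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    design = design.upper()
    if design not in ("TLM", "RSM"):
        raise ValueError(f"design must be 'TLM' or 'RSM', got {design!r}")
    children = np.random.SeedSequence(master_seed).spawn(n_trials)
    runner = run_tlm_trial if design == "TLM" else run_rsm_trial
    return [
        runner(
            sample_size,
            dist,
            interval=interval,
            error=error,
            rng=np.random.Generator(np.random.PCG64(child)),
            **kwargs,
        )
        for child in children
    ]
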