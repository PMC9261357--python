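"""Censoring-aware lifespan estimation.

Recorded deaths from discrete scoring are represented as weighted
censoring intervals (left, right]:

* an exact event time ``t`` is stored as ``left == right == t``
  (right-censoring convention: death assumed at the observation),
* a death first seen at observation ``t`` after a previous observation
  at ``t_prev`` is the interval ``(t_prev, t]``,
* current-status records (replica-set data) are ``(0, t]`` for animals
  found dead and ``(t, inf)`` for animals found alive.

Estimators:

* `km_right_censored` — Kaplan-Meier product-limit curve for exact /
  right-censored records (via lifelines),
* `npmle_interval` — Turnbull's nonparametric maximum-likelihood
  estimate for arbitrary interval censoring, computed by
  self-consistency/EM over the innermost (Turnbull) intervals,
* `fit_logistic_mle` — parametric logistic fit maximizing
  sum w_i * ln(S(left_i) - S(right_i)) over (mu, s).

Point summaries use the convention of R's ``survival`` package for
quantiles of step curves: the median is the earliest time at which the
curve drops to or below 0.5, except that when the curve sits exactly at
0.5 the median is the midpoint between that time and the next drop.
Masses on Turnbull equivalence intervals are placed at interval
midpoints for point summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from wormspan.simulate import RSMTrialResult, TLMTrialResult

__all__ = [
    "IntervalDataset",
    "FitResult",
    "SurvivalCurveEstimate",
    "CurveSummary",
    "tlm_to_intervals",
    "rsm_to_intervals",
    "fit_logistic_mle",
    "km_right_censored",
    "npmle_interval",
    "curve_summaries",
]

_ATOL = 1e-9


@dataclass
class IntervalDataset:
    """Weighted censoring intervals (left, right].

    ``left == right`` marks an exact event time; ``right == inf`` a
    right-censored (still alive) record.  Identical intervals are
    aggregated into ``weights``.
    """

    left: np.ndarray
    right: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (self.left.shape == self.right.shape == self.weights.shape):
            raise ValueError("left, right and weights must have equal length")
        if self.left.size == 0:
            raise ValueError("interval dataset is empty")
        if np.any(self.left > self.right):
            raise ValueError("intervals must satisfy left <= right")
        if np.any(np.isinf(self.left)) or np.any(np.isnan(self.left)):
            raise ValueError("left edges must be finite")
        if np.any(self.weights < 1):
            raise ValueError("weights must be >= 1")

    @classmethod
    def from_records(cls, left, right, weights=None) -> "IntervalDataset":
        """Build a dataset, aggregating identical (left, right] intervals."""
        left = np.asarray(left, dtype=float)
        right = np.asarray(right, dtype=float)
        weights = (
            np.ones_like(left) if weights is None else np.asarray(weights, dtype=float)
        )
        pairs = np.column_stack([left, right])
        uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
        w = np.zeros(len(uniq))
        np.add.at(w, inv, weights)
        return cls(left=uniq[:, 0], right=uniq[:, 1], weights=w)

    @property
    def n(self) -> float:
        """Total number of animals represented."""
        return float(self.weights.sum())

    def expand(self) -> Tuple[np.ndarray, np.ndarray]:
        """Per-animal (left, right) arrays, one row per unit of weight."""
        reps = np.rint(self.weights).astype(int)
        return np.repeat(self.left, reps), np.repeat(self.right, reps)

    @property
    def is_exact_or_right_censored(self) -> bool:
        exact = np.isclose(self.left, self.right)
        censored = np.isinf(self.right)
        return bool(np.all(exact | censored))


@dataclass
class FitResult:
    """Parametric logistic fit with derived lifespan summaries."""

    mu_hat: float
    s_hat: float
    loglik: float
    median: float
    mean: float
    q95: float
    converged: bool
    message: str = ""


@dataclass
class SurvivalCurveEstimate:
    """Step survival curve with probability mass at ``times``.

    ``survival[i]`` is the curve value just after the drop at
    ``times[i]``; ``mass_at_inf`` is the probability never placed at a
    finite time (right-censored tail).  ``horizon`` is the last observed
    event/censor time, used for restricted means.
    """

    times: np.ndarray
    survival: np.ndarray
    estimator: str
    mass_at_inf: float = 0.0
    horizon: float = field(default=np.nan)
    loglik: float = field(default=np.nan)
    turnbull_intervals: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if np.any(np.diff(self.survival) > _ATOL):
            raise ValueError("survival must be non-increasing")
        if np.any((self.survival < -_ATOL) | (self.survival > 1 + _ATOL)):
            raise ValueError("survival values must lie in [0, 1]")


class CurveSummary(NamedTuple):
    median: float
    mean: float
    q95: float


# ---------------------------------------------------------------------------
# conversions from simulated trials


def tlm_to_intervals(trial: TLMTrialResult, mode: str = "interval") -> IntervalDataset:
    """Per-death intervals from a TLM trial.

    ``mode='right'`` treats each recorded death as an exact event at the
    observation time; ``mode='interval'`` uses (t_prev, t] with t_prev
    the previous scheduled observation (one scoring interval earlier;
    deaths recorded at the day-0 scoring get the interval (-interval, 0],
    which the logistic model supports).
    """
    if mode not in ("right", "interval"):
        raise ValueError(f"mode must be 'right' or 'interval', got {mode!r}")
    t = np.asarray(trial.recorded_death_times, dtype=float)
    if t.size == 0 or np.any(np.isnan(t)):
        raise ValueError("trial has unrecorded animals; cannot build intervals")
    if mode == "right":
        return IntervalDataset.from_records(t, t)
    prev = t - trial.scoring_interval
    return IntervalDataset.from_records(prev, t)


def rsm_to_intervals(trial: RSMTrialResult) -> IntervalDataset:
    """Current-status intervals from a replica-set trial.

    Each animal found dead at its (single) observation at time t
    contributes (0, t]; each animal found alive contributes (t, inf).
    """
    if not trial.observations:
        raise ValueError("trial has no observations")
    left, right, weight = [], [], []
    for obs in trial.observations:
        if obs.n_dead > 0:
            left.append(0.0)
            right.append(obs.time)
            weight.append(obs.n_dead)
        if obs.n_live > 0:
            left.append(obs.time)
            right.append(np.inf)
            weight.append(obs.n_live)
    return IntervalDataset.from_records(left, right, weight)


# ---------------------------------------------------------------------------
# parametric logistic maximum likelihood


def _nll_and_grad(theta, left, right, w):
    """Negative interval log-likelihood of the logistic model and gradient.

    Parameterized as (mu, log s) to keep s > 0.  S(0) is evaluated at
    t = 0 (not forced to 1); S(inf) = 0.
    """
    mu, log_s = theta
    s = math.exp(log_s)
    ul = (left - mu) / s
    Sl = expit(-ul)
    finite_r = np.isfinite(right)
    ur = np.where(finite_r, (np.where(finite_r, right, 0.0) - mu) / s, np.inf)
    Sr = np.where(finite_r, expit(-np.where(finite_r, ur, 0.0)), 0.0)
    diff = np.maximum(Sl - Sr, 1e-300)
    nll = -float(np.sum(w * np.log(diff)))

    dl = Sl * (1.0 - Sl)
    dr = Sr * (1.0 - Sr)
    # d diff / d mu and d diff / d log s
    ddiff_dmu = (dl - dr) / s
    ddiff_dls = dl * ul - np.where(finite_r, dr * np.where(finite_r, ur, 0.0), 0.0)
    grad = np.array(
        [
            -float(np.sum(w * ddiff_dmu / diff)),
            -float(np.sum(w * ddiff_dls / diff)),
        ]
    )
    return nll, grad


def _initial_location(data: IntervalDataset) -> float:
    """Time at which observed proportional mortality first crosses 0.5.

    Mortality at time t is estimated as (animals known dead by t) /
    (known dead by t + known alive at t); the crossing is midpoint
    interpolated between adjacent candidate times.
    """
    edges = np.concatenate([data.left, data.right[np.isfinite(data.right)]])
    times = np.unique(edges[edges > 0])
    if times.size == 0:
        return float(np.average(data.left, weights=data.weights))
    prev_t, prev_frac = 0.0, 0.0
    for t in times:
        dead = data.weights[data.right <= t + _ATOL].sum()
        alive = data.weights[data.left >= t - _ATOL].sum()
        frac = dead / (dead + alive) if dead + alive > 0 else 0.0
        if frac >= 0.5:
            return float(0.5 * (prev_t + t)) if prev_frac < 0.5 else float(t)
        prev_t, prev_frac = t, frac
    return float(times[-1])


def fit_logistic_mle(
    data: IntervalDataset,
    init: Optional["LogisticParams"] = None,
) -> FitResult:
    """Maximum-likelihood logistic fit to censoring intervals.

    Maximizes sum_i w_i * ln(S(left_i) - S(right_i)) over (mu, log s)
    using L-BFGS-B with the analytic gradient, retrying from perturbed
    starting points (and a Nelder-Mead fallback) on failure.  Returns
    the location/scale estimates and the derived median (= mean = mu),
    and 95%-mortality quantile q95 = mu + s*ln(19).

    Data with no finite right edge, or no positive left edge, cannot
    identify both parameters and yields ``converged=False``.
    """
    exact = np.isclose(data.left, data.right)
    if np.any(exact):
        raise ValueError(
            "parametric fitting requires true intervals; convert exact event "
            "times with tlm_to_intervals(trial, mode='interval')"
        )
    has_finite_right = bool(np.any(np.isfinite(data.right)))
    has_positive_left = bool(np.any(data.left > 0))
    if not (has_finite_right and has_positive_left):
        return FitResult(
            mu_hat=np.nan,
            s_hat=np.nan,
            loglik=np.nan,
            median=np.nan,
            mean=np.nan,
            q95=np.nan,
            converged=False,
            message="non-identifiable: needs at least one observed death and "
            "one animal observed alive after time 0",
        )

    left, right, w = data.left, data.right, data.weights
    if init is not None:
        starts = [(float(init.mu), math.log(float(init.s)))]
    else:
        mu0 = _initial_location(data)
        starts = [(mu0, math.log(2.0))]
    # perturbed restarts used only if earlier attempts fail
    mu0 = starts[0][0]
    starts += [(mu0 + 2.0, 0.0), (mu0 - 2.0, math.log(4.0)), (mu0, math.log(1.0))]

    best = None
    for i, x0 in enumerate(starts):
        res = minimize(
            _nll_and_grad,
            x0=np.asarray(x0),
            args=(left, right, w),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-1e4, 1e4), (math.log(1e-3), math.log(1e3))],
        )
        if res.success and np.all(np.isfinite(res.x)):
            best = res
            break
    if best is None:
        res = minimize(
            lambda th: _nll_and_grad(th, left, right, w)[0],
            x0=np.asarray(starts[0]),
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        best = res
    converged = bool(best.success and np.all(np.isfinite(best.x)))
    mu_hat = float(best.x[0])
    s_hat = float(math.exp(best.x[1]))
    return FitResult(
        mu_hat=mu_hat,
        s_hat=s_hat,
        loglik=-float(best.fun),
        median=mu_hat,
        mean=mu_hat,
        q95=mu_hat + s_hat * math.log(19.0),
        converged=converged,
        message="" if converged else str(best.message),
    )


# ---------------------------------------------------------------------------
# non-parametric estimators


def km_right_censored(data: IntervalDataset) -> SurvivalCurveEstimate:
    """Kaplan-Meier product-limit curve for exact / right-censored records.

    With zero censoring this equals the empirical survival function.
    Current-status (replica-set) data is refused: each animal there is
    inspected once, so no exact event times exist.
    """
    if not data.is_exact_or_right_censored:
        raise ValueError(
            "Kaplan-Meier with right censoring requires exact event times; "
            "interval/current-status data needs npmle_interval or a "
            "parametric fit"
        )
    from lifelines import KaplanMeierFitter

    exact = np.isclose(data.left, data.right)
    durations = np.where(exact, data.right, data.left)
    events = exact.astype(int)
    if events.sum() == 0:
        raise ValueError("no death events; survival curve is undefined")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events, weights=data.weights)
    sf = kmf.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    drops = np.diff(np.concatenate([[1.0], surv])) < -_ATOL
    return SurvivalCurveEstimate(
        times=times[drops],
        survival=surv[drops],
        estimator="km_right",
        mass_at_inf=float(surv[-1]),
        horizon=float(durations.max()),
    )


def _turnbull_support(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Innermost (Turnbull) intervals (p, q] of an interval-censored sample.

    A candidate (p, q] pairs a left endpoint p with the smallest right
    endpoint q > p such that no other left endpoint lies in (p, q); the
    NPMLE can only place mass inside these intervals.
    """
    L = np.unique(left)
    R = np.unique(right)
    out = []
    for p in L:
        greater = R[R > p]
        if greater.size == 0:
            continue
        q = greater[0]
        inside = L[(L > p) & (L < q)]
        if inside.size == 0:
            out.append((p, q))
    return np.array(out, dtype=float)


def _current_status_masses(data: IntervalDataset, support: np.ndarray) -> np.ndarray:
    """Exact NPMLE masses for pure current-status data via isotonic regression.

    For one-inspection data the NPMLE of the cumulative death fraction is
    the weighted isotonic regression of the per-time dead fractions
    (Ayer's pool-adjacent-violators solution), which the self-consistency
    EM only approaches slowly.
    """
    from scipy.optimize import isotonic_regression

    dead = np.isfinite(data.right)
    tau = np.where(dead, data.right, data.left)
    order = np.unique(tau)
    d = np.zeros_like(order)
    n = np.zeros_like(order)
    for t, r, w in zip(tau, dead, data.weights):
        i = np.searchsorted(order, t)
        n[i] += w
        d[i] += w if r else 0.0
    fit = isotonic_regression(d / n, weights=n, increasing=True)
    F = np.clip(fit.x, 0.0, 1.0)

    def F_at(x):
        i = np.searchsorted(order, x + _ATOL) - 1
        return 0.0 if i < 0 else F[i]

    return np.array([F_at(q) - F_at(p) if np.isfinite(q) else 1.0 - F_at(p)
                     for p, q in support])


def npmle_interval(
    data: IntervalDataset,
    tol: float = 1e-9,
    max_iter: int = 20000,
) -> SurvivalCurveEstimate:
    """Turnbull NPMLE for interval-censored data.

    Exact event times are treated as atoms.  Pure current-status data
    (every record (0, t] or (t, inf)) is solved exactly by isotonic
    regression; anything else uses Turnbull's self-consistency EM over
    the innermost (Turnbull) intervals.  Probability mass within each
    Turnbull interval is unidentified; point summaries place it at the
    interval midpoint.
    """
    left = data.left.copy()
    right = data.right.copy()
    exact = np.isclose(left, right)
    left[exact] -= 1e-9  # atoms as infinitesimal intervals
    support = _turnbull_support(left, right)
    if support.size == 0:
        raise ValueError("no Turnbull support intervals; data degenerate")
    p_lo, q_hi = support[:, 0], support[:, 1]
    # membership: support interval j inside observation interval i
    A = (p_lo[None, :] >= left[:, None] - _ATOL) & (
        q_hi[None, :] <= right[:, None] + _ATOL
    )
    if not A.any(axis=1).all():
        raise ValueError("observation interval contains no support interval")
    w = data.weights
    W = w.sum()
    m = support.shape[0]
    current_status = bool(
        np.all(
            (np.isclose(data.left, 0.0) & np.isfinite(data.right))
            | (np.isinf(data.right) & (data.left > 0))
        )
    )
    if current_status:
        prob = _current_status_masses(data, support)
        total = prob.sum()
        if total > 0:
            prob = prob / total
    else:
        prob = np.full(m, 1.0 / m)
        converged = False
        for _ in range(max_iter):
            denom = np.maximum(A @ prob, 1e-300)  # guard mass underflow
            new = prob * ((w / denom) @ A) / W
            new = new / new.sum()
            if np.max(np.abs(new - prob)) < tol:
                prob = new
                converged = True
                break
            prob = new
        if not converged:
            raise RuntimeError(
                f"Turnbull EM did not converge within {max_iter} iterations "
                f"(last max change {np.max(np.abs(new - prob)):.2e})"
            )
    loglik = float(np.sum(w * np.log(np.maximum(A @ prob, 1e-300))))

    finite = np.isfinite(q_hi)
    mass_at_inf = float(prob[~finite].sum())
    locs = np.where(q_hi[finite] - p_lo[finite] <= 2e-9,
                    q_hi[finite],
                    0.5 * (p_lo[finite] + q_hi[finite]))
    mass = prob[finite]
    keep = mass > 1e-12
    locs, mass = locs[keep], mass[keep]
    order = np.argsort(locs)
    locs, mass = locs[order], mass[order]
    surv = 1.0 - np.cumsum(mass)
    edges = np.concatenate([left[left > 0], right[np.isfinite(right)]])
    horizon = float(edges.max()) if edges.size else float(locs.max())
    return SurvivalCurveEstimate(
        times=locs,
        survival=np.clip(surv, 0.0, 1.0),
        estimator="npmle_interval",
        mass_at_inf=mass_at_inf,
        horizon=horizon,
        loglik=loglik,
        turnbull_intervals=support,
    )


# ---------------------------------------------------------------------------
# summaries of step curves


def _step_quantile(times, surv, level: float) -> float:
    """Earliest time the curve reaches ``level``, midpoint-interpolating ties.

    Follows the convention of R's survival package: if the curve sits
    exactly at ``level`` from time t_i, the quantile is the midpoint of
    t_i and the next drop time.
    """
    below = np.nonzero(surv <= level + _ATOL)[0]
    if below.size == 0:
        return np.nan
    i = below[0]
    if abs(surv[i] - level) <= _ATOL and i + 1 < len(times):
        return float(0.5 * (times[i] + times[i + 1]))
    return float(times[i])


def curve_summaries(curve: SurvivalCurveEstimate) -> CurveSummary:
    """Median, restricted mean, and 95%-mortality quantile of a step curve.

    median: earliest time with S <= 0.5; q95: earliest time with
    S <= 0.05 (both midpoint-interpolated at exact ties).  The mean is
    the area under the curve restricted to the last observed time; the
    restriction only matters when a right-censored tail remains.
    Quantiles the curve never reaches are returned as NaN.
    """
    times, surv = curve.times, curve.survival
    if times.size == 0:
        raise ValueError("empty survival curve")
    median = _step_quantile(times, surv, 0.5)
    q95 = _step_quantile(times, surv, 0.05)
    horizon = curve.horizon if np.isfinite(curve.horizon) else float(times[-1])
    horizon = max(horizon, float(times[-1]))
    prev_t, prev_s, area = 0.0, 1.0, 0.0
    for t, s_val in zip(times, surv):
        area += prev_s * (t - prev_t)
        prev_t, prev_s = t, s_val
    area += prev_s * (horizon - prev_t)
    return CurveSummary(median=median, mean=float(area), q95=q95)
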