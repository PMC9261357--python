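"""Two-sample tests and Monte-Carlo power analysis for lifespan designs.

Three tests cover the analysis routes of the two designs:

* `logrank_test` — Mantel-Cox log-rank for exact / right-censored data
  (traditional-method data analyzed with right censoring),
* `interval_twosample_test` — a permutation generalized log-rank for
  arbitrary interval censoring: per-animal log-rank scores are computed
  under the pooled Turnbull NPMLE and the group labels permuted,
* `permutation_test_parametric` — label permutation of the absolute
  difference of fitted logistic location parameters, the quantity the
  analysis actually reports (median lifespan).

Permutation p-values use the add-one estimate p = (b + 1)/(n_perm + 1),
so they are never exactly zero.  Power over a set of like trials is the
fraction whose Benjamini-Hochberg-adjusted p-value falls below alpha
(default 0.01), adjusted within the set as `power_grid` does per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from wormspan.distributions import LogisticParams
from wormspan.estimate import (
    IntervalDataset,
    fit_logistic_mle,
    npmle_interval,
    rsm_to_intervals,
    tlm_to_intervals,
)
from wormspan.metrics import count_observations
from wormspan.simulate import NO_ERROR, ErrorModel, run_rsm_trial, run_tlm_trial

__all__ = [
    "logrank_test",
    "interval_twosample_test",
    "permutation_test_parametric",
    "bh_adjust",
    "power_from_pvalues",
    "power_grid",
    "PowerGridResult",
]

_ATOL = 1e-9


@dataclass(frozen=True)
class PowerGridResult:
    """Estimated power for one (design, analysis, n, effect) cell."""

    design: str
    analysis: str
    sample_size: int
    effect_median: float
    power: float
    n_trials: int
    alpha: float
    total_observations_median: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# tests


def logrank_test(group_a: IntervalDataset, group_b: IntervalDataset) -> float:
    """Mantel-Cox log-rank p-value for exact / right-censored groups."""
    from lifelines.statistics import logrank_test as _ll_logrank

    for name, g in (("group_a", group_a), ("group_b", group_b)):
        if not g.is_exact_or_right_censored:
            raise ValueError(f"{name}: log-rank requires exact/right-censored data")
        if not np.any(np.isclose(g.left, g.right)):
            raise ValueError(f"{name} has no death events")
    da, ra = group_a.expand()
    db, rb = group_b.expand()
    ea = np.isfinite(ra).astype(int)
    eb = np.isfinite(rb).astype(int)
    res = _ll_logrank(da, db, event_observed_A=ea, event_observed_B=eb)
    return float(res.p_value)


def _pooled_npmle_survival(pooled: IntervalDataset):
    """S(x) evaluator from the pooled Turnbull NPMLE.

    Only the cumulative mass past each support interval's right end is
    needed to score observation endpoints, which by construction never
    fall inside an open support interval.
    """
    curve = npmle_interval(pooled)
    s_prev = np.concatenate([[1.0], curve.survival[:-1]])
    drops = s_prev - curve.survival  # mass at each finite curve location
    # curve.times are midpoints (or atoms) of the finite support
    # intervals; recover their right ends for the cumulative sum
    sup = curve.turnbull_intervals[np.isfinite(curve.turnbull_intervals[:, 1])]
    locs = np.where(
        sup[:, 1] - sup[:, 0] <= 2e-9, sup[:, 1], 0.5 * (sup[:, 0] + sup[:, 1])
    )
    q_ends = np.array(
        [sup[int(np.argmin(np.abs(locs - t))), 1] for t in curve.times]
    )
    order = np.argsort(q_ends)
    q_sorted = q_ends[order]
    cum_mass = np.cumsum(drops[order])

    def S(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        idx = np.searchsorted(q_sorted, x + _ATOL, side="left")
        dead = np.where(idx > 0, cum_mass[np.maximum(idx - 1, 0)], 0.0)
        return np.clip(1.0 - dead, 0.0, 1.0)

    return S


def _logrank_scores(left, right, S) -> np.ndarray:
    """Sun-type log-rank scores under a pooled NPMLE survival S.

    score = (S(l) ln S(l) - S(r) ln S(r)) / (S(l) - S(r)), with the
    conventions 0*ln 0 = 0, S(inf) = 0, and the limit ln S + 1 when the
    interval carries no pooled mass.
    """
    Sl = S(left)
    Sr = np.where(np.isfinite(right), S(np.where(np.isfinite(right), right, 0.0)), 0.0)

    def xlogx(x):
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = x[pos] * np.log(x[pos])
        return out

    num = xlogx(Sl) - xlogx(Sr)
    den = Sl - Sr
    safe = den > 1e-12
    scores = np.empty_like(den)
    scores[safe] = num[safe] / den[safe]
    # degenerate interval: limit of the score as S(r) -> S(l)
    Sl_deg = np.clip(Sl[~safe], 1e-300, None)
    scores[~safe] = np.log(Sl_deg) + 1.0
    return scores


def interval_twosample_test(
    group_a: IntervalDataset,
    group_b: IntervalDataset,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Permutation generalized log-rank test for interval-censored groups.

    Scores are computed once under the pooled NPMLE; the null
    distribution of the centred group-A score sum is obtained by
    permuting animal labels.  Returns p = (b + 1)/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    la, ra = group_a.expand()
    lb, rb = group_b.expand()
    pooled = IntervalDataset.from_records(
        np.concatenate([la, lb]), np.concatenate([ra, rb])
    )
    S = _pooled_npmle_survival(pooled)
    left = np.concatenate([la, lb])
    right = np.concatenate([ra, rb])
    scores = _logrank_scores(left, right, S)
    na = len(la)
    n = len(left)
    centred = scores - scores.mean()
    observed = abs(centred[:na].sum())
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)[:na]
        if abs(centred[idx].sum()) >= observed - _ATOL:
            count += 1
    return (count + 1) / (n_perm + 1)


def _fit_location(left, right, w, start) -> float:
    """Logistic location estimate for permutation resamples (fast path)."""
    from scipy.optimize import minimize

    from wormspan.estimate import _nll_and_grad

    keep = w > 0
    left, right, w = left[keep], right[keep], w[keep]
    if not (np.any(np.isfinite(right)) and np.any(left > 0)):
        return np.nan
    res = minimize(
        _nll_and_grad,
        x0=np.asarray(start),
        args=(left, right, w),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-1e4, 1e4), (math.log(1e-3), math.log(1e3))],
    )
    if not res.success or not np.all(np.isfinite(res.x)):
        return np.nan
    return float(res.x[0])


def permutation_test_parametric(
    group_a: IntervalDataset,
    group_b: IntervalDataset,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
    max_failure_fraction: float = 0.01,
) -> float:
    """Label-permutation test on |mu_a - mu_b| from separate logistic fits.

    Animal-level records are pooled and condition labels permuted;
    each resample refits both pseudo-groups.  Aborts if more than
    ``max_failure_fraction`` of the resampled fits fail.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    fa = fit_logistic_mle(group_a)
    fb = fit_logistic_mle(group_b)
    if not (fa.converged and fb.converged):
        raise RuntimeError("observed groups are not identifiable for logistic fits")
    observed = abs(fa.mu_hat - fb.mu_hat)

    la, ra = group_a.expand()
    lb, rb = group_b.expand()
    left = np.concatenate([la, lb])
    right = np.concatenate([ra, rb])
    na, n = len(la), len(la) + len(lb)
    # aggregate identical records once; permutation only reshuffles counts
    pairs = np.column_stack([left, np.where(np.isfinite(right), right, -1.0)])
    uniq, pair_id = np.unique(pairs, axis=0, return_inverse=True)
    u_left = uniq[:, 0]
    u_right = np.where(uniq[:, 1] < 0, np.inf, uniq[:, 1])
    k = len(uniq)
    total_counts = np.bincount(pair_id, minlength=k).astype(float)
    pooled_mu = 0.5 * (fa.mu_hat + fb.mu_hat)
    pooled_s = max(0.5 * (fa.s_hat + fb.s_hat), 1e-3)
    start = (pooled_mu, math.log(pooled_s))

    count = 0
    failures = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)[:na]
        ca = np.bincount(pair_id[idx], minlength=k).astype(float)
        cb = total_counts - ca
        mu_a = _fit_location(u_left, u_right, ca, start)
        mu_b = _fit_location(u_left, u_right, cb, start)
        if np.isnan(mu_a) or np.isnan(mu_b):
            failures += 1
            continue
        if abs(mu_a - mu_b) >= observed - _ATOL:
            count += 1
    if failures > max_failure_fraction * n_perm:
        raise RuntimeError(
            f"{failures}/{n_perm} permutation fits failed; data too degenerate "
            "for the parametric permutation test"
        )
    return (count + 1) / (n_perm - failures + 1)


# ---------------------------------------------------------------------------
# multiplicity and power


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def power_from_pvalues(adjusted_p: Sequence[float], alpha: float = 0.01) -> float:
    """Fraction of (adjusted) p-values strictly below alpha."""
    p = np.asarray(adjusted_p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    return float(np.mean(p < alpha))


def _trial_datasets(design, analysis, sample_size, mu, s, interval, error, rng):
    dist = LogisticParams(mu, s)
    if design == "TLM":
        trial = run_tlm_trial(sample_size, dist, interval=interval, error=error, rng=rng)
        mode = "right" if analysis == "km_right" else "interval"
        return trial, tlm_to_intervals(trial, mode=mode)
    trial = run_rsm_trial(sample_size, dist, interval=interval, error=error, rng=rng)
    if analysis == "km_right":
        raise ValueError(
            "replica-set data is current-status; Kaplan-Meier with right "
            "censoring is not applicable"
        )
    return trial, rsm_to_intervals(trial)


def _cell_pvalue(analysis, data_a, data_b, n_perm, rng):
    if analysis == "km_right":
        return logrank_test(data_a, data_b)
    if analysis == "npmle_interval":
        return interval_twosample_test(data_a, data_b, n_perm=n_perm, rng=rng)
    if analysis == "logistic":
        return permutation_test_parametric(data_a, data_b, n_perm=n_perm, rng=rng)
    raise ValueError(f"unknown analysis {analysis!r}")


def power_grid(
    designs: Sequence[str],
    analyses: Sequence[str],
    sample_sizes: Sequence[int],
    effect_medians: Sequence[float],
    n_trials: int = 100,
    master_seed=0,
    *,
    reference_median: float = 20.0,
    s: float = 2.0,
    interval: float = 1.0,
    error: ErrorModel = NO_ERROR,
    alpha: float = 0.01,
    n_perm: int = 1000,
) -> List[PowerGridResult]:
    """Monte-Carlo power across designs, analyses, sizes and effects.

    Each cell simulates ``n_trials`` test-vs-reference comparisons with
    matched design and sample size (the reference population has median
    ``reference_median``), BH-adjusts the p-values within the cell, and
    reports the fraction below ``alpha`` plus the median per-trial total
    of animal observations.
    """
    if n_trials < 10:
        raise ValueError("n_trials must be >= 10 for a meaningful power estimate")
    results: List[PowerGridResult] = []
    root = np.random.SeedSequence(master_seed)
    cell_index = 0
    for design in designs:
        design = design.upper()
        for analysis in analyses:
            if design == "RSM" and analysis == "km_right":
                continue
            for size in sample_sizes:
                for effect in effect_medians:
                    cell_seed = np.random.SeedSequence(
                        entropy=root.entropy, spawn_key=(cell_index,)
                    )
                    cell_index += 1
                    children = cell_seed.spawn(n_trials)
                    pvals = []
                    obs_counts = []
                    for child in children:
                        rng = np.random.Generator(np.random.PCG64(child))
                        trial_t, data_t = _trial_datasets(
                            design, analysis, size, effect, s, interval, error, rng
                        )
                        _, data_r = _trial_datasets(
                            design,
                            analysis,
                            size,
                            reference_median,
                            s,
                            interval,
                            error,
                            rng,
                        )
                        pvals.append(
                            _cell_pvalue(analysis, data_t, data_r, n_perm, rng)
                        )
                        obs_counts.append(count_observations(trial_t))
                    adjusted = bh_adjust(pvals)
                    results.append(
                        PowerGridResult(
                            design=design,
                            analysis=analysis,
                            sample_size=int(size),
                            effect_median=float(effect),
                            power=power_from_pvalues(adjusted, alpha=alpha),
                            n_trials=n_trials,
                            alpha=alpha,
                            total_observations_median=float(np.median(obs_counts)),
                        )
                    )
    return results
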