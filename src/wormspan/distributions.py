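"""Parametric survival distributions for lifespan simulation and fitting.

Animals are generated by inverse-transform sampling from a closed-form
quantile function.  Three families are supported:

* logistic, parameterized by location ``mu`` (mean = median, days) and
  scale ``s`` (days); the reference wild-type population uses
  ``mu = 20, s = 2``,
* Gompertz, parameterized by a baseline mortality rate ``alpha`` (1/day)
  and a rate of aging ``beta`` (1/day), used as a mismatched generating
  model, and
* finite mixtures of the above, used to emulate accidentally mixed
  populations.

The logistic survival function is

    S(t) = 1 / (1 + exp((t - mu) / s))

and its quantile function, expressed in terms of the *survival*
probability ``p`` (the fraction still alive), is

    T(p) = s * ln(1/p - 1) + mu.

Because uniform draws are symmetric about 1/2, sampling through the
survival-quantile is distributionally identical to sampling through the
CDF-quantile.  A CDF-oriented quantile (`cdf_quantile`) is also exposed
for summaries such as the 99%-mortality time used to plan replica-set
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "LogisticParams",
    "GompertzParams",
    "MixtureSpec",
    "SurvivalDistribution",
    "logistic_survival",
    "logistic_quantile",
    "logistic_cdf",
    "gompertz_quantile",
    "gompertz_cdf",
    "gompertz_survival",
    "survival",
    "cdf",
    "cdf_quantile",
    "sample_death_times",
]


@dataclass(frozen=True)
class LogisticParams:
    """Location/scale parameters of a logistic lifespan distribution.

    ``mu`` is the mean (= median) lifespan in days; ``s`` controls the
    spread (slope of the survival curve at the median).
    """

    mu: float
    s: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or not np.isfinite(self.s):
            raise ValueError("logistic parameters must be finite")
        if self.s <= 0:
            raise ValueError(f"scale parameter s must be > 0, got {self.s}")


@dataclass(frozen=True)
class GompertzParams:
    """Two-parameter Gompertz mortality model.

    ``alpha`` is the baseline hazard at t = 0 (1/day) and ``beta`` the
    exponential rate of aging (1/day); the hazard is alpha * exp(beta*t).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Gompertz parameters alpha and beta must be > 0")


@dataclass(frozen=True)
class MixtureSpec:
    """Finite mixture of survival distributions.

    ``components`` is a sequence of ``(weight, distribution)`` pairs;
    weights must be non-negative and sum to 1.
    """

    components: tuple

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if len(comps) < 1:
            raise ValueError("mixture needs at least one component")
        weights = np.array([w for w, _ in comps], dtype=float)
        if np.any(weights < 0):
            raise ValueError("mixture weights must be non-negative")
        if not np.isclose(weights.sum(), 1.0, atol=1e-9):
            raise ValueError(f"mixture weights must sum to 1, got {weights.sum()}")

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for w, _ in self.components], dtype=float)


SurvivalDistribution = Union[LogisticParams, GompertzParams, MixtureSpec]


# ---------------------------------------------------------------------------
# logistic family


def logistic_survival(t, params: LogisticParams):
    """Survival probability S(t) = 1/(1 + e^((t-mu)/s)) of the logistic model."""
    t = np.asarray(t, dtype=float)
    u = (t - params.mu) / params.s
    out = expit(-u)
    return out if out.ndim else float(out)


def logistic_cdf(t, params: LogisticParams):
    """Cumulative death fraction F(t) = 1 - S(t)."""
    t = np.asarray(t, dtype=float)
    u = (t - params.mu) / params.s
    out = expit(u)
    return out if out.ndim else float(out)


def logistic_quantile(p_survival, params: LogisticParams):
    """Time at which a fraction ``p_survival`` of the population survives.

    T(p) = s * ln(1/p - 1) + mu; decreasing in ``p`` and the exact inverse
    of `logistic_survival`.
    """
    p = np.asarray(p_survival, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("survival probability must lie strictly in (0, 1)")
    out = params.s * np.log(1.0 / p - 1.0) + params.mu
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Gompertz family


def gompertz_cdf(t, params: GompertzParams):
    """Cumulative death fraction F(t) = 1 - exp((alpha/beta)(1 - e^(beta t)))."""
    t = np.asarray(t, dtype=float)
    out = 1.0 - np.exp((params.alpha / params.beta) * (1.0 - np.exp(params.beta * t)))
    return out if out.ndim else float(out)


def gompertz_survival(t, params: GompertzParams):
    """Survival probability 1 - F(t) of the Gompertz model."""
    t = np.asarray(t, dtype=float)
    out = np.exp((params.alpha / params.beta) * (1.0 - np.exp(params.beta * t)))
    return out if out.ndim else float(out)


def gompertz_quantile(p_death, params: GompertzParams):
    """Time by which a fraction ``p_death`` of the population has died.

    T(p) = ln(1 - (beta/alpha) * ln(1 - p)) / beta; increasing in ``p``
    with T(p -> 0) -> 0.
    """
    p = np.asarray(p_death, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("death probability must lie strictly in (0, 1)")
    out = np.log(1.0 - (params.beta / params.alpha) * np.log1p(-p)) / params.beta
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# generic dispatch


def survival(t, dist: SurvivalDistribution):
    """Survival function of any supported distribution (mixtures included)."""
    if isinstance(dist, LogisticParams):
        return logistic_survival(t, dist)
    if isinstance(dist, GompertzParams):
        return gompertz_survival(t, dist)
    if isinstance(dist, MixtureSpec):
        t = np.asarray(t, dtype=float)
        out = sum(w * np.asarray(survival(t, d)) for w, d in dist.components)
        out = np.asarray(out)
        return out if out.ndim else float(out)
    raise TypeError(f"unsupported distribution type: {type(dist)!r}")


def cdf(t, dist: SurvivalDistribution):
    """Cumulative death fraction of any supported distribution."""
    out = np.asarray(1.0 - np.asarray(survival(t, dist)))
    return out if out.ndim else float(out)


def cdf_quantile(p_death, dist: SurvivalDistribution):
    """Time by which a fraction ``p_death`` of the population has died.

    Closed form for logistic and Gompertz; numeric root-finding on the
    mixture CDF otherwise.  ``cdf_quantile(0.99, dist)`` is the "expected
    maximum lifespan" used to plan replica-set plate counts.
    """
    if isinstance(dist, LogisticParams):
        return logistic_quantile(np.asarray(1.0) - np.asarray(p_death), dist)
    if isinstance(dist, GompertzParams):
        return gompertz_quantile(p_death, dist)
    if isinstance(dist, MixtureSpec):
        scalar = np.asarray(p_death).ndim == 0
        ps = np.atleast_1d(np.asarray(p_death, dtype=float))
        if np.any((ps <= 0) | (ps >= 1)):
            raise ValueError("death probability must lie strictly in (0, 1)")
        # bracket using the most extreme component quantiles
        out = np.empty_like(ps)
        for i, p in enumerate(ps):
            los = [cdf_quantile(p, d) for _, d in dist.components]
            lo, hi = min(los) - 1.0, max(los) + 1.0
            out[i] = brentq(lambda t: cdf(t, dist) - p, lo, hi, xtol=1e-10)
        return out[0] if scalar else out
    raise TypeError(f"unsupported distribution type: {type(dist)!r}")


def _quantile_from_uniform(u: np.ndarray, dist) -> np.ndarray:
    """Death times from uniform(0,1) draws interpreted as CDF quantiles."""
    if isinstance(dist, LogisticParams):
        # survival-quantile at p = 1-u equals CDF-quantile at u
        return np.asarray(logistic_quantile(1.0 - u, dist))
    if isinstance(dist, GompertzParams):
        return np.asarray(gompertz_quantile(u, dist))
    raise TypeError(f"unsupported component type: {type(dist)!r}")


def sample_death_times(
    n: int, dist: SurvivalDistribution, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. death times by inverse-transform sampling.

    Uniform(0,1) draws are used as quantiles of the generating
    distribution.  For mixtures, each animal's component is chosen by
    weight first, then its death time drawn from that component; both
    decisions consume one uniform per animal so runs are reproducible
    under a fixed seed.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if isinstance(dist, MixtureSpec):
        comp_idx = rng.choice(len(dist.components), size=n, p=dist.weights)
        u = rng.random(n)
        out = np.empty(n, dtype=float)
        for j, (_, d) in enumerate(dist.components):
            mask = comp_idx == j
            if np.any(mask):
                out[mask] = _quantile_from_uniform(u[mask], d)
        return out
    u = rng.random(n)
    return _quantile_from_uniform(u, dist)
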