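"""Accuracy/precision summaries across trial sets and effort accounting.

Across a set of simulated trials the per-trial median lifespan estimates
are summarized by their median (location), standard error (precision)
and mean-squared error against the generating median (accuracy).  The
"total animal observations" of a trial — the number of times any animal
is assessed, a proxy for investigator effort — is the per-observation
sum of animals on the plate for the traditional method, and plates
scored times animals per plate for the replica-set method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from wormspan.simulate import RSMTrialResult, TLMTrialResult

__all__ = [
    "se_of_estimates",
    "mse_of_estimates",
    "count_observations",
    "TrialSetSummary",
    "summarize_trial_set",
]


@dataclass(frozen=True)
class TrialSetSummary:
    """Precision/accuracy summary of median-lifespan estimates."""

    n_trials: int
    median_of_medians: float
    se_median: float
    sd_median: float
    mse_median: float
    total_observations_median: Optional[float] = None

    def __post_init__(self) -> None:
        if self.se_median < 0 or self.mse_median < 0:
            raise ValueError("SE and MSE must be non-negative")


def se_of_estimates(estimates: Sequence[float]) -> float:
    """Standard error of the estimates: sample SD / sqrt(n)."""
    x = np.asarray(estimates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two estimates for a standard error")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def mse_of_estimates(estimates: Sequence[float], true_value: float) -> float:
    """Mean squared deviation of the estimates from the true value."""
    x = np.asarray(estimates, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one estimate")
    return float(np.mean((x - true_value) ** 2))


def count_observations(trial: Union[TLMTrialResult, RSMTrialResult]) -> int:
    """Total animal observations of one trial.

    Counts every assessment of every animal: for the traditional method
    an animal is counted at each observation until it is recorded dead
    and removed; for the replica set each scored plate contributes its
    full complement of animals.
    """
    if isinstance(trial, TLMTrialResult):
        return int(sum(o.n_live + o.n_dead for o in trial.observations))
    if isinstance(trial, RSMTrialResult):
        return int(
            sum(o.n_live + o.n_dead + o.n_censored for o in trial.observations)
        )
    raise TypeError(f"unsupported trial type: {type(trial)!r}")


def summarize_trial_set(
    medians: Sequence[float],
    true_value: float,
    observation_counts: Optional[Sequence[int]] = None,
) -> TrialSetSummary:
    """Summarize per-trial median estimates from one configuration cell."""
    x = np.asarray(medians, dtype=float)
    return TrialSetSummary(
        n_trials=int(x.size),
        median_of_medians=float(np.median(x)),
        se_median=se_of_estimates(x),
        sd_median=float(np.std(x, ddof=1)),
        mse_median=mse_of_estimates(x, true_value),
        total_observations_median=(
            float(np.median(observation_counts))
            if observation_counts is not None
            else None
        ),
    )
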