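"""Serialization: observation tables, interval TSVs, fit results, manifests.

All on-disk formats are plain text.  Observation tables are TSV with
columns (trial_id, design, time, n_live, n_dead, n_censored); interval
datasets are TSV with columns (left, right, weight) where ``right`` may
be the string ``inf`` for right-censored records.  Every simulation
output is accompanied by a JSON manifest echoing the configuration,
seed and software version, sufficient to regenerate the file exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from wormspan.distributions import (
    GompertzParams,
    LogisticParams,
    MixtureSpec,
    SurvivalDistribution,
)
from wormspan.estimate import FitResult, IntervalDataset
from wormspan.simulate import ErrorModel, RSMTrialResult, TLMTrialResult

__all__ = [
    "ExperimentConfig",
    "observations_to_frame",
    "write_observations_tsv",
    "read_observations_tsv",
    "trial_intervals_from_frame",
    "write_intervals_tsv",
    "read_intervals_tsv",
    "fit_result_to_dict",
    "write_manifest",
]

OBS_COLUMNS = ["trial_id", "design", "time", "n_live", "n_dead", "n_censored"]


# ---------------------------------------------------------------------------
# configuration


def distribution_from_dict(spec: dict) -> SurvivalDistribution:
    family = spec.get("family", "logistic").lower()
    if family == "logistic":
        return LogisticParams(mu=float(spec["mu"]), s=float(spec["s"]))
    if family == "gompertz":
        return GompertzParams(alpha=float(spec["alpha"]), beta=float(spec["beta"]))
    if family == "mixture":
        comps = tuple(
            (float(c["weight"]), distribution_from_dict(c["distribution"]))
            for c in spec["components"]
        )
        return MixtureSpec(components=comps)
    raise ValueError(f"unknown distribution family {family!r}")


def distribution_to_dict(dist: SurvivalDistribution) -> dict:
    if isinstance(dist, LogisticParams):
        return {"family": "logistic", "mu": dist.mu, "s": dist.s}
    if isinstance(dist, GompertzParams):
        return {"family": "gompertz", "alpha": dist.alpha, "beta": dist.beta}
    if isinstance(dist, MixtureSpec):
        return {
            "family": "mixture",
            "components": [
                {"weight": w, "distribution": distribution_to_dict(d)}
                for w, d in dist.components
            ],
        }
    raise TypeError(f"unsupported distribution type: {type(dist)!r}")


@dataclass
class ExperimentConfig:
    """Round-trippable description of one simulation configuration."""

    design: str
    distribution: SurvivalDistribution
    sample_size: int
    scoring_interval: float = 1.0
    error: ErrorModel = field(default_factory=ErrorModel)
    n_trials: int = 1
    master_seed: int = 0
    analyses: List[str] = field(default_factory=lambda: ["logistic"])

    def __post_init__(self) -> None:
        self.design = self.design.upper()
        if self.design not in ("TLM", "RSM"):
            raise ValueError(f"design must be TLM or RSM, got {self.design!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        valid = {"km_right", "npmle_interval", "logistic"}
        unknown = set(self.analyses) - valid
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(
            design=d["design"],
            distribution=distribution_from_dict(d["distribution"]),
            sample_size=int(d["sample_size"]),
            scoring_interval=float(d.get("scoring_interval", 1.0)),
            error=ErrorModel(**d.get("error", {})),
            n_trials=int(d.get("n_trials", 1)),
            master_seed=int(d.get("master_seed", 0)),
            analyses=list(d.get("analyses", ["logistic"])),
        )

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "distribution": distribution_to_dict(self.distribution),
            "sample_size": self.sample_size,
            "scoring_interval": self.scoring_interval,
            "error": dataclasses.asdict(self.error),
            "n_trials": self.n_trials,
            "master_seed": self.master_seed,
            "analyses": list(self.analyses),
        }


# ---------------------------------------------------------------------------
# observation tables


def observations_to_frame(
    trials: Sequence[Union[TLMTrialResult, RSMTrialResult]]
) -> pd.DataFrame:
    """Tidy table with one row per (trial, observation)."""
    rows = []
    for i, trial in enumerate(trials):
        for obs in trial.observations:
            rows.append(
                {
                    "trial_id": i,
                    "design": trial.design,
                    "time": obs.time,
                    "n_live": obs.n_live,
                    "n_dead": obs.n_dead,
                    "n_censored": obs.n_censored,
                }
            )
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def write_observations_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def _validate_observations(frame: pd.DataFrame) -> None:
    missing = set(OBS_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    if frame.empty:
        raise ValueError("observation table is empty")
    bad = frame[(frame[["n_live", "n_dead", "n_censored"]] < 0).any(axis=1)]
    if not bad.empty:
        raise ValueError(
            f"negative counts at lines {sorted((bad.index + 2).tolist())}"
        )
    if (frame["time"] < 0).any():
        bad = frame[frame["time"] < 0]
        raise ValueError(
            f"negative times at lines {sorted((bad.index + 2).tolist())}"
        )
    for trial_id, group in frame.groupby("trial_id"):
        t = group["time"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"trial {trial_id}: observation times must strictly increase"
            )


def read_observations_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    _validate_observations(frame)
    return frame


def trial_intervals_from_frame(
    group: pd.DataFrame, analysis: str
) -> IntervalDataset:
    """Censoring intervals for one trial's observation rows.

    TLM rows carry the per-observation death counts of a followed
    cohort: ``km_right`` takes deaths as exact events at the observation
    time, otherwise deaths fall in (previous observation, t].  RSM rows
    are current-status: deaths are (0, t] and live animals (t, inf).
    """
    design = str(group["design"].iloc[0]).upper()
    times = group["time"].to_numpy(dtype=float)
    n_dead = group["n_dead"].to_numpy(dtype=float)
    n_live = group["n_live"].to_numpy(dtype=float)
    if design == "TLM":
        if analysis == "km_right":
            mask = n_dead > 0
            return IntervalDataset.from_records(
                times[mask], times[mask], n_dead[mask]
            )
        step = times[1] - times[0] if len(times) > 1 else max(times[0], 1.0)
        prev = np.concatenate([[times[0] - step], times[:-1]])
        mask = n_dead > 0
        return IntervalDataset.from_records(prev[mask], times[mask], n_dead[mask])
    if analysis == "km_right":
        raise ValueError(
            "replica-set observations are current-status data; the "
            "right-censored Kaplan-Meier estimator is not applicable — "
            "use npmle_interval or logistic"
        )
    left, right, weight = [], [], []
    for t, nd, nl in zip(times, n_dead, n_live):
        if nd > 0:
            left.append(0.0)
            right.append(t)
            weight.append(nd)
        if nl > 0:
            left.append(t)
            right.append(np.inf)
            weight.append(nl)
    return IntervalDataset.from_records(left, right, weight)


# ---------------------------------------------------------------------------
# interval TSV and fit results


def write_intervals_tsv(data: IntervalDataset, path) -> None:
    frame = pd.DataFrame(
        {
            "left": data.left,
            "right": ["inf" if np.isinf(r) else r for r in data.right],
            "weight": data.weights,
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_intervals_tsv(path) -> IntervalDataset:
    frame = pd.read_csv(path, sep="\t")
    for col in ("left", "right", "weight"):
        if col not in frame.columns:
            raise ValueError(f"interval TSV missing column {col!r}")
    right = np.array(
        [np.inf if str(r).strip() == "inf" else float(r) for r in frame["right"]]
    )
    return IntervalDataset.from_records(
        frame["left"].to_numpy(dtype=float), right, frame["weight"].to_numpy(dtype=float)
    )


def fit_result_to_dict(result: FitResult) -> dict:
    d = dataclasses.asdict(result)
    return {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in d.items()}


def write_manifest(path, config: Optional[ExperimentConfig] = None, **extra) -> None:
    """JSON manifest sufficient to regenerate an output exactly."""
    from wormspan import __version__

    payload = {"software": "wormspan", "version": __version__}
    if config is not None:
        payload["config"] = config.to_dict()
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
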