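"""Synthetic associative-learning task generator.

A task presents ``n_cues`` one-hot cue vectors in round-robin order, each cue
bound to one outcome through a bijective base mapping.  On a fraction
``violation_prob`` of trials the observed outcome deviates from that mapping,
which is how stochasticity enters the task.  Outcomes come in two variants:

* ``categorical`` — the target is a one-hot vector over outcomes; a violation
  picks a different outcome uniformly at random.
* ``continuous`` — each cue maps to a distinct target level on a unit grid
  (cue ``i`` has level ``(i + 1) / n_cues``, placed in its mapped outcome
  slot), observed with additive Gaussian noise; a violation substitutes
  another cue's noiseless profile.

Everything is deterministic given ``TaskConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"

__all__ = [
    "CATEGORICAL",
    "CONTINUOUS",
    "ConfigError",
    "TaskConfig",
    "Trial",
    "TrialSequence",
    "base_mapping",
    "cue_levels",
    "noiseless_target",
    "generate_task",
]


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class TaskConfig:
    """Full specification of one synthetic associative-learning experiment.

    Parameters
    ----------
    n_cues, n_outcomes
        Number of cue units and outcome units.
    outcome_type
        ``"categorical"`` (one-hot targets) or ``"continuous"`` (graded
        target levels).
    violation_prob
        Per-trial probability that the outcome violates the bijective
        cue->outcome mapping.
    n_trials
        Number of learning trials.
    continuous_noise_sd
        Standard deviation of the Gaussian observation noise added to the
        target level (continuous variant only).
    compound_cues
        When True, every trial activates *all* cue units simultaneously
        (a compound stimulus) while the target still follows the round-robin
        schedule.  Off by default; used to probe multi-cue dynamics where
        the cue representations overlap.
    shuffle_cues
        When True, cue order is shuffled within each block of ``n_cues``
        trials instead of the default deterministic round-robin.
    seed
        Root seed; identical configs produce bit-identical sequences.
    """

    n_cues: int = 4
    n_outcomes: int = 4
    outcome_type: str = CATEGORICAL
    violation_prob: float = 0.1
    n_trials: int = 50
    continuous_noise_sd: float = 0.0
    compound_cues: bool = False
    shuffle_cues: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_cues, (int, np.integer)) and self.n_cues >= 1):
            raise ConfigError("n_cues", f"must be a positive integer, got {self.n_cues!r}")
        if not (isinstance(self.n_outcomes, (int, np.integer)) and self.n_outcomes >= 1):
            raise ConfigError("n_outcomes", f"must be a positive integer, got {self.n_outcomes!r}")
        if self.outcome_type not in (CATEGORICAL, CONTINUOUS):
            raise ConfigError(
                "outcome_type",
                f"must be {CATEGORICAL!r} or {CONTINUOUS!r}, got {self.outcome_type!r}",
            )
        if not (0.0 <= self.violation_prob <= 1.0):
            raise ConfigError("violation_prob", f"must lie in [0, 1], got {self.violation_prob!r}")
        if not (isinstance(self.n_trials, (int, np.integer)) and self.n_trials >= 0):
            raise ConfigError("n_trials", f"must be a non-negative integer, got {self.n_trials!r}")
        if self.continuous_noise_sd < 0:
            raise ConfigError(
                "continuous_noise_sd", f"must be non-negative, got {self.continuous_noise_sd!r}"
            )
        if (
            self.outcome_type == CATEGORICAL
            and self.violation_prob > 0
            and self.n_outcomes < 2
        ):
            raise ConfigError(
                "n_outcomes",
                "categorical violations need at least 2 outcomes so a violation "
                "can select a different outcome",
            )
        if (
            self.outcome_type == CONTINUOUS
            and self.violation_prob > 0
            and self.n_cues < 2
        ):
            raise ConfigError(
                "n_cues",
                "continuous violations substitute another cue's target profile "
                "and need at least 2 cues",
            )


@dataclass(frozen=True, eq=False)
class Trial:
    """One trial: cue-unit activities, the observed target, violation flag."""

    cue: np.ndarray
    target: np.ndarray
    is_violation: bool
    cue_index: int  # scheduled cue for this trial (round-robin position)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cue", np.asarray(self.cue, dtype=float))
        object.__setattr__(self, "target", np.asarray(self.target, dtype=float))


def base_mapping(config: TaskConfig) -> np.ndarray:
    """Base cue->outcome assignment: cue ``i`` maps to outcome ``i mod n_outcomes``.

    Bijective whenever ``n_cues == n_outcomes``, which is the standard design.
    """
    return np.arange(config.n_cues) % config.n_outcomes


def cue_levels(config: TaskConfig) -> np.ndarray:
    """Continuous target levels on a unit grid: cue ``i`` -> ``(i+1)/n_cues``."""
    return (np.arange(config.n_cues) + 1.0) / config.n_cues


def noiseless_target(config: TaskConfig, cue_index: int) -> np.ndarray:
    """The mapped (violation-free, noise-free) target vector for one cue."""
    mapping = base_mapping(config)
    target = np.zeros(config.n_outcomes)
    if config.outcome_type == CATEGORICAL:
        target[mapping[cue_index]] = 1.0
    else:
        target[mapping[cue_index]] = cue_levels(config)[cue_index]
    return target


@dataclass(frozen=True, eq=False)
class TrialSequence:
    """An ordered trial list plus the config and base mapping that produced it."""

    config: TaskConfig
    trials: tuple[Trial, ...]
    mapping: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mapping is None:
            object.__setattr__(self, "mapping", base_mapping(self.config))
        object.__setattr__(self, "mapping", np.asarray(self.mapping, dtype=int))
        object.__setattr__(self, "trials", tuple(self.trials))

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def violation_fraction(self) -> float:
        if not self.trials:
            return 0.0
        return float(np.mean([t.is_violation for t in self.trials]))

    # -- export / import ---------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for idx, trial in enumerate(self.trials):
            row: dict = {"trial_index": idx, "cue_index": trial.cue_index}
            for j, value in enumerate(trial.target):
                row[f"target_{j}"] = value
            row["is_violation"] = trial.is_violation
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: TaskConfig) -> "TrialSequence":
        """Rebuild a sequence from CSV; the config supplies cue geometry."""
        frame = pd.read_csv(path)
        target_cols = [f"target_{j}" for j in range(config.n_outcomes)]
        trials = []
        for _, row in frame.iterrows():
            cue_index = int(row["cue_index"])
            cue = _cue_vector(config, cue_index)
            target = row[target_cols].to_numpy(dtype=float)
            trials.append(Trial(cue, target, bool(row["is_violation"]), cue_index))
        return cls(config=config, trials=tuple(trials))

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "mapping": self.mapping.tolist(),
            "trials": [
                {
                    "cue": trial.cue.tolist(),
                    "target": trial.target.tolist(),
                    "is_violation": trial.is_violation,
                    "cue_index": trial.cue_index,
                }
                for trial in self.trials
            ],
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2)

    @classmethod
    def from_json(cls, path) -> "TrialSequence":
        with open(path) as handle:
            payload = json.load(handle)
        config = TaskConfig(**payload["config"])
        trials = tuple(
            Trial(
                np.asarray(t["cue"], dtype=float),
                np.asarray(t["target"], dtype=float),
                bool(t["is_violation"]),
                int(t["cue_index"]),
            )
            for t in payload["trials"]
        )
        return cls(config=config, trials=trials, mapping=np.asarray(payload["mapping"]))


def _cue_vector(config: TaskConfig, cue_index: int) -> np.ndarray:
    if config.compound_cues:
        return np.ones(config.n_cues)
    cue = np.zeros(config.n_cues)
    cue[cue_index] = 1.0
    return cue


def generate_task(config: TaskConfig, seed: int | None = None) -> TrialSequence:
    """Generate a deterministic trial sequence for ``config``.

    Trial ``tau`` presents cue ``tau mod n_cues`` (or a within-block shuffle
    when ``shuffle_cues`` is set).  Non-violation trials observe the mapped
    outcome; violation trials observe a uniformly chosen non-mapped outcome
    (categorical) or another cue's target profile (continuous).

    ``seed`` overrides ``config.seed`` when given.
    """
    if seed is not None:
        config = replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    mapping = base_mapping(config)
    levels = cue_levels(config)

    # cue presentation order, one full pass through the cues per block
    order = np.empty(config.n_trials, dtype=int)
    for start in range(0, config.n_trials, config.n_cues):
        block = np.arange(config.n_cues)
        if config.shuffle_cues:
            block = rng.permutation(block)
        take = min(config.n_cues, config.n_trials - start)
        order[start : start + take] = block[:take]

    trials = []
    for tau in range(config.n_trials):
        cue_index = int(order[tau])
        cue = _cue_vector(config, cue_index)
        is_violation = bool(rng.random() < config.violation_prob)

        if config.outcome_type == CATEGORICAL:
            if is_violation:
                others = np.delete(np.arange(config.n_outcomes), mapping[cue_index])
                outcome = int(rng.choice(others))
            else:
                outcome = int(mapping[cue_index])
            target = np.zeros(config.n_outcomes)
            target[outcome] = 1.0
        else:
            if is_violation:
                others = np.delete(np.arange(config.n_cues), cue_index)
                source = int(rng.choice(others))
            else:
                source = cue_index
            target = np.zeros(config.n_outcomes)
            slot = int(mapping[source])
            target[slot] = levels[source] + config.continuous_noise_sd * rng.standard_normal()

        trials.append(Trial(cue, target, is_violation, cue_index))

    return TrialSequence(config=config, trials=tuple(trials), mapping=mapping)
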