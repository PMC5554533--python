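"""Decay-augmented Hebbian and Widrow-Hoff (delta-rule) weight updates.

Both rules act on a cue-by-outcome weight matrix ``w_ij`` and share a linear
per-trial decay ``-d * w_ij`` applied to *every* weight, active or not — the
minimal modification that keeps pure Hebbian growth bounded.  The learning
terms differ:

* Hebbian:      ``dw_ij = -d * w_ij + k * a_i * a_j`` with the outcome-unit
  activity ``a_j`` clamped to the observed target ``t_j`` during learning
  (teacher forcing).  The rule never consults the network's prediction.
* Widrow-Hoff:  ``dw_ij = -d * w_ij + k * a_i * (t_j - sum_i' w_i'j a_i')``,
  i.e. Hebbian learning scaled by the raw (unnormalized) prediction error.

Parameter bounds: ``0 <= k < 1`` (learning rate) and ``0 < d <= 1`` (decay).
Updates are pure: they return a fresh :class:`WeightState` and never mutate
their inputs.  Decay and learning are evaluated simultaneously from the
pre-trial weights, one right-hand-side evaluation per trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tasks import ConfigError, Trial, TrialSequence

HEBBIAN = "hebbian"
WIDROW_HOFF = "widrow_hoff"

__all__ = [
    "HEBBIAN",
    "WIDROW_HOFF",
    "LearningParams",
    "WeightState",
    "ShapeError",
    "hebbian_update",
    "widrow_hoff_update",
    "update",
    "run_session",
    "trajectory_to_dataframe",
    "trajectory_to_csv",
]


class ShapeError(ValueError):
    """Raised when trial and weight dimensions disagree."""


@dataclass(frozen=True)
class LearningParams:
    """Learning rule selector plus its (k, d) parameters."""

    rule: str
    k: float
    d: float

    def __post_init__(self) -> None:
        if self.rule not in (HEBBIAN, WIDROW_HOFF):
            raise ConfigError("rule", f"must be {HEBBIAN!r} or {WIDROW_HOFF!r}, got {self.rule!r}")
        if not (0.0 <= self.k < 1.0):
            raise ConfigError("k", f"learning rate must satisfy 0 <= k < 1, got {self.k!r}")
        if not (0.0 < self.d <= 1.0):
            raise ConfigError("d", f"decay rate must satisfy 0 < d <= 1, got {self.d!r}")


@dataclass(frozen=True, eq=False)
class WeightState:
    """Immutable snapshot of the cue-by-outcome weight matrix.

    The stored array is a read-only copy, so states can be held in a
    trajectory without aliasing hazards.
    """

    weights: np.ndarray
    trial_index: int = 0

    def __post_init__(self) -> None:
        w = np.array(self.weights, dtype=float, copy=True)
        if w.ndim != 2:
            raise ShapeError(f"weights must be 2-D (n_cues x n_outcomes), got ndim={w.ndim}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @classmethod
    def zeros(cls, n_cues: int, n_outcomes: int) -> "WeightState":
        return cls(np.zeros((n_cues, n_outcomes)), trial_index=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape


def _check_dims(state: WeightState, trial: Trial) -> None:
    n_cues, n_outcomes = state.shape
    if trial.cue.shape != (n_cues,):
        raise ShapeError(
            f"cue length {trial.cue.shape[0]} does not match n_cues={n_cues}"
        )
    if trial.target.shape != (n_outcomes,):
        raise ShapeError(
            f"target length {trial.target.shape[0]} does not match n_outcomes={n_outcomes}"
        )


def hebbian_update(state: WeightState, trial: Trial, params: LearningParams) -> WeightState:
    """One Hebbian step: ``w' = w - d*w + k * outer(a, t)``.

    The outcome activity is clamped to the observed target (teacher forcing),
    so the update depends only on what was presented, never on what the
    network predicts.
    """
    if params.rule != HEBBIAN:
        raise ConfigError("rule", f"hebbian_update called with rule={params.rule!r}")
    _check_dims(state, trial)
    w = state.weights
    w_new = w - params.d * w + params.k * np.outer(trial.cue, trial.target)
    return WeightState(w_new, state.trial_index + 1)


def widrow_hoff_update(state: WeightState, trial: Trial, params: LearningParams) -> WeightState:
    """One delta-rule step: ``w' = w - d*w + k * outer(a, t - a @ w)``.

    The raw linear prediction ``a @ w`` (no normalization) enters the error
    term, so learning is gated by how wrong the current prediction is.
    """
    if params.rule != WIDROW_HOFF:
        raise ConfigError("rule", f"widrow_hoff_update called with rule={params.rule!r}")
    _check_dims(state, trial)
    w = state.weights
    prediction = trial.cue @ w
    w_new = w - params.d * w + params.k * np.outer(trial.cue, trial.target - prediction)
    return WeightState(w_new, state.trial_index + 1)


_UPDATES = {HEBBIAN: hebbian_update, WIDROW_HOFF: widrow_hoff_update}


def update(state: WeightState, trial: Trial, params: LearningParams) -> WeightState:
    """Dispatch to the update matching ``params.rule``."""
    return _UPDATES[params.rule](state, trial, params)


def run_session(
    sequence: TrialSequence,
    params: LearningParams,
    w0: WeightState | None = None,
) -> list[WeightState]:
    """Iterate the configured rule over a trial sequence.

    Returns the full weight trajectory ``[w0, w1, ..., w_T]`` of length
    ``n_trials + 1``.  Pure function of its arguments; defaults to an
    all-zero naive-learner start.
    """
    config = sequence.config
    if w0 is None:
        w0 = WeightState.zeros(config.n_cues, config.n_outcomes)
    if w0.shape != (config.n_cues, config.n_outcomes):
        raise ShapeError(
            f"w0 shape {w0.shape} does not match task ({config.n_cues}, {config.n_outcomes})"
        )
    step = _UPDATES[params.rule]
    trajectory = [w0]
    state = w0
    for trial in sequence:
        state = step(state, trial, params)
        trajectory.append(state)
    return trajectory


def trajectory_to_dataframe(trajectory: list[WeightState]) -> pd.DataFrame:
    """Long-format (trial, i, j, w) table of a weight trajectory."""
    rows = []
    for t, state in enumerate(trajectory):
        n_cues, n_outcomes = state.shape
        for i in range(n_cues):
            for j in range(n_outcomes):
                rows.append({"trial": t, "i": i, "j": j, "w": state.weights[i, j]})
    return pd.DataFrame(rows)


def trajectory_to_csv(trajectory: list[WeightState], path) -> None:
    trajectory_to_dataframe(trajectory).to_csv(path, index=False)
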