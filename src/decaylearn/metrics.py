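"""Population-level latent variables of a learning session.

These are the quantities a whole-population measurement (as opposed to a
single-unit recording) would be sensitive to:

* ``weight_change_magnitude`` — |dW|, the summed absolute per-synapse weight
  change on one trial.  Increases and decreases count alike, on the premise
  that both directions of synaptic change carry a metabolic cost.
* ``normalized_prediction`` — the network's outcome activations rectified and
  sum-normalized into a probability-like vector; an all-zero activation
  pattern falls back to the uniform vector and is flagged degenerate.
* ``pe_magnitude`` — |PE|, the summed absolute difference between the target
  and the normalized prediction; bounded by 2 for one-hot targets.
* ``classification_error`` — E, the post-learning summed absolute difference
  between each cue's normalized prediction and its noiseless mapped outcome.

``record_session`` runs a rule over a sequence and collects the per-trial
records, with |PE| always computed from the *pre-update* weights (the
prediction available on that trial, before learning).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .rules import LearningParams, ShapeError, WeightState, run_session
from .tasks import TaskConfig, TrialSequence, noiseless_target

__all__ = [
    "Prediction",
    "TrialRecord",
    "SessionTrace",
    "weight_change_magnitude",
    "normalized_prediction",
    "pe_magnitude",
    "classification_error",
    "record_session",
    "records_to_dataframe",
    "records_to_csv",
]


class Prediction(NamedTuple):
    """A normalized outcome-prediction vector plus its degeneracy flag."""

    probs: np.ndarray
    degenerate: bool


def _weights_of(state) -> np.ndarray:
    return state.weights if isinstance(state, WeightState) else np.asarray(state, dtype=float)


def weight_change_magnitude(w_prev, w_new) -> float:
    """|dW|: sum over synapses of the absolute one-trial weight change."""
    a = _weights_of(w_prev)
    b = _weights_of(w_new)
    if a.shape != b.shape:
        raise ShapeError(f"weight shapes differ: {a.shape} vs {b.shape}")
    return float(np.abs(b - a).sum())


def normalized_prediction(state, cue) -> Prediction:
    """Rectified, sum-normalized outcome activations for one cue vector.

    Raw activations ``a_j = sum_i a_i w_ij`` are clipped at zero (negative
    activation has no probability reading) and divided by their sum.  If the
    rectified sum is zero — e.g. an untrained network — the uniform vector is
    returned with ``degenerate=True``.
    """
    w = _weights_of(state)
    cue = np.asarray(cue, dtype=float)
    if cue.shape != (w.shape[0],):
        raise ShapeError(f"cue length {cue.shape} does not match n_cues={w.shape[0]}")
    raw = cue @ w
    rectified = np.clip(raw, 0.0, None)
    total = rectified.sum()
    if total == 0.0:
        n = w.shape[1]
        return Prediction(np.full(n, 1.0 / n), True)
    return Prediction(rectified / total, False)


def pe_magnitude(target, prediction) -> float:
    """|PE|: summed absolute difference between target and normalized prediction."""
    target = np.asarray(target, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    if target.shape != prediction.shape:
        raise ShapeError(f"target/prediction lengths differ: {target.shape} vs {prediction.shape}")
    return float(np.abs(target - prediction).sum())


def classification_error(state, config: TaskConfig) -> float:
    """E: summed per-cue, per-outcome absolute prediction error after learning.

    Each cue's normalized prediction is compared against its *noiseless*
    mapped outcome (the base bijection, ignoring violations), so E measures
    both what was learned and how resilient learning was to the noise.
    """
    w = _weights_of(state)
    if w.shape != (config.n_cues, config.n_outcomes):
        raise ShapeError(
            f"weights shape {w.shape} does not match task "
            f"({config.n_cues}, {config.n_outcomes})"
        )
    error = 0.0
    for c in range(config.n_cues):
        cue = np.zeros(config.n_cues)
        cue[c] = 1.0
        probs, _ = normalized_prediction(w, cue)
        error += float(np.abs(noiseless_target(config, c) - probs).sum())
    return error


@dataclass(frozen=True, eq=False)
class TrialRecord:
    """Per-trial latent variables: |dW|, |PE|, and the prediction that produced it."""

    trial_index: int
    delta_w_mag: float
    pe_mag: float
    prediction: np.ndarray
    degenerate: bool
    is_violation: bool


@dataclass(frozen=True, eq=False)
class SessionTrace:
    """The per-trial records of one session plus its final weight state."""

    records: tuple[TrialRecord, ...]
    final_state: WeightState

    def series(self, include_degenerate: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(|PE|, |dW|) series, optionally dropping degenerate-prediction trials."""
        records = self.records
        if not include_degenerate:
            records = tuple(r for r in records if not r.degenerate)
        pe = np.array([r.pe_mag for r in records])
        dw = np.array([r.delta_w_mag for r in records])
        return pe, dw


def record_session(
    sequence: TrialSequence,
    params: LearningParams,
    w0: WeightState | None = None,
) -> SessionTrace:
    """Run a session and record |PE| and |dW| on every trial.

    |PE| on trial tau uses the prediction made with the weights *before*
    that trial's update — the quantity available at stimulus onset.
    """
    trajectory = run_session(sequence, params, w0)
    records = []
    for tau, trial in enumerate(sequence):
        before, after = trajectory[tau], trajectory[tau + 1]
        probs, degenerate = normalized_prediction(before, trial.cue)
        records.append(
            TrialRecord(
                trial_index=tau,
                delta_w_mag=weight_change_magnitude(before, after),
                pe_mag=pe_magnitude(trial.target, probs),
                prediction=probs,
                degenerate=degenerate,
                is_violation=trial.is_violation,
            )
        )
    return SessionTrace(records=tuple(records), final_state=trajectory[-1])


def records_to_dataframe(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial": [r.trial_index for r in records],
            "delta_w_mag": [r.delta_w_mag for r in records],
            "pe_mag": [r.pe_mag for r in records],
            "degenerate": [r.degenerate for r in records],
            "is_violation": [r.is_violation for r in records],
        }
    )


def records_to_csv(records, path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)
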