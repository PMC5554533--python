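"""Numerical check of the single-cue Hebbian / Widrow-Hoff equivalence.

With a single, always-active cue the two rules collapse to scalar difference
equations that coincide exactly under the parameter mapping

    k_H = k_WH,    d_H = d_WH + k_WH,

because the delta rule's error term ``k*(t - w)`` splits into a Hebbian drive
``k*t`` plus an extra decay ``-k*w``.  Behaviour on a single-cue (parameter
estimation) task therefore cannot discriminate prediction-error learning from
decaying Hebbian learning.

With multiple cues the mapping breaks down: the delta rule's error involves
the *summed* prediction over all active cues, which no per-synapse Hebbian
term reproduces, and weights of momentarily inactive cues decay at d_WH under
one rule but d_WH + k_WH under the other.  :func:`verify_multi_cue` measures
that divergence; a compound-cue task (all cues active at once) is the
sharpest witness.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .rules import (
    HEBBIAN,
    WIDROW_HOFF,
    LearningParams,
    ShapeError,
    WeightState,
    run_session,
)
from .tasks import TrialSequence

SINGLE_CUE = "single_cue"
MULTI_CUE = "multi_cue"

__all__ = [
    "ParameterBoundError",
    "EquivalenceReport",
    "map_wh_to_hebbian",
    "verify_single_cue",
    "verify_multi_cue",
]


class ParameterBoundError(ValueError):
    """Raised when the mapped Hebbian decay would leave its admissible range."""


@dataclass(frozen=True)
class EquivalenceReport:
    """Mapped parameters and the trajectory divergence they produced."""

    k_wh: float
    d_wh: float
    k_h: float
    d_h: float
    max_abs_divergence: float
    n_trials: int
    setting: str

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2)


def map_wh_to_hebbian(k_wh: float, d_wh: float) -> tuple[float, float]:
    """Map Widrow-Hoff (k, d) to the Hebbian (k, d) that mimics it single-cue.

    Returns ``(k_wh, d_wh + k_wh)``; raises :class:`ParameterBoundError` when
    the mapped decay exceeds 1.
    """
    if not (0.0 <= k_wh < 1.0):
        raise ParameterBoundError(f"k_wh must satisfy 0 <= k < 1, got {k_wh!r}")
    if not (0.0 < d_wh <= 1.0):
        raise ParameterBoundError(f"d_wh must satisfy 0 < d <= 1, got {d_wh!r}")
    d_h = d_wh + k_wh
    if d_h > 1.0:
        raise ParameterBoundError(
            f"mapped Hebbian decay d_h = d_wh + k_wh = {d_h:.6g} violates 0 < d <= 1"
        )
    return float(k_wh), float(d_h)


def _trajectory_divergence(
    sequence: TrialSequence, k_wh: float, d_wh: float, w0: WeightState
) -> float:
    k_h, d_h = map_wh_to_hebbian(k_wh, d_wh)
    traj_wh = run_session(sequence, LearningParams(WIDROW_HOFF, k_wh, d_wh), w0)
    traj_h = run_session(sequence, LearningParams(HEBBIAN, k_h, d_h), w0)
    divergence = 0.0
    for s_wh, s_h in zip(traj_wh, traj_h):
        divergence = max(divergence, float(np.abs(s_wh.weights - s_h.weights).max()))
    return divergence


def _coerce_w0(sequence: TrialSequence, w0) -> WeightState:
    config = sequence.config
    if w0 is None:
        return WeightState.zeros(config.n_cues, config.n_outcomes)
    if isinstance(w0, WeightState):
        return w0
    w0 = np.asarray(w0, dtype=float)
    if w0.ndim == 0:
        w0 = np.full((config.n_cues, config.n_outcomes), float(w0))
    elif w0.ndim == 1 and config.n_cues == 1:
        w0 = w0.reshape(1, -1)
    return WeightState(w0)


def verify_single_cue(
    k_wh: float, d_wh: float, sequence: TrialSequence, w0=0.0
) -> EquivalenceReport:
    """Run both rules on a single-cue sequence and report their divergence.

    Under the parameter mapping the trajectories are algebraically identical;
    the reported divergence should sit at machine precision (<= 1e-12).
    ``w0`` may be a scalar, a vector over outcomes, or a WeightState.
    """
    if sequence.config.n_cues != 1:
        raise ShapeError(
            f"sequence has n_cues={sequence.config.n_cues}; "
            "use verify_multi_cue for multi-cue sequences"
        )
    state0 = _coerce_w0(sequence, w0)
    divergence = _trajectory_divergence(sequence, k_wh, d_wh, state0)
    k_h, d_h = map_wh_to_hebbian(k_wh, d_wh)
    return EquivalenceReport(
        k_wh=float(k_wh), d_wh=float(d_wh), k_h=k_h, d_h=d_h,
        max_abs_divergence=divergence, n_trials=len(sequence), setting=SINGLE_CUE,
    )


def verify_multi_cue(
    k_wh: float, d_wh: float, sequence: TrialSequence, w0=None
) -> EquivalenceReport:
    """Measure the divergence the single-cue mapping leaves on a multi-cue task.

    Any task in which more than one cue carries weight breaks the mapping:
    alternating one-hot cues already diverge (inactive rows decay at the
    wrong rate), and compound trials add the summed-prediction error term
    with no Hebbian counterpart.
    """
    if sequence.config.n_cues < 2:
        raise ShapeError("verify_multi_cue requires n_cues >= 2")
    state0 = _coerce_w0(sequence, w0)
    divergence = _trajectory_divergence(sequence, k_wh, d_wh, state0)
    k_h, d_h = map_wh_to_hebbian(k_wh, d_wh)
    return EquivalenceReport(
        k_wh=float(k_wh), d_wh=float(d_wh), k_h=k_h, d_h=d_h,
        max_abs_divergence=divergence, n_trials=len(sequence), setting=MULTI_CUE,
    )
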