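"""Population metrics: worked examples, brute-force oracles, bounds, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decaylearn import (
    LearningParams,
    ShapeError,
    TaskConfig,
    WeightState,
    classification_error,
    generate_task,
    normalized_prediction,
    pe_magnitude,
    record_session,
    weight_change_magnitude,
)


class TestWeightChangeMagnitude:
    def test_identical_states_give_zero(self):
        state = WeightState([[0.4, -0.1]])
        assert weight_change_magnitude(state, state) == 0.0

    def test_signed_changes_add_in_absolute_value(self):
        assert weight_change_magnitude([[0.0, 0.0]], [[0.3, -0.2]]) == pytest.approx(0.5)

    def test_matches_element_loop_oracle(self, rng):
        a = rng.normal(size=(4, 4))
        b = rng.normal(size=(4, 4))
        oracle = sum(abs(b[i, j] - a[i, j]) for i in range(4) for j in range(4))
        assert weight_change_magnitude(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeError):
            weight_change_magnitude(np.zeros((2, 2)), np.zeros((2, 3)))


class TestNormalizedPrediction:
    def test_symmetric_weights_normalize_to_uniform(self):
        probs, degenerate = normalized_prediction([[2.0, 2.0]], [1.0])
        assert np.allclose(probs, [0.5, 0.5])
        assert not degenerate

    def test_sum_normalization(self):
        probs, _ = normalized_prediction([[3.0, 1.0]], [1.0])
        assert np.allclose(probs, [0.75, 0.25])

    def test_zero_activation_falls_back_to_uniform_with_flag(self):
        probs, degenerate = normalized_prediction([[0.0, 0.0]], [1.0])
        assert np.allclose(probs, [0.5, 0.5])
        assert degenerate

    def test_negative_activations_are_rectified(self):
        probs, degenerate = normalized_prediction([[-1.0, 1.0]], [1.0])
        assert np.allclose(probs, [0.0, 1.0])
        assert not degenerate

    def test_probability_simplex(self, rng):
        for _ in range(20):
            w = rng.normal(size=(3, 5))
            cue = rng.normal(size=3)
            probs, _ = normalized_prediction(w, cue)
            assert probs.sum() == pytest.approx(1.0)
            assert np.all(probs >= 0) and np.all(probs <= 1)


class TestPEMagnitude:
    @pytest.mark.parametrize(
        "target, prediction, expected",
        [
            ([0, 1], [0, 1], 0.0),
            ([0, 1], [0.5, 0.5], 1.0),
            ([1, 0], [0, 1], 2.0),
        ],
    )
    def test_worked_examples(self, target, prediction, expected):
        assert pe_magnitude(target, prediction) == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(ShapeError):
            pe_magnitude([1.0, 0.0], [1.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        hot=st.integers(0, 3),
        raw=st.lists(st.floats(0, 10, allow_nan=False), min_size=4, max_size=4),
    )
    def test_bounded_by_two_for_one_hot_targets(self, hot, raw):
        target = np.zeros(4)
        target[hot] = 1.0
        raw = np.asarray(raw)
        prediction = raw / raw.sum() if raw.sum() > 0 else np.full(4, 0.25)
        assert 0.0 <= pe_magnitude(target, prediction) <= 2.0 + 1e-12


class TestClassificationError:
    def test_perfect_learner_has_zero_error(self):
        config = TaskConfig(violation_prob=0.0, seed=0)
        assert classification_error(np.eye(4) * 0.7, config) == pytest.approx(0.0)

    def test_untrained_network_uniform_fallback_arithmetic(self):
        # each cue contributes |1 - 1/4| + 3 * |0 - 1/4| = 1.5
        config = TaskConfig(seed=0)
        assert classification_error(np.zeros((4, 4)), config) == pytest.approx(6.0)

    def test_matches_per_cue_loop_oracle(self, rng):
        config = TaskConfig(seed=0)
        w = np.abs(rng.normal(size=(4, 4)))
        oracle = 0.0
        for c in range(4):
            row = w[c]
            probs = row / row.sum()
            for j in range(4):
                oracle += abs((1.0 if j == c else 0.0) - probs[j])
        assert classification_error(w, config) == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_joint_relabeling(self, rng):
        config = TaskConfig(seed=0)
        w = np.abs(rng.normal(size=(4, 4)))
        perm = rng.permutation(4)
        # permuting cues and outcomes jointly maps the bijection onto itself
        w_perm = w[np.ix_(perm, perm)]
        assert classification_error(w_perm, config) == pytest.approx(
            classification_error(w, config), abs=1e-12
        )


class TestRecordSession:
    def test_pe_uses_pre_update_weights(self, default_sequence):
        trace = record_session(default_sequence, LearningParams("hebbian", 0.3, 0.3))
        # trial 0 starts from zero weights: prediction degenerate uniform,
        # so |PE| = |1 - 1/4| + 3/4 = 1.5 regardless of the observed target
        assert trace.records[0].degenerate
        assert trace.records[0].pe_mag == pytest.approx(1.5)
        assert len(trace.records) == len(default_sequence)

    def test_first_presentation_of_each_cue_is_degenerate(self, default_sequence):
        trace = record_session(default_sequence, LearningParams("hebbian", 0.3, 0.3))
        degenerate = [r.degenerate for r in trace.records]
        assert degenerate[:4] == [True] * 4
        assert not any(degenerate[4:])

    def test_series_filtering_drops_degenerate_trials(self, default_sequence):
        trace = record_session(default_sequence, LearningParams("hebbian", 0.3, 0.3))
        pe_all, dw_all = trace.series(include_degenerate=True)
        pe_clean, dw_clean = trace.series(include_degenerate=False)
        assert len(pe_all) == 50 and len(pe_clean) == 46
        assert len(dw_all) == 50 and len(dw_clean) == 46

    def test_delta_w_matches_trajectory_differences(self, default_sequence):
        from decaylearn import run_session

        params = LearningParams("hebbian", 0.2, 0.4)
        trace = record_session(default_sequence, params)
        trajectory = run_session(default_sequence, params)
        for tau, record in enumerate(trace.records):
            expected = np.abs(
                trajectory[tau + 1].weights - trajectory[tau].weights
            ).sum()
            assert record.delta_w_mag == pytest.approx(expected, abs=1e-12)
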