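"""Classifier training/CV, rule-based baseline, movement and substage logic."""

import numpy as np
import pandas as pd
import pytest

from somnoscore.core import ACTIVE, NA, NREM, QUIET, REM, WAKE, Hypnogram
from somnoscore.features import FEATURE_COLUMNS
from somnoscore.staging import (
    MovementParams,
    cross_validate,
    heuristic_stage,
    load_model,
    movement_duration,
    predict_stages,
    save_model,
    split_wake_substages,
    train_classifier,
)

FS = 128.0


def separable_features(n_per_class=100, sep=10.0, seed=0):
    """Three well-separated Gaussian blobs in feature space, one per stage."""
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for i, stage in enumerate((WAKE, NREM, REM)):
        center = np.full(len(FEATURE_COLUMNS), i * sep)
        blocks.append(center + rng.normal(0, 1, (n_per_class, len(FEATURE_COLUMNS))))
        labels += [stage] * n_per_class
    feats = pd.DataFrame(np.vstack(blocks), columns=list(FEATURE_COLUMNS))
    return feats, np.array(labels)


class TestTrainPredict:
    def test_separable_classes_memorized(self):
        feats, labels = separable_features()
        model = train_classifier(feats, labels, seed=0)
        assert np.mean(predict_stages(model, feats) == labels) == 1.0

    def test_same_seed_same_predictions(self):
        feats, labels = separable_features()
        held, _ = separable_features(n_per_class=20, seed=99)
        a = predict_stages(train_classifier(feats, labels, seed=3), held)
        b = predict_stages(train_classifier(feats, labels, seed=3), held)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        feats, _ = separable_features(n_per_class=10)
        with pytest.raises(ValueError, match="two classes"):
            train_classifier(feats, np.full(30, NREM), seed=0)

    def test_label_count_mismatch_rejected(self):
        feats, labels = separable_features(n_per_class=10)
        with pytest.raises(ValueError, match="one label"):
            train_classifier(feats, labels[:-1], seed=0)

    def test_empty_table_predicts_empty(self):
        feats, labels = separable_features(n_per_class=10)
        model = train_classifier(feats, labels, seed=0)
        assert predict_stages(model, feats.iloc[:0]).size == 0

    def test_missing_feature_column_rejected(self):
        feats, labels = separable_features(n_per_class=10)
        model = train_classifier(feats, labels, seed=0)
        with pytest.raises(ValueError, match="lacks columns"):
            predict_stages(model, feats.drop(columns=["pfd"]))

    def test_save_load_round_trip(self, tmp_path):
        feats, labels = separable_features(n_per_class=20)
        model = train_classifier(feats, labels, seed=0)
        path = tmp_path / "model.bin"
        save_model(model, path)
        back = load_model(path)
        assert back.feature_order == model.feature_order
        assert np.array_equal(predict_stages(back, feats), predict_stages(model, feats))


class TestCrossValidate:
    def test_separable_data_near_perfect(self):
        feats, labels = separable_features()
        assert cross_validate(feats, labels, k=10, n_trees=50, seed=0) >= 0.99

    def test_shuffled_labels_hit_chance_level(self):
        # permutation null: balanced 3-class labels with no signal -> ~1/3
        feats, labels = separable_features(n_per_class=80, seed=1)
        accs = []
        for rep in range(20):
            shuffled = np.random.default_rng(rep).permutation(labels)
            accs.append(cross_validate(feats, shuffled, k=5, n_trees=25, seed=rep))
        assert np.mean(accs) == pytest.approx(1 / 3, abs=0.05)

    def test_leave_one_out_contract(self):
        feats, labels = separable_features(n_per_class=4)
        acc = cross_validate(feats, labels, k=len(labels), n_trees=10, seed=0)
        assert 0.0 <= acc <= 1.0

    def test_bad_k_rejected(self):
        feats, labels = separable_features(n_per_class=5)
        with pytest.raises(ValueError):
            cross_validate(feats, labels, k=1)


class TestHeuristicStage:
    def _row(self, motion_sd, delta, theta):
        return {"motion_sd": motion_sd, "delta_mean_amp": delta, "theta_mean_amp": theta}

    def test_high_motion_is_wake_regardless_of_spectrum(self):
        assert heuristic_stage(self._row(0.5, 100.0, 1.0), dominance_ratio=2.0) == WAKE

    def test_low_motion_delta_dominant_is_nrem(self):
        assert heuristic_stage(self._row(0.01, 50.0, 20.0), dominance_ratio=2.0) == NREM

    def test_low_motion_theta_dominant_is_rem(self):
        assert heuristic_stage(self._row(0.01, 10.0, 25.0), dominance_ratio=2.0) == REM

    def test_no_dominance_falls_back_to_wake(self):
        assert heuristic_stage(self._row(0.01, 20.0, 21.0), dominance_ratio=2.0) == WAKE


class TestMovementDuration:
    def test_flat_trace_zero(self):
        params = MovementParams(movement_threshold=0.05, smoothing_window_s=0.0)
        assert movement_duration(np.full(1024, 1.0), params, rate_hz=FS) == 0.0

    def test_pulse_counting_exact(self):
        x = np.zeros(1024)
        x[100:356] = 1.0  # 256 samples above threshold
        params = MovementParams(movement_threshold=0.5, smoothing_window_s=0.0)
        assert movement_duration(x, params, rate_hz=FS) == pytest.approx(2.0)

    def test_threshold_above_trace_zero(self):
        x = np.zeros(1024)
        x[100:356] = 1.0
        params = MovementParams(movement_threshold=2.0, smoothing_window_s=0.0)
        assert movement_duration(x, params, rate_hz=FS) == 0.0

    def test_gravity_offset_removed_by_median(self):
        # constant 1 G registers no movement even with a tiny threshold
        params = MovementParams(movement_threshold=0.01, smoothing_window_s=0.25)
        assert movement_duration(np.full(1024, 1.0), params, rate_hz=FS) == 0.0


class TestSplitWakeSubstages:
    def _motion(self, burst_s):
        x = np.zeros(1024)
        x[: int(burst_s * FS)] = 1.0
        return x

    def test_two_second_burst_is_active(self):
        params = MovementParams(movement_threshold=0.5, smoothing_window_s=0.0)
        h = split_wake_substages(
            np.array([WAKE]), self._motion(2.0)[None, :], params, rate_hz=FS)
        assert h.substages[0] == ACTIVE

    def test_half_second_burst_is_quiet(self):
        params = MovementParams(movement_threshold=0.5, smoothing_window_s=0.0)
        h = split_wake_substages(
            np.array([WAKE]), self._motion(0.5)[None, :], params, rate_hz=FS)
        assert h.substages[0] == QUIET

    def test_moving_nrem_epoch_stays_na(self):
        params = MovementParams(movement_threshold=0.5, smoothing_window_s=0.0)
        h = split_wake_substages(
            np.array([NREM]), self._motion(5.0)[None, :], params, rate_hz=FS)
        assert h.stages[0] == NREM and h.substages[0] == NA

    def test_substages_partition_wake(self, rng):
        stages = rng.choice([WAKE, NREM, REM], size=50)
        motion = rng.normal(0, 0.02, (50, 1024)) + 1.0
        params = MovementParams()
        h = split_wake_substages(stages, motion, params, rate_hz=FS)
        wake = h.stages == WAKE
        assert np.all(np.isin(h.substages[wake], [ACTIVE, QUIET]))
        assert np.all(h.substages[~wake] == NA)

    def test_raising_threshold_never_promotes_to_active(self, rng):
        stages = np.full(30, WAKE)
        motion = 1.0 + rng.normal(0, 0.02, (30, 1024))
        for i in range(30):
            dur = int(rng.uniform(0.2, 3.0) * FS)
            motion[i, :dur] += 0.3
        low = split_wake_substages(stages, motion, MovementParams(movement_threshold=0.1))
        high = split_wake_substages(stages, motion, MovementParams(movement_threshold=0.2))
        promoted = (low.substages == QUIET) & (high.substages == ACTIVE)
        assert not promoted.any()

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            split_wake_substages(np.array([WAKE, NREM]), np.zeros((1, 1024)),
                                 MovementParams())
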