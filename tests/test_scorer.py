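"""The recurrent deficit scorer: heads, training, CV, segmentation metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import reachscore as rs
from reachscore import grammar
from reachscore.scorer import DataError, predict_batch


class TestBuildAndPredict:
    def test_cumulative_head_shape_and_range(self, rng):
        model = rs.build_scorer(rs.ScorerArchitecture(
            n_features=6, lstm_units=8, head="cumulative"))
        x = rng.standard_normal((10, 6)).astype(np.float32)
        out = rs.predict_score(model, x)
        assert out.shape == (1,)
        assert out[0] >= 0  # ReLU output

    def test_categorical_head_votes_in_unit_interval(self, rng):
        model = rs.build_scorer(rs.ScorerArchitecture(
            n_features=6, lstm_units=8, head="categorical"))
        out = rs.predict_score(model, rng.standard_normal((10, 6)).astype(np.float32))
        assert out.shape == (2,)
        assert np.all((out > 0) & (out < 1))

    def test_elements_head_has_seven_outputs(self, rng):
        model = rs.build_scorer(rs.ScorerArchitecture(
            n_features=6, lstm_units=8, head="elements"))
        out = rs.predict_score(model, rng.standard_normal((10, 6)).astype(np.float32))
        assert out.shape == (7,)

    def test_zero_dropout_training_forward_equals_inference(self, rng):
        model = rs.build_scorer(rs.ScorerArchitecture(
            n_features=6, lstm_units=8, head="cumulative", dropout_rate=0.0))
        x = rng.standard_normal((1, 10, 6)).astype(np.float32)
        y_train, _ = model.net.forward(x, train=True,
                                       rng=np.random.default_rng(0))
        y_inf, _ = model.net.forward(x, train=False)
        assert np.array_equal(y_train, y_inf)

    def test_invalid_head_rejected(self):
        with pytest.raises(ValueError, match="head"):
            rs.ScorerArchitecture(head="nonsense")

    def test_shape_mismatch_is_geometry_error(self, rng):
        model = rs.build_scorer(rs.ScorerArchitecture(
            n_features=6, lstm_units=8))
        with pytest.raises(DataError, match="features"):
            rs.predict_score(model, rng.standard_normal((10, 9)).astype(np.float32))


class TestTraining:
    def test_loss_decreases_on_separable_cohort(self, tiny_cohort):
        """On clearly separated planted animals training MSE collapses."""
        model = rs.build_scorer(rs.ScorerArchitecture(
            n_features=64, lstm_units=32, head="cumulative"), seed=0)
        targets = rs.targets_for_head("cumulative", tiny_cohort.scores.df,
                                      tiny_cohort.clips)
        hyper = rs.TrainHyper(learning_rate=3e-3, batch_size=8, epochs=100,
                              weight_decay=3e-3, seed=0)
        rs.train_scorer(model, tiny_cohort.clips, targets, hyper)
        curve = model.manifest["loss_curve"]
        assert curve[-1] < curve[0]
        assert curve[-1] < 0.10 * curve[0]

    def test_training_is_seed_deterministic(self, tiny_cohort):
        targets = rs.targets_for_head("cumulative", tiny_cohort.scores.df,
                                      tiny_cohort.clips)
        hyper = rs.TrainHyper(learning_rate=1e-3, batch_size=8, epochs=5, seed=3)
        finals = []
        for _ in range(2):
            m = rs.build_scorer(rs.ScorerArchitecture(
                n_features=64, lstm_units=16, head="cumulative"), seed=1)
            rs.train_scorer(m, tiny_cohort.clips, targets, hyper)
            finals.append(m.manifest["loss_curve"][-1])
        assert finals[0] == finals[1]

    def test_constant_targets_drive_predictions_to_constant(self, tiny_cohort):
        model = rs.build_scorer(rs.ScorerArchitecture(
            n_features=64, lstm_units=16, head="cumulative"), seed=0)
        targets = np.full((len(tiny_cohort.clips), 1), 3.0, np.float32)
        hyper = rs.TrainHyper(learning_rate=1e-2, batch_size=8, epochs=40, seed=0)
        rs.train_scorer(model, tiny_cohort.clips, targets, hyper)
        preds = predict_batch(model, tiny_cohort.clips)
        assert np.allclose(preds, 3.0, atol=0.5)

    def test_misaligned_targets_rejected(self, tiny_cohort):
        model = rs.build_scorer(rs.ScorerArchitecture(
            n_features=64, lstm_units=8, head="cumulative"))
        with pytest.raises(DataError):
            rs.train_scorer(model, tiny_cohort.clips, np.zeros((3, 1)),
                            rs.TrainHyper(epochs=1))

    def test_trained_predictions_order_planted_severity(
            self, small_trained_scorer, tiny_cohort):
        """Mean prediction for a severe animal exceeds a control's."""
        preds = predict_batch(small_trained_scorer, tiny_cohort.clips)
        df = pd.DataFrame({
            "animal": [c.animal_id for c in tiny_cohort.clips],
            "group": [c.group for c in tiny_cohort.clips],
            "pred": preds[:, 0]})
        by_group = df.groupby("group")["pred"].mean()
        assert by_group[1] > by_group[0]


class TestNsc:
    @pytest.mark.parametrize("votes,expected", [
        ((1.0, 0.0), 1.0),   # confident stroke
        ((0.0, 1.0), 0.0),   # confident control
        ((0.6, 0.5), 0.55),
    ])
    def test_nsc_values(self, votes, expected):
        assert rs.compute_nsc(votes) == pytest.approx(expected)

    def test_out_of_range_votes_rejected(self):
        with pytest.raises(ValueError):
            rs.compute_nsc((1.2, 0.0))

    @given(n0=st.floats(0, 1), n1=st.floats(0, 1),
           d=st.floats(0.01, 0.5))
    @settings(deadline=None, max_examples=50)
    def test_nsc_bounds_and_monotonicity(self, n0, n1, d):
        v = rs.compute_nsc((n0, n1))
        assert 0.0 <= v <= 1.0
        if n0 + d <= 1:
            assert rs.compute_nsc((n0 + d, n1)) > v
        if n1 + d <= 1:
            assert rs.compute_nsc((n0, n1 + d)) < v


class TestCrossValidation:
    def test_folds_partition_all_trials(self, tiny_cohort):
        targets = rs.targets_for_head("cumulative", tiny_cohort.scores.df,
                                      tiny_cohort.clips)
        arch = rs.ScorerArchitecture(n_features=64, lstm_units=8,
                                     head="cumulative")
        hyper = rs.TrainHyper(learning_rate=1e-3, batch_size=8, epochs=2, seed=0)
        table = rs.crossvalidate(tiny_cohort.clips, targets, arch, hyper)
        df = table.df
        assert set(df["trial_id"]) == {c.trial_id for c in tiny_cohort.clips}
        assert df["trial_id"].is_unique
        assert df["fold"].nunique() == 4  # one fold per animal
        # fold hygiene: each trial predicted by the fold excluding its animal
        assert (df["fold"] == df["animal_id"]).all()

    def test_leave_one_day_out_folds_by_day(self, tiny_cohort):
        targets = rs.targets_for_head("cumulative", tiny_cohort.scores.df,
                                      tiny_cohort.clips)
        arch = rs.ScorerArchitecture(n_features=64, lstm_units=8,
                                     head="cumulative")
        hyper = rs.TrainHyper(learning_rate=1e-3, batch_size=8, epochs=2, seed=0)
        table = rs.crossvalidate(tiny_cohort.clips, targets, arch, hyper,
                                 scheme="leave_one_day_out")
        assert table.df["fold"].nunique() == 2
        assert (table.df["fold"] == table.df["day"].astype(str)).all()

    def test_single_unit_scheme_rejected(self, tiny_cohort):
        one_animal = [c for c in tiny_cohort.clips
                      if c.animal_id == "animal00"]
        with pytest.raises(ValueError, match=">= 2"):
            rs.crossvalidate(one_animal, np.zeros(len(one_animal)),
                             rs.ScorerArchitecture(n_features=64, lstm_units=8),
                             rs.TrainHyper(epochs=1))


class TestSegmentation:
    def test_window_count_is_floor_division(self, tiny_cohort):
        segs, onehot, classes = rs.make_segment_dataset(
            tiny_cohort.clips[:2], tiny_cohort.truth["timelines"], window=7)
        assert len(segs) == 2 * (40 // 7)
        assert onehot.shape == (len(segs), len(classes))
        assert np.all(onehot.sum(axis=1) == 1)

    def test_segment_movements_probabilities_sum_to_one(self, tiny_cohort):
        arch = rs.ScorerArchitecture(n_features=64, lstm_units=8,
                                     head="element_class")
        model = rs.build_scorer(arch, seed=0)
        model.manifest["epochs_run"] = 1  # untrained forward is enough here
        probs, timeline = rs.segment_movements(model, tiny_cohort.clips[0],
                                               window=7)
        assert probs.shape == (40 // 7, arch.n_classes)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert len(timeline) == 40 // 7

    def test_clip_shorter_than_window_rejected(self, tiny_cohort):
        arch = rs.ScorerArchitecture(n_features=64, lstm_units=8,
                                     head="element_class")
        model = rs.build_scorer(arch)
        short = rs.FeatureClip(features=np.zeros((3, 64), np.float32),
                               trial_id="s", encoder_tag="x")
        with pytest.raises(ValueError, match="window"):
            rs.segment_movements(model, short, window=7)


class TestSegmentationMetrics:
    def test_perfect_prediction_is_100_percent(self):
        tl = ["lift", "aim", "grasp", "eat"]
        m = rs.evaluate_segmentation(tl, tl, tolerance=1)
        assert m["accuracy"] == 100.0
        assert m["precision"] == 100.0
        assert m["recall"] == 100.0

    def test_one_category_shift_forgiven_only_with_tolerance(self):
        true = ["lift", "aim", "advance", "pronation"]
        pred = ["aim", "advance", "pronation", "grasp"]
        assert rs.evaluate_segmentation(pred, true, tolerance=1)["accuracy"] == 100.0
        assert rs.evaluate_segmentation(pred, true, tolerance=0)["accuracy"] == 0.0

    def test_hand_enumerated_three_window_toy(self):
        """Positions: lift=0 vs aim=1 (hit), aim=1 vs aim=1 (hit),
        grasp=4 vs supination II=6 (miss) -> accuracy 2/3."""
        true = ["lift", "aim", "grasp"]
        pred = ["aim", "aim", "supination_ii"]
        m = rs.evaluate_segmentation(pred, true, tolerance=1)
        assert m["accuracy"] == pytest.approx(100 * 2 / 3)

    def test_unknown_category_is_configuration_error(self):
        with pytest.raises(KeyError):
            rs.evaluate_segmentation(["lift"], ["warble"])
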