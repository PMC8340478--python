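"""Loss primitives, dense connectivity and the reference classifier."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slitscreen import phantom
from slitscreen.classifier import (
    FocalSpec,
    LensClassifier,
    SmoothingSpec,
    TrainConfig,
    cross_entropy,
    dense_connection_count,
    focal_loss,
    learning_rate_at,
    smooth_labels,
    smoothed_cross_entropy,
)
from slitscreen.nn import DenseBlock


class TestCrossEntropy:
    def test_perfect_one_hot_prediction(self):
        assert cross_entropy([1, 0], [1, 0]) == 0.0

    def test_uniform_prediction_of_one_hot_target(self):
        assert cross_entropy([1, 0], [0.5, 0.5]) == pytest.approx(math.log(2))

    def test_matches_brute_force_summation(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(4))
            q = rng.dirichlet(np.ones(4))
            expected = -sum(p[i] * math.log(q[i]) for i in range(4))
            assert cross_entropy(p, q) == pytest.approx(expected, abs=1e-12)

    def test_zero_predicted_mass_flags_infinity(self):
        assert cross_entropy([1, 0], [0, 1]) == float("inf")

    def test_invalid_probability_vectors_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy([0.5, 0.6], [0.5, 0.5])


class TestLabelSmoothing:
    @pytest.mark.parametrize(
        "eps,expected",
        [(0.0, [1.0, 0.0]), (0.1, [0.95, 0.05])],
    )
    def test_two_class_examples(self, eps, expected):
        out = smooth_labels(SmoothingSpec(epsilon=eps, n_classes=2, target_index=0))
        assert np.allclose(out, expected)

    @given(
        st.floats(min_value=0, max_value=0.999),
        st.integers(min_value=2, max_value=8),
    )
    @settings(derandomize=True, max_examples=50)
    def test_always_sums_to_one(self, eps, k):
        out = smooth_labels(SmoothingSpec(epsilon=eps, n_classes=k, target_index=k - 1))
        assert abs(out.sum() - 1.0) < 1e-12
        assert np.all(out >= 0)

    def test_epsilon_one_rejected(self):
        with pytest.raises(ValueError):
            SmoothingSpec(epsilon=1.0)


class TestSmoothedCrossEntropy:
    def test_no_smoothing_equals_plain_cross_entropy(self, rng):
        q = rng.dirichlet(np.ones(2))
        spec = SmoothingSpec(epsilon=0.0, n_classes=2, target_index=0)
        assert smoothed_cross_entropy(spec, q) == pytest.approx(
            cross_entropy([1, 0], q), abs=1e-15
        )

    def test_decomposition_identity_on_random_draws(self, rng):
        """H(p', q) equals (1-eps) H(one_hot, q) + eps H(uniform, q) to 1e-12,
        the two sides computed by independent routes."""
        for _ in range(100):
            k = int(rng.integers(2, 6))
            eps = float(rng.uniform(0, 0.999))
            target = int(rng.integers(0, k))
            q = rng.dirichlet(np.ones(k))
            spec = SmoothingSpec(epsilon=eps, n_classes=k, target_index=target)
            lhs = smoothed_cross_entropy(spec, q)
            one_hot = np.eye(k)[target]
            uniform = np.full(k, 1.0 / k)
            rhs = (1 - eps) * cross_entropy(one_hot, q) + eps * cross_entropy(uniform, q)
            assert abs(lhs - rhs) < 1e-12


class TestFocalLoss:
    def test_degenerates_to_cross_entropy_at_gamma_zero(self, rng):
        for p_t in rng.uniform(0.01, 1.0, size=20):
            fl = focal_loss(float(p_t), FocalSpec(alpha=1.0, gamma=0.0))
            assert fl == pytest.approx(-math.log(p_t), abs=1e-12)

    def test_perfectly_classified_example_contributes_nothing(self):
        for spec in (FocalSpec(), FocalSpec(alpha=3.0, gamma=0.5)):
            assert focal_loss(1.0, spec) == 0.0

    def test_half_confidence_closed_form(self):
        assert focal_loss(0.5, FocalSpec(alpha=1.0, gamma=2.0)) == pytest.approx(
            0.25 * math.log(2)
        )

    @given(st.floats(min_value=1e-6, max_value=1.0), st.floats(min_value=1e-6, max_value=1.0))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_decreasing_in_true_class_probability(self, a, b):
        lo, hi = min(a, b), max(a, b)
        spec = FocalSpec(alpha=0.25, gamma=2.0)
        assert focal_loss(lo, spec) >= focal_loss(hi, spec)

    def test_zero_probability_flags_infinity(self):
        assert focal_loss(0.0) == float("inf")
        assert focal_loss(0.5) >= 0


class TestDenseConnectivity:
    @pytest.mark.parametrize("layers,expected", [(1, 1), (3, 6), (10, 55)])
    def test_closed_form(self, layers, expected):
        assert dense_connection_count(layers) == expected

    @pytest.mark.parametrize("layers", range(1, 7))
    def test_matches_enumerated_concatenation_edges(self, layers):
        block = DenseBlock(in_ch=4, n_layers=layers, growth=2)
        assert len(block.concatenation_edges()) == dense_connection_count(layers)

    def test_invalid_layer_count(self):
        with pytest.raises(ValueError):
            dense_connection_count(0)


class TestSchedule:
    def test_reference_schedule_drops_at_30_and_60(self):
        cfg = TrainConfig.reference()
        assert learning_rate_at(0, cfg) == pytest.approx(0.01)
        assert learning_rate_at(31, cfg) == pytest.approx(0.001)
        assert learning_rate_at(61, cfg) == pytest.approx(0.0001)

    def test_scaled_budget_moves_drops_proportionally(self):
        cfg = TrainConfig(epochs=20)
        assert cfg.scaled_drop_epochs() == (2, 4)


class TestReferenceClassifier:
    def test_heldout_accuracy_on_separable_synthetic_crops(self, trained_classifier):
        crops, labels = phantom.in_pupil_crop_dataset(30, seed=99)
        predictions = trained_classifier.predict(crops)
        accuracy = np.mean([p == t for p, t in zip(predictions, labels)])
        assert accuracy >= 0.9

    def test_training_set_fit(self, trained_classifier):
        crops, labels = phantom.in_pupil_crop_dataset(30, seed=123)
        predictions = trained_classifier.predict(crops)
        assert np.mean([p == t for p, t in zip(predictions, labels)]) >= 0.9

    def test_inference_is_deterministic(self, trained_classifier):
        crop, _ = phantom.in_pupil_crop_dataset(1, seed=5)
        a = trained_classifier(crop[0])
        b = trained_classifier(crop[0])
        assert np.array_equal(a, b)
        assert a.sum() == pytest.approx(1.0)

    def test_training_is_seeded_and_reproducible(self):
        crops, labels = phantom.in_pupil_crop_dataset(6, seed=42)
        cfg = TrainConfig(epochs=2, batch_size=4, seed=3)
        m1 = LensClassifier(config=cfg).fit(crops, labels)
        m2 = LensClassifier(config=cfg).fit(crops, labels)
        assert m1.loss_trace_ == m2.loss_trace_

    def test_single_class_dataset_rejected(self):
        crops, _ = phantom.in_pupil_crop_dataset(3, seed=1)
        with pytest.raises(ValueError):
            LensClassifier(config=TrainConfig(epochs=1)).fit(
                crops, ["normal"] * len(crops)
            )

    def test_checkpoint_round_trip(self, trained_classifier, tmp_path):
        path = tmp_path / "model.npz"
        trained_classifier.save(path)
        loaded = LensClassifier.load(path)
        crops, _ = phantom.in_pupil_crop_dataset(2, seed=77)
        assert np.allclose(trained_classifier.predict_proba(crops),
                           loaded.predict_proba(crops))
        assert loaded.config == trained_classifier.config
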