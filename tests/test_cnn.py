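import dataclasses

import numpy as np
import pytest

from planim.augment import HAS_STENOSIS, NO_STENOSIS, LabelledImageSet
from planim.cnn import (
    CNNSpec,
    Model,
    aggregate_frame_votes,
    build_model,
    encode_labels,
    evaluate,
    evaluate_arrays,
    train,
)
from planim.errors import ValidationError

TINY = CNNSpec(conv_filters=(4, 8, 12, 16), input_size=48, dense_units=16, seed=0)


def _separable_data(n_per_class=20, size=48, seed=0):
    """Bright images = no stenosis, dark images = stenosis."""
    rng = np.random.default_rng(seed)
    dark = rng.uniform(0.0, 0.3, (n_per_class, size, size, 3))
    bright = rng.uniform(0.7, 1.0, (n_per_class, size, size, 3))
    x = np.concatenate([dark, bright]).astype(np.float32)
    y = np.array([0] * n_per_class + [1] * n_per_class)
    perm = rng.permutation(len(x))
    return x[perm], y[perm]


class TestBuildModel:
    def test_too_small_input_rejected(self):
        with pytest.raises(ValidationError):
            build_model(CNNSpec(input_size=8))

    def test_non_increasing_filters_rejected(self):
        with pytest.raises(ValidationError):
            CNNSpec(conv_filters=(32, 32, 64, 128))

    def test_two_builds_identical_shapes_and_weights(self):
        a, b = build_model(TINY), build_model(TINY)
        assert [p.shape for p in a.parameters] == [p.shape for p in b.parameters]
        assert all((pa == pb).all() for pa, pb in zip(a.parameters, b.parameters))

    def test_parameter_count_reported(self):
        model = build_model(TINY)
        assert model.n_params() == sum(p.size for p in model.parameters) > 0

    def test_output_probabilities_sum_to_one(self):
        model = build_model(TINY)
        x = np.random.default_rng(1).random((5, 48, 48, 3)).astype(np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (5, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-5)


class TestTrain:
    def test_learns_separable_data(self):
        x, y = _separable_data()
        model = build_model(dataclasses.replace(TINY, max_epochs=10, batch_size=20))
        history = train(model, x, y, x, y, seed=0)
        metrics = evaluate_arrays(model, x, y)
        assert metrics["accuracy"] == 1.0
        assert history["train_loss"][-1] < history["train_loss"][0]

    def test_zero_epochs_empty_history(self):
        x, y = _separable_data(4)
        model = build_model(dataclasses.replace(TINY, max_epochs=0))
        history = train(model, x, y, x, y)
        assert history["train_loss"] == []

    def test_reproducible_history(self):
        x, y = _separable_data(6)
        spec = dataclasses.replace(TINY, max_epochs=2)
        h1 = train(build_model(spec), x, y, x, y, seed=3)
        h2 = train(build_model(spec), x, y, x, y, seed=3)
        assert h1 == h2

    def test_single_class_training_rejected(self):
        x, _ = _separable_data(4)
        y = np.zeros(len(x), dtype=np.int64)
        with pytest.raises(ValidationError):
            train(build_model(TINY), x, y, x, y)

    def test_save_load_round_trip(self, tmp_path):
        x, y = _separable_data(4)
        model = build_model(TINY)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = Model.load(path)
        np.testing.assert_allclose(
            model.predict_proba(x), loaded.predict_proba(x), rtol=1e-6
        )


class TestEvaluate:
    def test_confusion_matrix_conserves_samples(self):
        x, y = _separable_data(5)
        model = build_model(TINY)
        m = evaluate_arrays(model, x, y)
        assert m["confusion"].sum() == len(y)
        assert m["accuracy"] == pytest.approx(np.trace(m["confusion"]) / len(y))

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_arrays(build_model(TINY), np.empty((0, 48, 48, 3)), np.empty(0))

    def test_evaluate_accepts_labelled_set(self):
        s = LabelledImageSet()
        rng = np.random.default_rng(0)
        for i in range(4):
            s.add(
                rng.integers(0, 256, (60, 60, 3), dtype=np.uint8),
                HAS_STENOSIS if i % 2 else NO_STENOSIS,
                f"v{i}",
            )
        m = evaluate(build_model(TINY), s)
        assert m["confusion"].sum() == 4


class TestAggregation:
    def test_majority_vote(self):
        assert aggregate_frame_votes(np.array([0, 0, 1])) == HAS_STENOSIS
        assert aggregate_frame_votes(np.array([1, 1, 0])) == NO_STENOSIS

    def test_tie_is_conservative(self):
        assert aggregate_frame_votes(np.array([0, 1])) == HAS_STENOSIS

    def test_label_encoding_order(self):
        assert encode_labels([HAS_STENOSIS, NO_STENOSIS]).tolist() == [0, 1]
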