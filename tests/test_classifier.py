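"""Compact CNN: architecture arithmetic, prediction contract, export."""

import numpy as np
import pytest

from echoscope import nn
from echoscope.classifier import (LayerSpec, ModelSpec, TrainConfig,
                                  build_classifier_spec, build_network,
                                  count_parameters, export_compact,
                                  load_compact, predict, propagate_shapes,
                                  train_classifier, TrainedClassifier)
from echoscope.dataset_prep import stratified_split

# The published layer table of the compact CNN: (kind, output shape, params).
REFERENCE_LAYER_TABLE = [
    ("input", (112, 170, 3), 0),
    ("conv2d", (56, 85, 56), 8288),
    ("batchnorm", (56, 85, 56), 224),
    ("relu", (56, 85, 56), 0),
    ("maxpool", (28, 43, 56), 0),
    ("spatial_dropout", (28, 43, 56), 0),
    ("conv2d", (14, 22, 72), 100872),
    ("batchnorm", (14, 22, 72), 288),
    ("relu", (14, 22, 72), 0),
    ("avgpool", (7, 11, 72), 0),
    ("spatial_dropout", (7, 11, 72), 0),
    ("conv2d", (7, 11, 56), 36344),
    ("batchnorm", (7, 11, 56), 224),
    ("relu", (7, 11, 56), 0),
    ("avgpool", (4, 6, 56), 0),
    ("spatial_dropout", (4, 6, 56), 0),
    ("conv2d", (4, 6, 72), 36360),
    ("batchnorm", (4, 6, 72), 288),
    ("relu", (4, 6, 72), 0),
    ("avgpool", (2, 3, 72), 0),
    ("spatial_dropout", (2, 3, 72), 0),
    ("flatten", (432,), 0),
    ("dense", (48,), 20784),
    ("batchnorm", (48,), 192),
    ("relu", (48,), 0),
    ("dropout", (48,), 0),
    ("dense", (8,), 392),
    ("softmax", (8,), 0),
]


class TestArchitectureArithmetic:
    def test_layer_table_reproduced_exactly(self):
        spec = build_classifier_spec()
        total, trainable, per_layer = count_parameters(spec)
        got = [(p["kind"], p["output_shape"], p["params"])
               for p in per_layer]
        assert got == REFERENCE_LAYER_TABLE
        assert total == 204_256
        assert trainable == 203_648
        assert total - trainable == 2 * (56 + 72 + 56 + 72 + 48)  # 608

    def test_flatten_size_is_432(self):
        shapes = propagate_shapes(build_classifier_spec())
        assert (432,) in shapes

    def test_dense_one_to_one(self):
        spec = ModelSpec((LayerSpec("input", shape=(1,)),
                          LayerSpec("dense", 1)), n_classes=1)
        assert count_parameters(spec)[0] == 2

    def test_discriminator_input_shares_flatten_width(self):
        """The 112x168 discriminator variant reaches the same 432 flatten."""
        spec = build_classifier_spec(input_shape=(112, 168, 3))
        assert (432,) in propagate_shapes(spec)
        assert count_parameters(spec)[0] == 204_256

    def test_unknown_layer_kind_rejected(self):
        spec = ModelSpec((LayerSpec("input", shape=(4,)),
                          LayerSpec("mystery")), n_classes=1)
        with pytest.raises(ValueError):
            propagate_shapes(spec)


@pytest.fixture(scope="module")
def model():
    """An untrained (randomly initialized) 8-class model."""
    spec = build_classifier_spec(n_classes=8)
    net = build_network(spec, np.random.default_rng(0))
    return TrainedClassifier(spec, net)


class TestPredict:
    def test_probabilities_on_simplex(self, model, rng):
        probs = model.predict(rng.random((5, 112, 170, 3),
                                         dtype=np.float32))
        assert probs.shape == (5, 8)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_functional_alias_and_single_image(self, model, rng):
        img = rng.random((112, 170, 3), dtype=np.float32)
        assert predict(model, img).shape == (1, 8)

    def test_wrong_shape_rejected(self, model, rng):
        with pytest.raises(ValueError):
            model.predict(rng.random((2, 64, 64, 3), dtype=np.float32))

    def test_softmax_shift_invariance(self, rng):
        logits = rng.normal(size=(10, 8))
        p1 = nn.softmax(logits)
        p2 = nn.softmax(logits + 123.4)
        np.testing.assert_allclose(p1, p2, atol=1e-9)
        np.testing.assert_array_equal(p1.argmax(axis=1), p2.argmax(axis=1))


class TestExportCompact:
    def test_lossless_roundtrip(self, model, rng):
        data, report = export_compact(model, quantize=False)
        assert report.before_bytes > 0
        restored = load_compact(data)
        x = rng.random((3, 112, 170, 3), dtype=np.float32)
        np.testing.assert_array_equal(model.predict(x), restored.predict(x))

    def test_quantized_export_smaller_and_close(self, model, rng):
        full, _ = export_compact(model, quantize=False)
        quant, report = export_compact(model, quantize=True)
        assert len(quant) < len(full)
        assert report.after_bytes < report.before_bytes
        restored = load_compact(quant)
        # int8 symmetric quantization bounds the per-weight error
        for w_full, w_q in zip(model.net.get_weights(),
                               restored.net.get_weights()):
            if w_full.ndim >= 2:
                scale = np.abs(w_full).max() / 127.0
                assert np.abs(w_full - w_q).max() <= 0.51 * scale + 1e-8


class TestTraining:
    def test_missing_class_rejected(self, tiny_images):
        images, labels = tiny_images
        spec = build_classifier_spec(n_classes=8)  # labels only cover 0-3
        split = stratified_split(labels, 0.2, 0.25, seed=0)
        with pytest.raises(ValueError, match="absent"):
            train_classifier(spec, split, images, labels,
                             TrainConfig(max_epochs=1))

    def test_single_class_training_predicts_that_class(self, rng):
        images = rng.random((10, 112, 170, 3), dtype=np.float32)
        labels = np.zeros(10, dtype=np.int64)
        split = stratified_split(labels, 0.2, 0.25, seed=0)
        spec = build_classifier_spec(n_classes=1)
        model, history = train_classifier(spec, split, images, labels,
                                          TrainConfig(max_epochs=2, seed=0))
        assert len(history["train_loss"]) >= 1
        assert history["train_loss"][-1] <= history["train_loss"][0] + 1e-6
        preds = model.predict(images[split.test_idx])
        assert np.all(preds.argmax(axis=1) == 0)

    def test_same_seed_reproduces_history(self, tiny_images):
        images, labels = tiny_images
        spec = build_classifier_spec(n_classes=4)
        split = stratified_split(labels, 0.2, 0.25, seed=1)
        cfg = TrainConfig(max_epochs=2, seed=5)
        _, h1 = train_classifier(spec, split, images, labels, cfg)
        _, h2 = train_classifier(spec, split, images, labels, cfg)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]
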