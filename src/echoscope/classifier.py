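"""The compact 204k-parameter CNN: declarative spec, training, inference.

The architecture is fixed and small enough for single-board edge computers:
four convolution blocks (conv + batchnorm + ReLU + pool + spatial dropout)
followed by a 48-unit dense block and an 8-way softmax. On a 112x170x3 mel
spectrogram image it has exactly 204,256 parameters (203,648 trainable; the
608 non-trainable ones are the batchnorm running statistics). Shape
propagation uses ceil-mode ``same`` pooling throughout, which is what maps
an 85-wide feature map to 43.

``ModelSpec`` is declarative: parameter counting and shape checking are
closed-form over the layer list, independent of the runtime network, so the
architecture arithmetic can be verified without instantiating weights.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = [
    "LayerSpec", "ModelSpec", "TrainConfig", "build_classifier_spec",
    "propagate_shapes", "count_parameters", "build_network",
    "TrainedClassifier", "train_classifier", "predict",
    "oversample_training", "export_compact", "load_compact", "SizeReport",
]


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a declarative model description."""

    kind: str
    filters: int | None = None      # conv filters or dense units
    kernel: tuple[int, int] | None = None
    stride: int = 1
    pool: int = 2
    padding: str = "same"
    rate: float = 0.0               # dropout rate / leaky-relu slope
    shape: tuple[int, ...] | None = None  # input / reshape target

    def __post_init__(self):
        if self.filters is not None and self.filters <= 0:
            raise ValueError("filters/units must be positive")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must lie in [0, 1]")


@dataclass(frozen=True)
class ModelSpec:
    layers: tuple[LayerSpec, ...]
    n_classes: int = 8

    @property
    def input_shape(self) -> tuple[int, ...]:
        return self.layers[0].shape


@dataclass(frozen=True)
class TrainConfig:
    """Reference training configuration: Adam, batch 8, learning rate 3e-3."""

    batch_size: int = 8
    learning_rate: float = 0.003
    optimizer: str = "adam"
    max_epochs: int = 100
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size >= 1 and learning_rate > 0 required")


def build_classifier_spec(input_shape: tuple[int, int, int] = (112, 170, 3),
                          n_classes: int = 8,
                          spatial_dropout: float = 0.05,
                          dense_dropout: float = 0.2) -> ModelSpec:
    """The fixed compact CNN: conv(56,7x7,s2) .. dense(48) .. softmax(8)."""
    def block(filters, kernel, stride, pool_kind):
        return [
            LayerSpec("conv2d", filters, kernel, stride),
            LayerSpec("batchnorm"),
            LayerSpec("relu"),
            LayerSpec(pool_kind),
            LayerSpec("spatial_dropout", rate=spatial_dropout),
        ]

    layers = [LayerSpec("input", shape=tuple(input_shape))]
    layers += block(56, (7, 7), 2, "maxpool")
    layers += block(72, (5, 5), 2, "avgpool")
    layers += block(56, (3, 3), 1, "avgpool")
    layers += block(72, (3, 3), 1, "avgpool")
    layers += [
        LayerSpec("flatten"),
        LayerSpec("dense", 48),
        LayerSpec("batchnorm"),
        LayerSpec("relu"),
        LayerSpec("dropout", rate=dense_dropout),
        LayerSpec("dense", n_classes),
        LayerSpec("softmax"),
    ]
    return ModelSpec(tuple(layers), n_classes)


def _ceil_div(a: int, b: int) -> int:
    return -(-a // b)


def propagate_shapes(spec: ModelSpec) -> list[tuple[int, ...]]:
    """Output shape after every layer (batch axis omitted)."""
    shapes: list[tuple[int, ...]] = []
    cur: tuple[int, ...] | None = None
    for lay in spec.layers:
        if lay.kind == "input":
            cur = lay.shape
        elif lay.kind in ("conv2d",):
            h, w, _ = cur
            cur = (_ceil_div(h, lay.stride), _ceil_div(w, lay.stride),
                   lay.filters)
        elif lay.kind == "conv2d_transpose":
            h, w, _ = cur
            cur = (h * lay.stride, w * lay.stride, lay.filters)
        elif lay.kind in ("maxpool", "avgpool"):
            h, w, c = cur
            cur = (_ceil_div(h, lay.pool), _ceil_div(w, lay.pool), c)
        elif lay.kind == "flatten":
            cur = (int(np.prod(cur)),)
        elif lay.kind == "reshape":
            if np.prod(lay.shape) != np.prod(cur):
                raise ValueError("reshape size mismatch")
            cur = lay.shape
        elif lay.kind == "dense":
            if len(cur) != 1:
                raise ValueError("dense requires a flat input")
            cur = (lay.filters,)
        elif lay.kind in ("batchnorm", "relu", "leaky_relu", "softmax",
                          "sigmoid", "dropout", "spatial_dropout"):
            pass
        else:
            raise ValueError(f"unknown layer kind {lay.kind!r}")
        shapes.append(cur)
    return shapes


def count_parameters(spec: ModelSpec) -> tuple[int, int, list[dict]]:
    """Exact closed-form parameter counts: (total, trainable, per-layer).

    conv: kh*kw*c_in*c_out + c_out; dense: n_in*n_out + n_out; batchnorm:
    4*c with 2*c non-trainable; everything else: 0.
    """
    shapes = propagate_shapes(spec)
    per_layer: list[dict] = []
    total = trainable = 0
    prev: tuple[int, ...] | None = None
    for lay, shape in zip(spec.layers, shapes):
        n = nt = 0
        if lay.kind in ("conv2d", "conv2d_transpose"):
            kh, kw = lay.kernel
            c_in = prev[-1]
            n = nt = kh * kw * c_in * lay.filters + lay.filters
        elif lay.kind == "dense":
            n = nt = prev[0] * lay.filters + lay.filters
        elif lay.kind == "batchnorm":
            c = shape[-1]
            n, nt = 4 * c, 2 * c
        per_layer.append({"kind": lay.kind, "output_shape": shape,
                          "params": n, "trainable": nt})
        total += n
        trainable += nt
        prev = shape
    return total, trainable, per_layer


def build_network(spec: ModelSpec, rng: np.random.Generator) -> nn.Sequential:
    """Instantiate a runtime network (softmax excluded; outputs are logits)."""
    shapes = propagate_shapes(spec)
    layers: list[nn.Layer] = []
    prev: tuple[int, ...] | None = None
    for lay, shape in zip(spec.layers, shapes):
        if lay.kind == "conv2d":
            layers.append(nn.Conv2D(prev[-1], lay.filters, lay.kernel,
                                    lay.stride, rng))
        elif lay.kind == "conv2d_transpose":
            layers.append(nn.ConvTranspose2D(prev[-1], lay.filters,
                                             lay.kernel, lay.stride, rng))
        elif lay.kind == "batchnorm":
            layers.append(nn.BatchNorm(shape[-1]))
        elif lay.kind == "relu":
            layers.append(nn.ReLU())
        elif lay.kind == "leaky_relu":
            layers.append(nn.LeakyReLU(lay.rate or 0.2))
        elif lay.kind == "sigmoid":
            layers.append(nn.Sigmoid())
        elif lay.kind == "maxpool":
            layers.append(nn.MaxPool2D(lay.pool))
        elif lay.kind == "avgpool":
            layers.append(nn.AvgPool2D(lay.pool))
        elif lay.kind == "dropout":
            layers.append(nn.Dropout(lay.rate, rng))
        elif lay.kind == "spatial_dropout":
            layers.append(nn.SpatialDropout2D(lay.rate, rng))
        elif lay.kind == "flatten":
            layers.append(nn.Flatten())
        elif lay.kind == "reshape":
            layers.append(nn.Reshape(lay.shape))
        elif lay.kind == "dense":
            layers.append(nn.Dense(prev[0], lay.filters, rng))
        elif lay.kind in ("input", "softmax"):
            pass
        prev = shape
    return nn.Sequential(layers)


@dataclass
class TrainedClassifier:
    """A spec plus its trained runtime network."""

    spec: ModelSpec
    net: nn.Sequential

    def logits(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        if tuple(images.shape[1:]) != tuple(self.spec.input_shape):
            raise ValueError(
                f"expected images of shape {self.spec.input_shape}, "
                f"got {images.shape[1:]}")
        return self.net.forward(images, training=False)

    def predict(self, images: np.ndarray,
                batch_size: int = 64) -> np.ndarray:
        """Class-probability vectors, one row per image."""
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        out = [nn.softmax(self.logits(images[i:i + batch_size]))
               for i in range(0, len(images), batch_size)]
        return np.concatenate(out)


def predict(model: TrainedClassifier, images: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`TrainedClassifier.predict`."""
    return model.predict(images)


def oversample_training(images: np.ndarray, labels: np.ndarray, split,
                        config=None, seed: int = 0):
    """SMOTE the training partition only; returns (images', labels', split').

    Synthetic samples are appended after the originals and added to the
    training index list; validation and test indices are untouched.
    """
    from .dataset_prep import smote_oversample, DatasetSplit

    tr_imgs, tr_labels = images[split.train_idx], labels[split.train_idx]
    new_imgs, new_labels = smote_oversample(tr_imgs, tr_labels, config, seed)
    n_orig, n_added = len(images), len(new_imgs) - len(tr_imgs)
    images2 = np.concatenate([images, new_imgs[len(tr_imgs):]])
    labels2 = np.concatenate([labels, new_labels[len(tr_labels):]])
    train_idx2 = np.concatenate([split.train_idx,
                                 np.arange(n_orig, n_orig + n_added)])
    counts = {c: (int((labels2[train_idx2] == c).sum()), v, t)
              for c, (_, v, t) in split.per_class_counts.items()}
    split2 = DatasetSplit(train_idx2, split.val_idx, split.test_idx,
                          counts, split.seed)
    return images2, labels2, split2


def _epoch_eval(net, images, labels, batch_size=64):
    losses, correct = [], 0
    for i in range(0, len(images), batch_size):
        logits = net.forward(images[i:i + batch_size], training=False)
        loss, _ = nn.sparse_softmax_xent(logits, labels[i:i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) ==
                        labels[i:i + batch_size]).sum())
    return float(np.sum(losses) / len(images)), correct / len(images)


def train_classifier(spec: ModelSpec, split, images: np.ndarray,
                     labels: np.ndarray, config: TrainConfig | None = None,
                     verbose: bool = False):
    """Train the CNN with Adam and early stopping on validation loss.

    ``images``/``labels`` hold the full dataset; the split's train and
    validation indices select the partitions (apply
    :func:`oversample_training` first if SMOTE balancing is wanted).
    Returns (model, history) where history has per-epoch train/validation
    loss and accuracy. Weights from the best validation epoch are restored.
    """
    config = config or TrainConfig()
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    tr_idx, va_idx = split.train_idx, split.val_idx
    present = np.unique(labels[tr_idx])
    if len(present) < spec.n_classes:
        missing = sorted(set(range(spec.n_classes)) - set(present.tolist()))
        raise ValueError(f"classes absent from training partition: {missing}")
    rng = np.random.default_rng(config.seed)
    net = build_network(spec, rng)
    opt = nn.Adam(net, lr=config.learning_rate)
    history = {"train_loss": [], "train_acc": [], "val_loss": [],
               "val_acc": []}
    best_val, best_weights, patience = np.inf, None, 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(tr_idx)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            batch = order[i:i + config.batch_size]
            logits = net.forward(images[batch], training=True)
            loss, dlogits = nn.sparse_softmax_xent(logits, labels[batch])
            net.backward(dlogits)
            opt.step()
            ep_loss += loss * len(batch)
            ep_correct += int((logits.argmax(axis=1) == labels[batch]).sum())
        val_loss, val_acc = _epoch_eval(net, images[va_idx], labels[va_idx])
        history["train_loss"].append(ep_loss / len(order))
        history["train_acc"].append(ep_correct / len(order))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if verbose:
            print(f"epoch {epoch + 1}: train_loss="
                  f"{history['train_loss'][-1]:.4f} val_loss={val_loss:.4f} "
                  f"val_acc={val_acc:.3f}")
        if val_loss < best_val - 1e-5:
            best_val, best_weights, patience = val_loss, net.get_weights(), 0
        else:
            patience += 1
            if patience >= config.early_stop_patience:
                break
    if best_weights is not None:
        net.set_weights(best_weights)
    return TrainedClassifier(spec, net), history


@dataclass
class SizeReport:
    before_bytes: int
    after_bytes: int

    @property
    def reduction_pct(self) -> float:
        return 100.0 * (1.0 - self.after_bytes / self.before_bytes)


def _spec_to_json(spec: ModelSpec) -> str:
    return json.dumps({"n_classes": spec.n_classes,
                       "layers": [asdict(lay) for lay in spec.layers]})


def _spec_from_json(text: str) -> ModelSpec:
    raw = json.loads(text)
    layers = []
    for d in raw["layers"]:
        for key in ("kernel", "shape"):
            if d[key] is not None:
                d[key] = tuple(d[key])
        layers.append(LayerSpec(**d))
    return ModelSpec(tuple(layers), raw["n_classes"])


def export_compact(model: TrainedClassifier,
                   quantize: bool = False) -> tuple[bytes, SizeReport]:
    """Serialize the model; optionally int8-quantize large weight tensors.

    Quantization is symmetric per-tensor (scale = max|w| / 127) on arrays
    with at least two dimensions; biases and batchnorm vectors stay float32.
    With ``quantize=False`` a round-trip through :func:`load_compact`
    reproduces bit-identical predictions.
    """
    weights = model.net.get_weights()
    arrays: dict[str, np.ndarray] = {"arch": np.frombuffer(
        _spec_to_json(model.spec).encode(), dtype=np.uint8)}
    for i, w in enumerate(weights):
        if quantize and w.ndim >= 2:
            scale = float(np.abs(w).max()) / 127.0 or 1.0
            arrays[f"q_{i}"] = np.round(w / scale).astype(np.int8)
            arrays[f"s_{i}"] = np.asarray(scale, dtype=np.float32)
        else:
            arrays[f"w_{i}"] = w.astype(np.float32)
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    data = buf.getvalue()
    before = sum(w.nbytes for w in weights) + len(arrays["arch"])
    return data, SizeReport(before_bytes=before, after_bytes=len(data))


def load_compact(data: bytes) -> TrainedClassifier:
    """Rebuild a model exported by :func:`export_compact`."""
    with np.load(io.BytesIO(data)) as archive:
        spec = _spec_from_json(bytes(archive["arch"]).decode())
        weights = []
        i = 0
        while True:
            if f"w_{i}" in archive:
                weights.append(archive[f"w_{i}"])
            elif f"q_{i}" in archive:
                weights.append(archive[f"q_{i}"].astype(np.float32)
                               * archive[f"s_{i}"])
            else:
                break
            i += 1
    net = build_network(spec, np.random.default_rng(0))
    net.set_weights(weights)
    return TrainedClassifier(spec, net)
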