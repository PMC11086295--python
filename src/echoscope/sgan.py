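"""Semi-supervised GAN built around the compact classifier.

The discriminator is the compact CNN itself with two heads sharing every
weight including the final 8-unit dense layer: C_out applies a softmax over
the class logits (supervised head, sparse cross-entropy on labeled samples),
while D_out squashes the same logits into a real/fake score
``D = Z / (Z + 1)`` with ``Z = sum_k exp(logit_k)`` — equivalently a sigmoid
of the logsumexp — trained with binary cross-entropy. The generator maps
100-dimensional standard-normal latents through a 15.2M-parameter dense
layer and two stride-2 transposed convolutions to a 112x168x3 image.

Per training step the discriminator is updated twice — once on real images
(D_out target 1, plus the supervised loss on the labeled subset) and once on
generator fakes (D_out target 0) — and the generator once, through the
frozen discriminator with D_out target 1.

The discriminator input is 112x168 rather than 112x170: real spectrogram
images are center-cropped two columns so the generator's stride-doubling
output shape can be fed back directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .classifier import (LayerSpec, ModelSpec, TrainedClassifier,
                         build_classifier_spec, build_network)

__all__ = [
    "SganConfig", "SganGenerator", "SganDiscriminator",
    "build_generator_spec", "d_out_activation", "crop_for_discriminator",
    "select_labeled", "sgan_train", "labeled_fraction_experiment",
]


@dataclass(frozen=True)
class SganConfig:
    latent_dim: int = 100
    labeled_fraction: float = 1.0
    epochs: int = 5
    batch_size: int = 8
    #: batch size for the generator pathway (fakes); None -> batch_size
    fake_batch_size: int | None = None
    d_lr: float = 0.001
    g_lr: float = 5e-5
    #: Adam beta1 for both players; 0.5 is the usual GAN stabilization
    adam_beta1: float = 0.5
    #: weight of the two D_out (real/fake) losses relative to the
    #: supervised C_out loss; the supervised task stays primary
    unsup_weight: float = 0.2
    leaky_slope: float = 0.2
    #: real-batch draws per epoch; None means one pass over the real set
    steps_per_epoch: int | None = None
    #: if True (default) the full real set feeds D_out; only the labeled
    #: subset feeds C_out. If False, unlabeled reals are not used at all.
    unlabeled_reals: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0 < self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must lie in (0, 1]")


def build_generator_spec(config: SganConfig | None = None) -> ModelSpec:
    """Latent -> 112x168x3 generator (dense 15.2M + two deconv blocks)."""
    config = config or SganConfig()
    slope = config.leaky_slope
    layers = (
        LayerSpec("input", shape=(config.latent_dim,)),
        LayerSpec("dense", 28 * 42 * 128),
        LayerSpec("leaky_relu", rate=slope),
        LayerSpec("reshape", shape=(28, 42, 128)),
        LayerSpec("conv2d_transpose", 128, (4, 4), 2),
        LayerSpec("leaky_relu", rate=slope),
        LayerSpec("conv2d_transpose", 128, (4, 4), 2),
        LayerSpec("leaky_relu", rate=slope),
        LayerSpec("conv2d", 3, (7, 7), 1),
        LayerSpec("sigmoid"),  # bound fakes to the [0, 1] image range
    )
    return ModelSpec(layers, n_classes=0)


def d_out_activation(logits: np.ndarray) -> np.ndarray:
    """Real/fake score D = Z/(Z+1), Z = sum(exp(logits)); in (0, 1)."""
    return nn.dout_score(np.atleast_2d(np.asarray(logits, dtype=np.float64)))


def crop_for_discriminator(images: np.ndarray,
                           width: int = 168) -> np.ndarray:
    """Center-crop image width (170 -> 168) for the modified discriminator."""
    w = images.shape[2]
    if w < width:
        raise ValueError(f"images narrower than {width}")
    off = (w - width) // 2
    return np.ascontiguousarray(images[:, :, off:off + width])


@dataclass
class SganGenerator:
    spec: ModelSpec
    net: nn.Sequential
    latent_dim: int

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Generate n fake images from standard-normal latents."""
        z = rng.standard_normal((n, self.latent_dim)).astype(np.float32)
        return self.net.forward(z, training=False)


class SganDiscriminator(TrainedClassifier):
    """Classifier wrapper exposing the unsupervised head as well."""

    def d_out(self, images: np.ndarray) -> np.ndarray:
        return nn.dout_score(self.logits(images))


def select_labeled(labels: np.ndarray, fraction: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Boolean mask marking the stratified labeled subset."""
    labels = np.asarray(labels)
    mask = np.zeros(labels.size, dtype=bool)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_keep = int(round(fraction * idx.size))
        if n_keep == 0:
            warnings.warn(f"labeled fraction {fraction} leaves class {cls} "
                          "without labeled samples", stacklevel=2)
        chosen = rng.choice(idx, size=n_keep, replace=False)
        mask[chosen] = True
    return mask


def sgan_train(config: SganConfig, images: np.ndarray, labels: np.ndarray,
               seed: int | None = None, val_images: np.ndarray | None = None,
               val_labels: np.ndarray | None = None, verbose: bool = False):
    """Train the SGAN; returns (discriminator, generator, history).

    ``images`` are 112x170x3 (or already 112x168x3) training images;
    ``labels`` their classes. A stratified ``labeled_fraction`` subset keeps
    its labels for the supervised head; the rest participates through D_out
    only (or not at all if ``unlabeled_reals`` is False). History logs the
    per-epoch mean of the three losses. When a validation set is supplied,
    per-epoch C_out validation accuracy is logged and the
    best-validation-epoch discriminator weights are restored at the end,
    as in the supervised trainer.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    if images.shape[2] != 168:
        images = crop_for_discriminator(images)
    if val_images is not None:
        val_images = crop_for_discriminator(
            np.asarray(val_images, dtype=np.float32))
        val_labels = np.asarray(val_labels, dtype=np.int64)
    n_classes = int(labels.max()) + 1
    d_spec = build_classifier_spec(input_shape=(112, 168, 3),
                                   n_classes=n_classes)
    g_spec = build_generator_spec(config)
    d_net = build_network(d_spec, rng)
    g_net = build_network(g_spec, rng)
    d_opt = nn.Adam(d_net, lr=config.d_lr, beta1=config.adam_beta1)
    g_opt = nn.Adam(g_net, lr=config.g_lr, beta1=config.adam_beta1)

    labeled_mask = select_labeled(labels, config.labeled_fraction, rng)
    pool = np.arange(len(images)) if config.unlabeled_reals \
        else np.flatnonzero(labeled_mask)
    bs = config.batch_size
    fbs = config.fake_batch_size or bs
    uw = config.unsup_weight
    steps = config.steps_per_epoch or -(-len(pool) // bs)
    history = {"d_loss_real": [], "d_loss_fake": [], "g_loss": []}
    if val_images is not None:
        history["val_acc"] = []
    best_acc, best_weights = -1.0, None

    for epoch in range(config.epochs):
        order = rng.permutation(pool)
        ep = {k: 0.0 for k in history}
        for step in range(steps):
            batch = order[(step * bs) % len(order):][:bs]
            if batch.size == 0:
                batch = rng.choice(pool, size=min(bs, len(pool)),
                                   replace=False)
            # --- discriminator on real images: D_out target 1 + C_out ---
            logits = d_net.forward(images[batch], training=True)
            loss_u, dl = nn.dout_bce(logits, 1.0, weight=uw)
            lab = labeled_mask[batch]
            if lab.any():
                # supervised loss at full strength (mean over the labeled
                # members); the labeled fraction controls diversity, not
                # gradient magnitude
                loss_s, dl_s = nn.sparse_softmax_xent(logits[lab],
                                                      labels[batch][lab])
                dl[lab] += dl_s
                loss_u += loss_s
            d_net.backward(dl)
            d_opt.step()
            ep["d_loss_real"] += loss_u
            # --- discriminator on generator fakes: D_out target 0 ---
            z = rng.standard_normal((fbs, config.latent_dim)).astype(np.float32)
            fakes = g_net.forward(z, training=True)
            logits = d_net.forward(fakes, training=True)
            loss_f, dl = nn.dout_bce(logits, 0.0, weight=uw)
            d_net.backward(dl)
            d_opt.step()
            ep["d_loss_fake"] += loss_f
            # --- generator through the frozen discriminator: target 1 ---
            # (the same fake batch is reused; the generator's forward caches
            # from the discriminator step are still valid)
            logits = d_net.forward(fakes, training=True)
            loss_g, dl = nn.dout_bce(logits, 1.0)
            d_images_grad = d_net.backward(dl)  # discriminator not stepped
            g_net.backward(d_images_grad)
            g_opt.step()
            ep["g_loss"] += loss_g
        for k in ep:
            history[k].append(ep[k] / steps)
        if val_images is not None:
            preds = d_net.forward(val_images, training=False).argmax(axis=1)
            acc = float((preds == val_labels).mean())
            history["val_acc"].append(acc)
            if acc > best_acc:
                best_acc, best_weights = acc, d_net.get_weights()
        if verbose:
            print(f"epoch {epoch + 1}: " +
                  " ".join(f"{k}={history[k][-1]:.4f}" for k in history))
    if best_weights is not None:
        d_net.set_weights(best_weights)
    return (SganDiscriminator(d_spec, d_net),
            SganGenerator(g_spec, g_net, config.latent_dim), history)


def labeled_fraction_experiment(fractions, train_images, train_labels,
                                test_images, test_labels,
                                config: SganConfig | None = None,
                                seed: int = 0) -> list[dict]:
    """One SGAN run per labeled fraction on identical data; returns a table.

    Each row records the fraction, C_out test accuracy and macro F1. The
    rows use the same seed and the same train/validation/test data, so
    differences are attributable to the labeled fraction alone. A
    stratified 20% of the training pool is carved out once as a shared
    validation set for best-epoch selection within each run.
    """
    from dataclasses import replace
    from .evaluation import evaluate

    base = config or SganConfig()
    train_labels = np.asarray(train_labels, dtype=np.int64)
    rng = np.random.default_rng(seed)
    val_mask = select_labeled(train_labels, 0.2, rng)
    tr, va = ~val_mask, val_mask
    rows = []
    for frac in fractions:
        cfg = replace(base, labeled_fraction=float(frac), seed=seed)
        disc, _, _ = sgan_train(cfg, train_images[tr], train_labels[tr],
                                val_images=train_images[va],
                                val_labels=train_labels[va])
        report = evaluate(disc, crop_for_discriminator(test_images),
                          test_labels)
        rows.append({"labeled_fraction": float(frac),
                     "accuracy": report.accuracy,
                     "macro_f1": report.macro_f1})
    return rows
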