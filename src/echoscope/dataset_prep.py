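"""Stratified train/validation/test splitting and SMOTE oversampling.

The split preserves per-class proportions: for each class, the test set gets
``round(test_frac * n_c)`` samples and the validation set
``round(val_frac * remainder)``, with nearest-integer (half-up) rounding —
per-class counts are therefore within one sample of the exact fractions.

SMOTE (synthetic minority oversampling) raises every class to the size of
the largest class by interpolating between a minority sample and one of its
k nearest same-class neighbors: ``x = x_i + u * (x_nn - x_i)``, u ~ U[0, 1).
Applied to flattened spectrogram images this stays inside [0, 1]^d, so every
synthetic vector is itself a valid image. Oversampling is meant for the
training partition only; validation and test sets are never touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["DatasetSplit", "SmoteConfig", "stratified_split",
           "smote_oversample"]


@dataclass
class DatasetSplit:
    """Index-level partition of a labeled dataset."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    per_class_counts: dict[int, tuple[int, int, int]]  # class -> (train, val, test)
    seed: int

    def validate(self, n_samples: int) -> None:
        all_idx = np.concatenate([self.train_idx, self.val_idx,
                                  self.test_idx])
        if len(np.unique(all_idx)) != n_samples or len(all_idx) != n_samples:
            raise ValueError("partitions must be disjoint and cover all samples")


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    target_count: int | str = "max"  # every class raised to this count

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(labels, test_frac: float = 0.10,
                     val_frac_of_remainder: float = 0.20,
                     seed: int = 0) -> DatasetSplit:
    """Per-class stratified split into train/validation/test index lists.

    ``test_frac`` is taken from each class first; ``val_frac_of_remainder``
    is then taken from what is left. Deterministic given ``seed``. Classes
    too small to populate all three partitions are allocated with test
    priority and a warning.
    """
    if not (0 < test_frac < 1 and 0 < val_frac_of_remainder < 1):
        raise ValueError("fractions must lie in (0, 1)")
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    counts: dict[int, tuple[int, int, int]] = {}
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = idx.size
        n_test = min(_round_half_up(test_frac * n), n)
        n_val = min(_round_half_up(val_frac_of_remainder * (n - n_test)),
                    n - n_test)
        n_train = n - n_test - n_val
        if min(n_test, n_val, n_train) == 0:
            warnings.warn(
                f"class {cls} has too few samples ({n}) for all three "
                "partitions; allocating with test priority", stacklevel=2)
            if n_test == 0 and n > 0:
                n_test, n_train = 1, max(n_train - 1, 0)
                n_val = n - n_test - n_train
        test.append(idx[:n_test])
        val.append(idx[n_test:n_test + n_val])
        train.append(idx[n_test + n_val:])
        counts[int(cls)] = (n_train, n_val, n_test)
    split = DatasetSplit(np.concatenate(train), np.concatenate(val),
                         np.concatenate(test), counts, seed)
    split.validate(labels.size)
    return split


def smote_oversample(features: np.ndarray, labels, config: SmoteConfig | None = None,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts by convex same-class interpolation.

    Input features of any shape are flattened per sample for neighbor
    search and interpolation, then restored. Originals are preserved
    unchanged and come first in the output; synthetic samples are appended.
    A one-sample class cannot be interpolated and falls back to duplication
    with a warning; for classes smaller than ``k_neighbors + 1`` the
    neighbor count is reduced to ``class_size - 1``.
    """
    config = config or SmoteConfig()
    features = np.asarray(features)
    labels = np.asarray(labels)
    flat = features.reshape(features.shape[0], -1)
    class_counts = {int(c): int((labels == c).sum()) for c in np.unique(labels)}
    target = (max(class_counts.values()) if config.target_count == "max"
              else int(config.target_count))
    rng = np.random.default_rng(seed)
    new_feats, new_labels = [features], [labels]
    for cls, n_c in class_counts.items():
        n_need = target - n_c
        if n_need <= 0:
            continue
        idx = np.flatnonzero(labels == cls)
        x = flat[idx]
        if n_c == 1:
            warnings.warn(f"class {cls} has a single sample; duplicating "
                          "instead of interpolating", stacklevel=2)
            synth = np.repeat(x, n_need, axis=0)
        else:
            k = min(config.k_neighbors, n_c - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
            neigh = nn.kneighbors(x, return_distance=False)[:, 1:]
            base = rng.integers(0, n_c, n_need)
            pick = neigh[base, rng.integers(0, k, n_need)]
            u = rng.random((n_need, 1))
            synth = x[base] + u * (x[pick] - x[base])
        new_feats.append(synth.reshape((n_need,) + features.shape[1:])
                         .astype(features.dtype))
        new_labels.append(np.full(n_need, cls, dtype=labels.dtype))
    return np.concatenate(new_feats), np.concatenate(new_labels)
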