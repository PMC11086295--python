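"""Per-class metrics, confusion matrices, and one-vs-one ROC analysis.

F1 is the harmonic mean 2PR/(P+R) of precision and recall; the headline
score is the unweighted (macro) mean over classes, the conservative choice
for imbalanced data. "Pairwise ROC" is one-vs-one: for each unordered class
pair (a, b) only samples of those two classes are kept and scored with the
renormalized probability p_a / (p_a + p_b); the AUC is the Mann-Whitney rank
statistic with half-credit for ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = ["EvalReport", "confusion_matrix", "precision_recall_f1",
           "pairwise_roc_auc", "evaluate"]


@dataclass
class EvalReport:
    per_class: dict[int, dict[str, float]]  # class -> precision/recall/f1
    macro_f1: float
    accuracy: float
    confusion: np.ndarray
    normalized_confusion: np.ndarray
    pairwise_auc: dict[tuple[int, int], float | None]

    def to_json(self) -> str:
        return json.dumps({
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "normalized_confusion": self.normalized_confusion.tolist(),
            "pairwise_auc": {f"{a},{b}": v
                             for (a, b), v in self.pairwise_auc.items()},
        })

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        raw = json.loads(text)
        return cls(
            per_class={int(k): v for k, v in raw["per_class"].items()},
            macro_f1=raw["macro_f1"],
            accuracy=raw["accuracy"],
            confusion=np.asarray(raw["confusion"]),
            normalized_confusion=np.asarray(raw["normalized_confusion"]),
            pairwise_auc={tuple(map(int, k.split(","))): v
                          for k, v in raw["pairwise_auc"].items()},
        )


def confusion_matrix(y_true, y_pred, n_classes: int,
                     normalize: bool = False) -> np.ndarray:
    """Entry (i, j) counts true-class-i samples predicted as class j.

    With ``normalize`` rows are divided by their sums (empty rows stay 0).
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside "
                             f"[0, {n_classes})")
    mat = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(mat, (y_true, y_pred), 1)
    if normalize:
        sums = mat.sum(axis=1, keepdims=True)
        return np.divide(mat, sums, out=np.zeros(mat.shape), where=sums > 0)
    return mat


def precision_recall_f1(confusion: np.ndarray) -> dict[int, dict[str, float]]:
    """Per-class precision, recall and F1 from a count confusion matrix.

    Zero denominators (a class never predicted or absent) yield 0.
    """
    confusion = np.asarray(confusion, dtype=np.float64)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion must be a square count matrix")
    tp = np.diag(confusion)
    pred_tot = confusion.sum(axis=0)
    true_tot = confusion.sum(axis=1)
    out = {}
    for c in range(confusion.shape[0]):
        p = tp[c] / pred_tot[c] if pred_tot[c] > 0 else 0.0
        r = tp[c] / true_tot[c] if true_tot[c] > 0 else 0.0
        f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        out[c] = {"precision": float(p), "recall": float(r), "f1": float(f1)}
    return out


def _rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC with half-credit ties via midranks."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    ranks = rankdata(scores)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pairwise_roc_auc(y_true, probabilities) -> dict[tuple[int, int], float | None]:
    """One-vs-one AUC for every unordered class pair.

    For pair (a, b), samples of the two classes are scored with
    ``p_a / (p_a + p_b)`` and class a is the positive. Pairs with an empty
    class are reported as None.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    probs = np.asarray(probabilities, dtype=np.float64)
    n_classes = probs.shape[1]
    out: dict[tuple[int, int], float | None] = {}
    for a in range(n_classes):
        for b in range(a + 1, n_classes):
            keep = (y_true == a) | (y_true == b)
            if not ((y_true == a).any() and (y_true == b).any()):
                out[(a, b)] = None
                continue
            pa, pb = probs[keep, a], probs[keep, b]
            denom = pa + pb
            score = np.divide(pa, denom, out=np.full(pa.shape, 0.5),
                              where=denom > 0)
            out[(a, b)] = _rank_auc(score, y_true[keep] == a)
    return out


def evaluate(model, test_images, test_labels) -> EvalReport:
    """Run the model on a held-out test set and assemble the full report."""
    test_labels = np.asarray(test_labels, dtype=np.int64)
    if test_labels.size == 0:
        raise ValueError("test set must be non-empty")
    probs = model.predict(test_images)
    n_classes = probs.shape[1]
    y_pred = probs.argmax(axis=1)
    conf = confusion_matrix(test_labels, y_pred, n_classes)
    per_class = precision_recall_f1(conf)
    return EvalReport(
        per_class=per_class,
        macro_f1=float(np.mean([m["f1"] for m in per_class.values()])),
        accuracy=float(np.trace(conf) / conf.sum()),
        confusion=conf,
        normalized_confusion=confusion_matrix(test_labels, y_pred,
                                              n_classes, normalize=True),
        pairwise_auc=pairwise_roc_auc(test_labels, probs),
    )
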