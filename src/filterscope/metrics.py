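"""Classification metrics and the percent-change importance statistic.

Precision, recall and F1 are computed per class from raw confusion counts:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with the zero-denominator convention that an undefined precision, recall or
F1 is 0 — the convention that keeps ablation percent changes finite.  The
weighted F1 averages per-class F1 with true-label support weights.

``percent_change`` is the importance statistic every perturbation engine
reports: 100 * (perturbed - baseline) / baseline, so a large negative value
marks an important component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClassMetrics",
    "class_metrics",
    "percent_change",
    "class_share_percent",
]


@dataclass(frozen=True)
class ClassMetrics:
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    weighted_f1: float
    class_names: tuple[str, ...] = ()

    @property
    def n_classes(self) -> int:
        return len(self.f1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (class, metric, value) table."""
        names = self.class_names or tuple(str(i) for i in range(self.n_classes))
        rows = []
        for i, name in enumerate(names):
            rows += [
                (name, "precision", self.precision[i]),
                (name, "recall", self.recall[i]),
                (name, "f1", self.f1[i]),
                (name, "support", float(self.support[i])),
            ]
        rows.append(("all", "weighted_f1", self.weighted_f1))
        return pd.DataFrame(rows, columns=["class", "metric", "value"])

    def to_dict(self) -> dict:
        return {
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "support": self.support.tolist(),
            "weighted_f1": self.weighted_f1,
            "class_names": list(self.class_names),
        }


def class_metrics(
    true_labels: np.ndarray,
    pred_labels: np.ndarray,
    n_classes: int,
    class_names: tuple[str, ...] = (),
) -> ClassMetrics:
    """Per-class precision/recall/F1 and support-weighted F1 from labels."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.size == 0:
        raise ValueError("cannot compute metrics on empty label vectors")
    if t.shape != p.shape:
        raise ValueError(
            f"label vectors differ in length: {t.shape} vs {p.shape}"
        )
    precision = np.zeros(n_classes)
    recall = np.zeros(n_classes)
    f1 = np.zeros(n_classes)
    support = np.zeros(n_classes, dtype=np.int64)
    for c in range(n_classes):
        tp = int(np.sum((p == c) & (t == c)))
        fp = int(np.sum((p == c) & (t != c)))
        fn = int(np.sum((p != c) & (t == c)))
        support[c] = tp + fn
        precision[c] = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        recall[c] = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        denom = precision[c] + recall[c]
        f1[c] = 2.0 * precision[c] * recall[c] / denom if denom > 0 else 0.0
    total = support.sum()
    weighted_f1 = float((support / total) @ f1) if total > 0 else 0.0
    return ClassMetrics(
        precision=precision, recall=recall, f1=f1, support=support,
        weighted_f1=weighted_f1, class_names=tuple(class_names),
    )


def percent_change(
    baseline: ClassMetrics, perturbed: ClassMetrics
) -> tuple[np.ndarray, float]:
    """Per-class and weighted F1 percent change relative to baseline.

    Returns ``(per_class, weighted)`` where per-class entries with a zero
    baseline F1 are NaN (undefined, never silently 0).
    """
    if baseline.n_classes != perturbed.n_classes:
        raise ValueError("baseline and perturbed metrics have different sizes")
    per_class = np.full(baseline.n_classes, np.nan)
    ok = baseline.f1 > 0
    per_class[ok] = 100.0 * (perturbed.f1[ok] - baseline.f1[ok]) / baseline.f1[ok]
    if baseline.weighted_f1 > 0:
        weighted = 100.0 * (perturbed.weighted_f1 - baseline.weighted_f1) / baseline.weighted_f1
    else:
        weighted = float("nan")
    return per_class, float(weighted)


def class_share_percent(counts, decimals: int = 2) -> np.ndarray:
    """Percentage share of each class from raw sample counts, rounded to
    ``decimals`` places — the arithmetic behind a class-distribution table."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("counts must be non-empty with a positive total")
    return np.round(100.0 * counts / counts.sum(), decimals)
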