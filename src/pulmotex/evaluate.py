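"""Metric battery for predicted label maps and class probabilities.

Label-map metrics are computed over labelled lung voxels only and
macro-averaged over the six classes where applicable: Jaccard, f1, recall,
precision, accuracy, the multiclass (Gorodkin) Matthews correlation
coefficient, the raw and millimetre-scaled Hamming disagreement, and the
RMSE over ordinal class indices (healthy=0 … unhealthy=5).  Probability
outputs are scored with one-vs-rest AUC-ROC per class (midrank ties).

Percentages are reported on a 0–100 scale.  The millimetre Hamming distance
is the disagreeing-voxel count scaled by the in-plane pixel spacing and
normalized by the number of evaluated slices; it is a per-slice mismatch
length, not comparable across datasets with different slice layouts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import (
    f1_score,
    jaccard_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .patching import N_CLASSES, CLASS_NAMES, SENTINEL, LabelMap


@dataclass
class MetricsReport:
    jaccard_pct: float
    hamming_voxels: int
    hamming_mm: float
    rmse: float
    f1_pct: float
    recall_pct: float
    precision_pct: float
    accuracy_pct: float
    mcc_pct: float

    def as_dict(self) -> dict:
        return asdict(self)


def confusion_metrics(
    pred: LabelMap, truth: LabelMap, mask: np.ndarray
) -> MetricsReport:
    """All label-map metrics over voxels labelled in both maps."""
    if pred.labels.shape != truth.labels.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.labels.shape} vs truth {truth.labels.shape}"
        )
    mask = np.asarray(mask).astype(bool)
    sel = mask & (pred.labels != SENTINEL) & (truth.labels != SENTINEL)
    if not sel.any():
        raise ValueError("no voxels labelled in both maps")
    y_pred = pred.labels[sel].astype(int)
    y_true = truth.labels[sel].astype(int)
    classes = list(range(N_CLASSES))

    mismatches = int((y_pred != y_true).sum())
    n_slices = int(np.unique(np.nonzero(sel)[2]).size)
    in_plane = float(np.mean(truth.spacing[:2]))
    hamming_mm = mismatches * in_plane / n_slices

    return MetricsReport(
        jaccard_pct=100 * jaccard_score(
            y_true, y_pred, labels=classes, average="macro", zero_division=0
        ),
        hamming_voxels=mismatches,
        hamming_mm=hamming_mm,
        rmse=float(np.sqrt(np.mean((y_pred - y_true) ** 2.0))),
        f1_pct=100 * f1_score(
            y_true, y_pred, labels=classes, average="macro", zero_division=0
        ),
        recall_pct=100 * recall_score(
            y_true, y_pred, labels=classes, average="macro", zero_division=0
        ),
        precision_pct=100 * precision_score(
            y_true, y_pred, labels=classes, average="macro", zero_division=0
        ),
        accuracy_pct=100 * float((y_pred == y_true).mean()),
        mcc_pct=100 * matthews_corrcoef(y_true, y_pred),
    )


def auc_roc_per_class(
    probs: np.ndarray, labels: np.ndarray
) -> dict[str, float | None]:
    """One-vs-rest AUC per class; classes without both outcomes report None."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.ndim != 2 or probs.shape[1] != N_CLASSES:
        raise ValueError(f"probs must be (n, {N_CLASSES}), got {probs.shape}")
    out: dict[str, float | None] = {}
    for c, name in enumerate(CLASS_NAMES):
        y = (labels == c).astype(int)
        if y.min() == y.max():  # degenerate: no positives or no negatives
            out[name] = None
            continue
        out[name] = float(roc_auc_score(y, probs[:, c]))
    return out


def summarize_cases(reports: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Mean ± sd of every metric across cases (volumes)."""
    if not reports:
        raise ValueError("no cases to summarize")
    keys = reports[0].as_dict().keys()
    table = {k: np.array([r.as_dict()[k] for r in reports], dtype=float) for k in keys}
    return {k: (float(v.mean()), float(v.std(ddof=0))) for k, v in table.items()}
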