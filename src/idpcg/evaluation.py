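"""Confusion-matrix metrics, one-vs-rest ROC/AUC and the evaluation harness.

Sensitivity and specificity are reported in percent, accuracy as a
fraction; all three raise on an undefined (zero-denominator) case rather
than silently returning 0.  ROC curves sweep the unique scores in
descending order (ties grouped) and integrate trapezoidally, which equals
the Mann-Whitney concordance probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import MLPModel
from .pipeline import PipelineConfig, features_from_record

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "MetricUndefinedError",
    "sensitivity",
    "specificity",
    "accuracy",
    "confusion_one_vs_rest",
    "roc_curve",
    "EvaluationReport",
    "evaluate_system",
]


class MetricUndefinedError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("at least one count required")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def sensitivity(c: ConfusionCounts) -> float:
    """100 * TP / (TP + FN), percent."""
    if c.tp + c.fn == 0:
        raise MetricUndefinedError("sensitivity undefined: no positive cases")
    return 100.0 * c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """100 * TN / (TN + FP), percent."""
    if c.tn + c.fp == 0:
        raise MetricUndefinedError("specificity undefined: no negative cases")
    return 100.0 * c.tn / (c.tn + c.fp)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / n as a fraction in [0, 1]."""
    return (c.tp + c.tn) / c.n


def accuracy_percent(c: ConfusionCounts) -> float:
    return 100.0 * accuracy(c)


def confusion_one_vs_rest(true_labels, predicted_labels, target_class) -> ConfusionCounts:
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    tp = int(np.sum((t == target_class) & (p == target_class)))
    fp = int(np.sum((t != target_class) & (p == target_class)))
    fn = int(np.sum((t == target_class) & (p != target_class)))
    tn = int(np.sum((t != target_class) & (p != target_class)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    @property
    def points(self):
        return list(zip(self.fpr, self.tpr))


def roc_curve(scores, truth) -> ROCCurve:
    """One-vs-rest ROC from continuous scores and a binary truth vector."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores/truth length mismatch")
    n_pos = int(np.sum(y))
    n_neg = int(np.sum(~y))
    if n_pos == 0 or n_neg == 0:
        raise MetricUndefinedError("ROC undefined: only one class present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # group ties: take cumulative counts at the last index of each distinct score
    distinct = np.flatnonzero(np.diff(s_sorted)) if len(s_sorted) > 1 else np.array([], int)
    cut = np.concatenate([distinct, [len(s_sorted) - 1]])
    cum_tp = np.cumsum(y_sorted)[cut]
    cum_fp = np.cumsum(~y_sorted)[cut]
    tpr = np.concatenate([[0.0], cum_tp / n_pos])
    fpr = np.concatenate([[0.0], cum_fp / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[cut]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


# ---------------------------------------------------------------------------
# end-to-end harness
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-class metrics table plus the raw material behind it."""

    table: pd.DataFrame
    confusions: dict
    rocs: dict
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    scores: np.ndarray
    n_excluded: int
    class_names: tuple

    def to_text(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _scores_for(model, features_matrix: np.ndarray) -> np.ndarray:
    from .classifier import HeartSoundClassifierResults
    from .network import forward

    if isinstance(model, HeartSoundClassifierResults):
        return np.atleast_2d(model.predict_scores(features_matrix))
    if isinstance(model, MLPModel):
        Z = model.scaler.transform(features_matrix) if model.scaler else features_matrix
        return np.atleast_2d(forward(model, Z))
    raise TypeError(f"unsupported model type {type(model)!r}")


def evaluate_system(
    model,
    records,
    segmentation: str = "estimated",
    pipeline_config: PipelineConfig | None = None,
    score_fn=None,
) -> EvaluationReport:
    """Run preprocess -> segment -> features -> classify on every record.

    ``model`` is a fitted :class:`HeartSoundClassifierResults` or a bare
    :class:`MLPModel`; alternatively ``score_fn(record, feature_vector)``
    may supply the 5 scores directly (used for oracle upper-bound checks).
    Records whose segmentation fails are excluded and tallied.
    Returns per-class sensitivity/specificity (percent), accuracy
    (fraction) and one-vs-rest AUC.
    """
    from .synth import CLASS_NAMES

    cfg = pipeline_config or PipelineConfig()
    if score_fn is None:
        class_names = (
            model.class_names
            if isinstance(model, MLPModel)
            else model.model.class_names
        )
    else:
        class_names = CLASS_NAMES
    feats, truths, excluded = [], [], 0
    kept_records = []
    for rec in records:
        try:
            fv = features_from_record(rec, segmentation, cfg)
        except Exception:
            excluded += 1
            continue
        feats.append(fv.as_array())
        truths.append(rec.label)
        kept_records.append(rec)
    if not feats:
        raise ValueError("no records survived segmentation")
    F = np.array(feats)

    if score_fn is not None:
        scores = np.array([score_fn(rec, f) for rec, f in zip(kept_records, feats)])
    else:
        scores = _scores_for(model, F)

    name_to_idx = {n: i for i, n in enumerate(class_names)}
    y_true = np.array([name_to_idx[t] for t in truths])
    y_pred = np.argmax(scores, axis=1)

    rows, confs, rocs = [], {}, {}
    for k, name in enumerate(class_names):
        if not np.any(y_true == k):
            continue
        c = confusion_one_vs_rest(y_true, y_pred, k)
        confs[name] = c
        roc = roc_curve(scores[:, k], y_true == k)
        rocs[name] = roc
        rows.append(
            {
                "component": name,
                "sensitivity_pct": sensitivity(c),
                "specificity_pct": specificity(c),
                "accuracy": accuracy(c),
                "auc": roc.auc,
            }
        )
    table = pd.DataFrame(rows)
    return EvaluationReport(
        table=table,
        confusions=confs,
        rocs=rocs,
        true_labels=y_true,
        predicted_labels=y_pred,
        scores=scores,
        n_excluded=excluded,
        class_names=tuple(class_names),
    )
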