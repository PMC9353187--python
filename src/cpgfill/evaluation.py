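"""Class-imbalance-aware evaluation.

With heavily skewed binarised labels (oocyte/embryo profiles have
methylation rates of a few percent), accuracy and AUC reward a constant
majority-class predictor; the primary metric here is therefore the F1
score computed with the *minor* binarised class as the positive class.
The minor class is determined per task on the evaluation subset itself.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import (accuracy_score, average_precision_score, f1_score,
                             precision_score, recall_score, roc_auc_score)

from .losses import binarize


@dataclass
class TaskMetrics:
    f1_minor: float
    precision: float
    recall: float
    accuracy: float
    auc_roc: float | None
    auprc: float | None
    n_eval: int
    minor_class: int


@dataclass
class EvalReport:
    per_task: list[TaskMetrics]
    binarize_threshold: float = 0.5
    positive_class_rule: str = "minor class of the evaluation subset"

    @property
    def mean_f1_minor(self) -> float:
        vals = [t.f1_minor for t in self.per_task if t.n_eval > 0]
        return float(np.mean(vals)) if vals else float("nan")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def _minor_class(y_bin: np.ndarray) -> int:
    """The rarer binary class; ties resolve to the methylated class (1)."""
    n1 = int(y_bin.sum())
    n0 = len(y_bin) - n1
    return 1 if n1 <= n0 else 0


def evaluate(predictions: np.ndarray, labels: np.ndarray,
             mask: np.ndarray | None = None,
             binarize_threshold: float = 0.5) -> EvalReport:
    """Per-task metrics over unmasked entries.

    ``predictions`` and ``labels`` are (n, m) (or (n,) for one task);
    labels may be continuous levels — they are binarised at the threshold
    for F1/precision/recall/accuracy, while raw probabilities feed AUC-ROC
    and AUPRC.  A task whose evaluation subset contains a single class gets
    ``None`` for the ranking metrics but still a (degenerate) F1.
    """
    predictions = np.atleast_2d(np.asarray(predictions, dtype=np.float64).T).T
    labels = np.atleast_2d(np.asarray(labels, dtype=np.float64).T).T
    if mask is None:
        mask = np.ones(labels.shape, dtype=bool)
    mask = np.atleast_2d(np.asarray(mask, dtype=bool).T).T
    per_task = []
    for j in range(labels.shape[1]):
        mj = mask[:, j]
        n = int(mj.sum())
        if n == 0:
            per_task.append(TaskMetrics(*(float("nan"),) * 4, None, None, 0, 1))
            continue
        y = binarize(labels[mj, j], binarize_threshold).astype(int)
        p = predictions[mj, j]
        pb = binarize(p, binarize_threshold).astype(int)
        minor = _minor_class(y)
        single_class = len(np.unique(y)) < 2
        f1 = f1_score(y, pb, pos_label=minor, zero_division=0)
        prec = precision_score(y, pb, pos_label=minor, zero_division=0)
        rec = recall_score(y, pb, pos_label=minor, zero_division=0)
        acc = accuracy_score(y, pb)
        score_minor = p if minor == 1 else 1.0 - p
        y_minor = (y == minor).astype(int)
        auc = None if single_class else float(roc_auc_score(y_minor, score_minor))
        ap = None if single_class else float(
            average_precision_score(y_minor, score_minor))
        per_task.append(TaskMetrics(float(f1), float(prec), float(rec),
                                    float(acc), auc, ap, n, minor))
    return EvalReport(per_task=per_task, binarize_threshold=binarize_threshold)


@dataclass
class TauCurve:
    """Minor-class F1 over retained (confident) predictions per tau."""

    taus: list[float]
    f1_minor: list[float | None]
    fraction_retained: list[float]

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


DEFAULT_TAU_GRID = tuple(np.round(np.arange(0.5, 1.0, 0.05), 2))


def retained(predictions: np.ndarray, tau: float) -> np.ndarray:
    """Confidence retention rule: keep yhat > tau or yhat < 1 - tau (strict)."""
    p = np.asarray(predictions, dtype=np.float64)
    return (p > tau) | (p < 1.0 - tau)


def tau_curve(predictions: np.ndarray, labels: np.ndarray,
              tau_grid=DEFAULT_TAU_GRID,
              binarize_threshold: float = 0.5) -> TauCurve:
    """Sweep the confidence threshold tau for one task.

    For each tau only predictions outside (1 - tau, tau) are retained; the
    minor-class F1 is computed on the retained subset.  A tau retaining
    nothing yields ``None`` with a warning.
    """
    import logging
    predictions = np.asarray(predictions, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    taus, f1s, fracs = [], [], []
    for tau in tau_grid:
        if not (0.5 <= tau < 1.0):
            raise ValueError("tau values must lie in [0.5, 1)")
        keep = retained(predictions, tau)
        frac = float(keep.mean()) if len(keep) else 0.0
        taus.append(float(tau))
        fracs.append(frac)
        if not keep.any():
            logging.getLogger(__name__).warning(
                "tau=%.2f retains no predictions", tau)
            f1s.append(None)
            continue
        rep = evaluate(predictions[keep], labels[keep],
                       binarize_threshold=binarize_threshold)
        f1s.append(rep.per_task[0].f1_minor)
    return TauCurve(taus=taus, f1_minor=f1s, fraction_retained=fracs)
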