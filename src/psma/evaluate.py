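"""Train/test splitting and binary-classification scoring (ROC/AUC, MCC)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import ActivityTable


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn}


@dataclass
class ROCCurve:
    """Threshold sweep of (FPR, TPR) with trapezoidal area."""

    thresholds: np.ndarray   # descending unique scores
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def split_train_test(labels: ActivityTable | np.ndarray,
                     test_fraction: float = 0.2, seed: int = 0,
                     stratified: bool = True,
                     ids: list[str] | None = None
                     ) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive, seeded train/test partition of the ids.

    Stratified by label by default so small positive classes survive the
    split; plain random mode is retained for strict replication.
    """
    if isinstance(labels, ActivityTable):
        ids = list(labels.ids)
        y = labels.labels
    else:
        y = np.asarray(labels, dtype=int)
        if ids is None:
            ids = [str(i) for i in range(len(y))]
    if not 0 < test_fraction < 1:
        raise ValidationError(f"test_fraction must be in (0,1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    if stratified:
        for cls in (0, 1):
            members = np.flatnonzero(y == cls)
            n_test = int(round(test_fraction * len(members)))
            if len(members) and (n_test < 1 or len(members) - n_test < 1):
                raise ValidationError(
                    f"class {cls} has only {len(members)} members — too few to "
                    f"stratify at test_fraction={test_fraction}; "
                    "consider stratified=False")
            test_idx.extend(rng.permutation(members)[:n_test].tolist())
    else:
        n_test = int(round(test_fraction * len(y)))
        if n_test < 1 or len(y) - n_test < 1:
            raise ValidationError("split leaves an empty train or test set")
        test_idx = rng.permutation(len(y))[:n_test].tolist()
    test_set = set(test_idx)
    train_ids = [ids[i] for i in range(len(y)) if i not in test_set]
    test_ids = [ids[i] for i in sorted(test_set)]
    return train_ids, test_ids


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValidationError(f"length mismatch: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> ROCCurve:
    """ROC by sweeping the positive-accepting threshold over unique scores.

    Tied scores move across the threshold together; the AUC is the
    trapezoidal area through the resulting vertices, which equals the
    Mann-Whitney pair-ordering fraction (ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValidationError("scores and truth lengths differ")
    if not np.isfinite(scores).all():
        raise ValidationError("non-finite scores")
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined: both classes must be present")

    order = np.argsort(-scores, kind="stable")
    s_sorted, t_sorted = scores[order], truth[order]
    distinct = np.flatnonzero(np.diff(s_sorted)) if len(s_sorted) > 1 else np.array([], int)
    block_ends = np.append(distinct, len(s_sorted) - 1)

    cum_tp = np.cumsum(t_sorted)
    cum_fp = np.cumsum(~t_sorted)
    tpr = np.concatenate([[0.0], cum_tp[block_ends] / n_pos, [1.0]])
    fpr = np.concatenate([[0.0], cum_fp[block_ends] / n_neg, [1.0]])
    thresholds = np.concatenate([[np.inf], s_sorted[block_ends], [-np.inf]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds, tpr, fpr, auc)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation; any zero factor in the denominator gives 0."""
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    return float((c.tp * c.tn - c.fp * c.fn) / np.sqrt(float(denom)))


def evaluation_report(scores: np.ndarray, truth: np.ndarray,
                      threshold: float = 0.5) -> dict:
    """Bundle confusion, MCC and ROC/AUC for one scored test set."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    pred = scores > threshold
    counts = confusion(pred, truth.astype(bool))
    roc = roc_auc(scores, truth)
    return {
        "auc": roc.auc,
        "mcc": mcc(counts),
        "threshold": threshold,
        "confusion": counts.as_dict(),
        "roc": [{"threshold": float(t), "fpr": float(f), "tpr": float(s)}
                for t, f, s in zip(roc.thresholds, roc.fpr, roc.tpr)],
        "n_test": int(len(truth)),
        "n_test_pos": int(truth.sum()),
    }
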