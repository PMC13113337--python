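"""Binary classification metrics (abnormal = positive class) and multi-run
aggregation.

ACC, SEN, SPE, QI (geometric mean of SEN and SPE), F1, MCC are computed from
the confusion counts; AUC is computed two independent ways — trapezoidal area
under the swept-threshold ROC and the tie-corrected Mann–Whitney rank
statistic — and the two are asserted to agree; the Brier score is the mean
squared difference between predicted probabilities and outcomes.  Metrics
whose denominator vanishes take the conventional 0 sentinel.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "ConfusionCounts", "MetricSet", "confusion", "classification_metrics",
    "roc_auc", "brier", "aggregate_runs", "evaluate_predictions",
]

#: operating threshold on the abnormal probability
DECISION_THRESHOLD = 0.5


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    acc: float = np.nan
    sen: float = np.nan
    spe: float = np.nan
    qi: float = np.nan
    f1: float = np.nan
    mcc: float = np.nan
    auc: float = np.nan
    bs: float = np.nan

    def to_dict(self) -> dict:
        return asdict(self)


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def classification_metrics(c: ConfusionCounts) -> MetricSet:
    """Threshold metrics from confusion counts (no AUC/Brier)."""
    if c.total <= 0:
        raise ValueError("empty confusion matrix")
    sen = _safe_div(c.tp, c.tp + c.fn)
    spe = _safe_div(c.tn, c.tn + c.fp)
    mcc_den = np.sqrt(float(c.tp + c.fp) * (c.tp + c.fn)
                      * (c.tn + c.fp) * (c.tn + c.fn))
    return MetricSet(
        acc=(c.tp + c.tn) / c.total,
        sen=sen,
        spe=spe,
        qi=float(np.sqrt(sen * spe)),
        f1=_safe_div(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        mcc=_safe_div(c.tp * c.tn - c.fp * c.fn, mcc_den),
    )


def _auc_trapezoid(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal area under the ROC swept over the distinct score
    thresholds (tied scores grouped at one threshold)."""
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    distinct = np.flatnonzero(np.diff(scores)) + 1
    cut = np.concatenate([distinct, [scores.size]])
    tps = np.cumsum(labels == 1)[cut - 1]
    fps = np.cumsum(labels == 0)[cut - 1]
    P, N = tps[-1], fps[-1]
    tpr = np.concatenate([[0.0], tps / P])
    fpr = np.concatenate([[0.0], fps / N])
    return float(np.trapezoid(tpr, fpr))


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Mann–Whitney statistic via midranks."""
    from scipy.stats import rankdata
    ranks = rankdata(scores)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores, labels) -> float:
    """AUC by both the trapezoid-over-ROC and rank-statistic routes; the two
    must agree to numerical precision (they are equal analytically)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    trap = _auc_trapezoid(scores, labels)
    rank = _auc_rank(scores, labels)
    if abs(trap - rank) > 1e-10:
        raise AssertionError(
            f"AUC implementations disagree: trapezoid {trap} vs rank {rank}")
    return trap


def brier(probs, outcomes) -> float:
    """Mean squared difference between probabilities and binary outcomes."""
    probs = np.asarray(probs, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if probs.shape != outcomes.shape:
        raise ValueError("probs and outcomes must have equal length")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.isin(outcomes, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary")
    return float(np.mean((probs - outcomes) ** 2))


def evaluate_predictions(y_true, probs,
                         threshold: float = DECISION_THRESHOLD) -> MetricSet:
    """Full metric set from abnormal-class probabilities."""
    y_true = np.asarray(y_true, dtype=int)
    probs = np.asarray(probs, dtype=float)
    preds = (probs >= threshold).astype(int)
    ms = classification_metrics(confusion(y_true, preds))
    ms.auc = roc_auc(probs, y_true) if len(np.unique(y_true)) == 2 else np.nan
    ms.bs = brier(probs, y_true)
    return ms


def aggregate_runs(runs: list[MetricSet]) -> dict[str, dict[str, float]]:
    """Per-metric mean and sample (n−1) standard deviation; sd = 0 for a
    single run."""
    if not runs:
        raise ValueError("need at least one run")
    out: dict[str, dict[str, float]] = {}
    for name in MetricSet().to_dict():
        vals = np.array([getattr(r, name) for r in runs], dtype=float)
        sd = float(vals.std(ddof=1)) if vals.size >= 2 else 0.0
        out[name] = {"mean": float(vals.mean()), "sd": sd}
    return out
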