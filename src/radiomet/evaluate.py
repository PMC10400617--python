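"""ROC/AUC analysis, bootstrap confidence intervals, DeLong comparison,
and confusion-matrix metrics for binary benign/malignant classifiers.

AUC is computed two equivalent ways — a trapezoid rule over the tie-grouped
ROC sweep and the Mann-Whitney U statistic over positive/negative score pairs
(ties count 1/2) — and the two agree on every input. Confidence intervals use
stratified case resampling (percentile method, 2000 resamples at the 95% level
by default). Paired classifiers on the same validation samples are compared
with DeLong's method via midrank structural components.

Metrics with an empty denominator (e.g. PPV with no predicted positives) are
reported as ``None``, never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .io import BENIGN, MALIGNANT


def _as_binary(labels) -> np.ndarray:
    """Map labels to {0, 1} with malignant (or 1/True) as the positive class."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        y = (arr == MALIGNANT).astype(int)
        bad = ~np.isin(arr, (BENIGN, MALIGNANT))
        if bad.any():
            raise ValueError(f"unknown labels: {sorted(set(arr[bad]))}")
    else:
        y = arr.astype(int)
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("numeric labels must be 0/1")
    return y


def _check_both_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise ValueError("both classes must be present")


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic (midranks; ties = 1/2)."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    _check_both_classes(y)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    r = rankdata(s)
    u = r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class RocAnalysis:
    """ROC sweep with AUC and (optionally) a bootstrap CI."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    ci_lower: float | None = None
    ci_upper: float | None = None
    ci_level: float | None = None
    n_boot: int | None = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "ci_level": self.ci_level,
            "n_boot": self.n_boot,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "fpr": [float(v) for v in self.fpr],
            "tpr": [float(v) for v in self.tpr],
        }


def roc_points(scores, labels) -> RocAnalysis:
    """ROC curve by threshold sweep over unique scores, ties grouped.

    The curve is anchored at (0, 0) and (1, 1) and the AUC is the trapezoid
    rule over the swept points; on every input this equals the Mann-Whitney
    pair-counting AUC.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    _check_both_classes(y)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # group ties: step once per distinct score
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocAnalysis(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
                       n_pos=n_pos, n_neg=n_neg)


def _auc_batch(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise AUC for matrices of positive and negative scores (B x n each)."""
    gt = (pos[:, :, None] > neg[:, None, :]).mean(axis=(1, 2))
    eq = (pos[:, :, None] == neg[:, None, :]).mean(axis=(1, 2))
    return gt + 0.5 * eq


def bootstrap_auc_ci(
    scores, labels, n_boot: int = 2000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC under stratified case resampling.

    Positive and negative cases are resampled separately, so every resample
    keeps both classes and the AUC is always defined.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    _check_both_classes(y)
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    pos, neg = s[y == 1], s[y == 0]
    aucs = np.empty(n_boot)
    chunk = max(1, int(5e6 // max(1, len(pos) * len(neg))))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        pos_rs = pos[rng.integers(len(pos), size=(b, len(pos)))]
        neg_rs = neg[rng.integers(len(neg), size=(b, len(neg)))]
        aucs[done:done + b] = _auc_batch(pos_rs, neg_rs)
        done += b
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lower), float(upper)


def roc_analysis(
    scores, labels, n_boot: int = 2000, level: float = 0.95, seed: int = 0
) -> RocAnalysis:
    """ROC sweep plus bootstrap CI in one report."""
    roc = roc_points(scores, labels)
    lo, hi = bootstrap_auc_ci(scores, labels, n_boot=n_boot, level=level, seed=seed)
    roc.ci_lower, roc.ci_upper = lo, hi
    roc.ci_level, roc.n_boot = level, n_boot
    return roc


# --------------------------------------------------------------------------- #
# DeLong comparison
# --------------------------------------------------------------------------- #

@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    delta_auc: float
    z: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "auc_a": self.auc_a, "auc_b": self.auc_b,
            "delta_auc": self.delta_auc, "z": self.z, "p_value": self.p_value,
        }


def _structural_components(s: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong V10 (per positive) and V01 (per negative) via midranks."""
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    r_all = rankdata(np.r_[pos, neg])
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return v10, v01, float(auc)


def delong_compare(scores_a, scores_b, labels) -> DelongResult:
    """DeLong paired test for the difference of two correlated AUCs.

    Both score vectors must be evaluated on the same samples in the same
    order. Returns the AUC difference (A - B), the z statistic and the
    two-sided normal p-value. Identical score vectors give p = 1 by
    convention; zero estimated variance with a nonzero AUC difference is an
    error (the normal approximation is meaningless there).
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = _as_binary(labels)
    if sa.shape != sb.shape or sa.shape[0] != y.shape[0]:
        raise ValueError("scores_a, scores_b and labels must have equal lengths")
    _check_both_classes(y)

    v10a, v01a, auc_a = _structural_components(sa, y)
    v10b, v01b, auc_b = _structural_components(sb, y)
    m, n = len(v10a), len(v01a)
    delta = auc_a - auc_b
    if m < 2 or n < 2:
        raise ValueError("DeLong needs at least 2 samples per class")
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + \
          (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        if abs(delta) < 1e-12:
            return DelongResult(auc_a, auc_b, 0.0, 0.0, 1.0)
        raise ValueError("zero DeLong variance with a nonzero AUC difference")
    z = delta / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return DelongResult(auc_a, auc_b, float(delta), float(z), min(p, 1.0))


# --------------------------------------------------------------------------- #
# confusion metrics
# --------------------------------------------------------------------------- #

@dataclass
class ConfusionMetrics:
    """Threshold-applied binary classification metrics (malignant = positive).

    Fields with an empty denominator are ``None`` (undefined), never 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    accuracy: float | None
    prevalence: float | None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "tp", "fp", "tn", "fn", "sensitivity", "specificity",
            "ppv", "npv", "f1", "accuracy", "prevalence")}


def _ratio(num: float, den: float) -> float | None:
    return float(num / den) if den > 0 else None


def confusion_metrics(predicted, truth) -> ConfusionMetrics:
    """Confusion counts and derived rates from hard predicted labels."""
    y_pred = _as_binary(predicted)
    y_true = _as_binary(truth)
    if y_pred.shape != y_true.shape:
        raise ValueError("predicted and true labels must have equal lengths")
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        accuracy=_ratio(tp + tn, tp + fp + tn + fn),
        prevalence=_ratio(tp + fn, tp + fp + tn + fn),
    )


def youden_threshold(scores, labels) -> float:
    """Score threshold maximizing sensitivity + specificity - 1."""
    roc = roc_points(scores, labels)
    j = roc.tpr - roc.fpr
    return float(roc.thresholds[int(np.argmax(j))])


@dataclass
class EvalReport:
    """Per-model evaluation bundle (ROC + CI + confusion at a threshold)."""

    name: str
    roc: RocAnalysis
    confusion: ConfusionMetrics
    threshold: float

    def to_dict(self) -> dict:
        return {
            "model": self.name,
            "threshold": self.threshold,
            "roc": self.roc.to_dict(),
            "confusion": self.confusion.to_dict(),
        }


def evaluate_scores(
    name: str,
    scores,
    labels,
    threshold: float = 0.5,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> EvalReport:
    """Full evaluation of one score vector against true labels."""
    roc = roc_analysis(scores, labels, n_boot=n_boot, level=level, seed=seed)
    y = _as_binary(labels)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    conf = confusion_metrics(pred, y)
    return EvalReport(name=name, roc=roc, confusion=conf, threshold=threshold)
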