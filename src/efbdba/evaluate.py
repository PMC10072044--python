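"""SVM cross-validation fitness, classification metrics and biomarker stats.

The wrapper's fitness signal is the mean accuracy of a support vector
machine over stratified k-fold cross-validation (5 folds by default).
Fold assignment is derived once from the run seed and reused for every
candidate mask, making the accuracy a pure function of the mask — the
:class:`FitnessEvaluator` caches it by mask bytes.

The kernel is linear with C = 1 by default.  The source method never
states its kernel; linear is the standard choice for wide (n << p)
expression matrices and the single most consequential unknown of this
reimplementation (see docs/methods.md).

Biomarker statistics per feature: the absolute Welch t statistic
``t = |mean_pos - mean_neg| / sqrt(s2_pos/n_pos + s2_neg/n_neg)`` with a
two-sided p-value on Welch–Satterthwaite degrees of freedom, and the
fold change ``FC = mean_pos / mean_neg``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataio import BDBAConfig, ExpressionDataset, ValidationError

logger = logging.getLogger("efbdba")

__all__ = [
    "FitnessEvaluator",
    "cv_accuracy",
    "cv_metrics",
    "classification_metrics",
    "t_statistic",
    "fold_change",
    "biomarker_table",
]


def _make_splits(y: np.ndarray, n_folds: int, seed: int):
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValidationError("stratified CV impossible: a class has < 2 samples")
    k = min(n_folds, int(counts.min()))
    if k < n_folds:
        logger.info("CV folds reduced from %d to %d (small minority class)", n_folds, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    return list(skf.split(np.zeros(len(y)), y))


class FitnessEvaluator:
    """Cached SVM-CV accuracy over a fixed candidate pool.

    Splits are fixed at construction from the config seed, so accuracy is
    deterministic per mask and safe to cache.
    """

    def __init__(self, ds_pool: ExpressionDataset, cfg: BDBAConfig):
        ds_pool.require_two_classes()
        self.X = ds_pool.values
        self.y = np.asarray(ds_pool.labels, dtype=int)
        self.cfg = cfg
        self.splits = _make_splits(self.y, cfg.cv_folds, cfg.rng_seed)
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def _svm(self) -> SVC:
        return SVC(kernel=self.cfg.svm_kernel, C=self.cfg.svm_C)

    def accuracy(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=np.uint8)
        if mask.sum() == 0:
            raise ValidationError("cannot evaluate an empty feature mask")
        key = mask.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        cols = np.where(mask == 1)[0]
        X = self.X[:, cols]
        accs = []
        for train, test in self.splits:
            clf = self._svm()
            clf.fit(X[train], self.y[train])
            accs.append(float(np.mean(clf.predict(X[test]) == self.y[test])))
        acc = float(np.mean(accs))
        self._cache[key] = acc
        self.n_evaluations += 1
        return acc


def cv_accuracy(ds_sub: ExpressionDataset, cfg: BDBAConfig | None = None) -> float:
    """Stratified-CV SVM accuracy of a dataset view (all features used)."""
    cfg = cfg or BDBAConfig()
    ev = FitnessEvaluator(ds_sub, cfg)
    return ev.accuracy(np.ones(ds_sub.n_features, dtype=np.uint8))


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Accuracy, recall, precision and F1 with positive class = 1.

    Zero-denominator ratios (no predicted positives, no true positives)
    return 0 by convention.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    acc = (tp + tn) / len(y_true) if len(y_true) else 0.0
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    rec = tp / (tp + fn) if (tp + fn) else 0.0
    if (tp + fp) == 0 or (tp + fn) == 0:
        logger.debug("degenerate confusion matrix: zero denominator -> 0")
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    return {"accuracy": acc, "recall": rec, "precision": prec, "f1": f1}


def cv_metrics(ds_sub: ExpressionDataset, cfg: BDBAConfig | None = None) -> dict[str, float]:
    """Per-fold classification metrics, averaged over the CV folds."""
    cfg = cfg or BDBAConfig()
    ds_sub.require_two_classes()
    y = np.asarray(ds_sub.labels, dtype=int)
    splits = _make_splits(y, cfg.cv_folds, cfg.rng_seed)
    folds = []
    for train, test in splits:
        clf = SVC(kernel=cfg.svm_kernel, C=cfg.svm_C)
        clf.fit(ds_sub.values[train], y[train])
        folds.append(classification_metrics(y[test], clf.predict(ds_sub.values[test])))
    return {k: float(np.mean([f[k] for f in folds])) for k in folds[0]}


def t_statistic(f_pos: np.ndarray, f_neg: np.ndarray) -> tuple[float, float]:
    """Absolute Welch t statistic and its two-sided p-value.

    Sample variances (n-1 denominator); degenerate groups with zero
    variance and equal means give (0, 1), and zero variance with unequal
    means gives (inf, 0).
    """
    f_pos = np.asarray(f_pos, dtype=float)
    f_neg = np.asarray(f_neg, dtype=float)
    if f_pos.size < 2 or f_neg.size < 2:
        raise ValidationError("t statistic needs >= 2 values per group")
    n1, n2 = f_pos.size, f_neg.size
    v1, v2 = f_pos.var(ddof=1), f_neg.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    delta = abs(f_pos.mean() - f_neg.mean())
    if se2 == 0.0:
        return (0.0, 1.0) if delta == 0.0 else (math.inf, 0.0)
    t = delta / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(t, df))
    return t, p


def fold_change(f_pos: np.ndarray, f_neg: np.ndarray) -> float:
    """Ratio of class means; NaN (logged) when the negative mean is 0."""
    m_pos = float(np.mean(f_pos))
    m_neg = float(np.mean(f_neg))
    if m_neg == 0.0:
        logger.info("fold change undefined: negative-class mean is 0")
        return math.nan
    return m_pos / m_neg


def biomarker_table(
    ds: ExpressionDataset, feature_indices: list[int]
) -> list[dict]:
    """t / p / FC per selected feature, ranked by ascending p-value."""
    ds.require_two_classes()
    pos = ds.labels == 1
    rows = []
    for j in feature_indices:
        f_pos = ds.values[pos, j]
        f_neg = ds.values[~pos, j]
        t, p = t_statistic(f_pos, f_neg)
        rows.append(
            {
                "feature_id": ds.feature_ids[j],
                "t": float(t),
                "p_value": float(p),
                "FC": fold_change(f_pos, f_neg),
            }
        )
    for rank, row in enumerate(sorted(rows, key=lambda r: r["p_value"]), start=1):
        row["rank"] = rank
    return rows
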