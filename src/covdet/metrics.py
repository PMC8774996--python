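"""Diagnostic metrics and evaluation protocols.

Twelve metrics are derived from the confusion counts (TP, FN, TN, FP):
accuracy, sensitivity, specificity, negative predictive value, false
negative rate (1 − Sen), false positive rate, F-score, informedness
(Youden's J = Sen + Spec − 1), negative and positive likelihood ratios
(FNR/Spec and Sen/FPR), diagnostic odds ratio ((TP/FN)/(FP/TN)), and the
Matthews correlation coefficient.

Zero-denominator policy: DOR/PLR/NLR-style ratios return ``+inf`` when only
the denominator vanishes and ``nan`` when the ratio is 0/0 (reported as
undefined, never silently 0); an MCC with a zero denominator is 0 by the
usual convention.

Three protocols wrap a model factory: a stratified 50/50 split, stratified
ten-fold cross-validation, and leave-one-subject-out.  The factory builds a
fresh model per fold, so anything fitted from data (feature screening,
standardisation) is re-fit inside each training fold — no leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneGroupOut, StratifiedKFold, train_test_split

from .exceptions import InvalidArgumentError

logger = logging.getLogger("covdet")

METRIC_NAMES = ("acc", "sen", "spec", "npv", "fnr", "fpr", "fscore", "info",
                "nlr", "dor", "plr", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise InvalidArgumentError("confusion counts must be >= 0")
        if self.total == 0:
            raise InvalidArgumentError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive: int = 1) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise InvalidArgumentError("label/prediction length mismatch")
        pos = y_true == positive
        hit = y_pred == positive
        return cls(tp=int(np.sum(pos & hit)), fn=int(np.sum(pos & ~hit)),
                   tn=int(np.sum(~pos & ~hit)), fp=int(np.sum(~pos & hit)))

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fn + other.fn,
                               self.tn + other.tn, self.fp + other.fp)


@dataclass(frozen=True)
class MetricPanel:
    acc: float
    sen: float
    spec: float
    npv: float
    fnr: float
    fpr: float
    fscore: float
    info: float
    nlr: float
    dor: float
    plr: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _ratio(num: float, den: float) -> float:
    """num/den with the zero-denominator policy (+inf or nan, never 0)."""
    if den != 0:
        return num / den
    return np.nan if num == 0 else np.inf


def compute_metrics(c: ConfusionCounts) -> MetricPanel:
    """All twelve metrics from one confusion-count quadruple."""
    tp, fn, tn, fp = float(c.tp), float(c.fn), float(c.tn), float(c.fp)
    acc = (tp + tn) / c.total
    sen = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    npv = _ratio(tn, tn + fn)
    ppv = _ratio(tp, tp + fp)
    fnr = 1.0 - sen
    fpr = _ratio(fp, fp + tn)
    fscore = _ratio(2.0 * ppv * sen, ppv + sen)
    info = sen + spec - 1.0
    nlr = _ratio(fnr, spec)
    dor = _ratio(_ratio(tp, fn), _ratio(fp, tn))
    plr = _ratio(sen, fpr)
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den
    return MetricPanel(acc=acc, sen=sen, spec=spec, npv=npv, fnr=fnr, fpr=fpr,
                       fscore=fscore, info=info, nlr=nlr, dor=dor, plr=plr,
                       mcc=mcc)


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

@dataclass
class ProtocolResult:
    """Per-fold panels plus the pooled panel over all test predictions."""

    panels: list[MetricPanel]
    confusions: list[ConfusionCounts]
    pooled: MetricPanel
    n_test: int

    @property
    def accuracy(self) -> float:
        return self.pooled.acc

    def _aggregate(self, fn) -> dict[str, float]:
        out = {}
        for m in METRIC_NAMES:
            vals = [getattr(p, m) for p in self.panels
                    if np.isfinite(getattr(p, m))]
            out[m] = float(fn(vals)) if vals else float("nan")
        return out

    def mean(self) -> dict[str, float]:
        """Per-metric mean over folds (finite values only)."""
        return self._aggregate(np.mean)

    def std(self) -> dict[str, float]:
        """Per-metric standard deviation over folds (finite values only)."""
        return self._aggregate(np.std)

    def to_frame(self) -> pd.DataFrame:
        rows = [p.as_dict() for p in self.panels]
        df = pd.DataFrame(rows)
        df.index.name = "fold"
        return df


def _take(X, idx):
    return X.iloc[idx] if hasattr(X, "iloc") else np.asarray(X)[idx]


def _run_folds(X, y, splits, model_factory: Callable) -> ProtocolResult:
    y = np.asarray(y).astype(int)
    panels, confusions = [], []
    pooled = None
    n_test = 0
    for train_idx, test_idx in splits:
        model = model_factory()
        model.fit(_take(X, train_idx), y[train_idx])
        y_hat = model.predict(_take(X, test_idx))
        c = ConfusionCounts.from_predictions(y[test_idx], y_hat)
        confusions.append(c)
        panels.append(compute_metrics(c))
        pooled = c if pooled is None else pooled + c
        n_test += len(test_idx)
    return ProtocolResult(panels=panels, confusions=confusions,
                          pooled=compute_metrics(pooled), n_test=n_test)


def ten_fold_cv(X, y, model_factory: Callable, seed: int = 0,
                n_folds: int = 10) -> ProtocolResult:
    """Stratified k-fold cross-validation (default ten folds).

    Everything data-dependent (screening, standardisation, the ensemble) is
    re-fit by the factory's model inside each training fold.
    """
    y = np.asarray(y).astype(int)
    counts = np.bincount(y)
    if np.min(counts[counts > 0]) < n_folds:
        raise InvalidArgumentError(f"need >= {n_folds} examples per class")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return _run_folds(X, y, skf.split(np.zeros(len(y)), y), model_factory)


def equal_split_eval(X, y, model_factory: Callable, seed: int = 0) -> ProtocolResult:
    """Stratified 50/50 split: train on one half, evaluate on the other."""
    y = np.asarray(y).astype(int)
    if np.min(np.bincount(y)[np.bincount(y) > 0]) < 2:
        raise InvalidArgumentError("need >= 2 examples per class")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(idx, test_size=0.5, stratify=y,
                                           random_state=seed)
    return _run_folds(X, y, [(train_idx, test_idx)], model_factory)


def loocv_by_subject(X, y, subject_ids, model_factory: Callable) -> ProtocolResult:
    """Leave-one-subject-out: one fold per subject, no subject in both sides."""
    groups = np.asarray(subject_ids)
    if np.unique(groups).size < 2:
        raise InvalidArgumentError("need >= 2 distinct subjects")
    logo = LeaveOneGroupOut()
    y = np.asarray(y).astype(int)
    splits = [(tr, te) for tr, te in logo.split(np.zeros(len(y)), y, groups)]
    return _run_folds(X, y, splits, model_factory)
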