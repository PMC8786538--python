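"""Evaluation metrics: confusion-derived detection scores and signal-pair errors.

Detection quality is summarized from the 2x2 confusion table (accuracy,
precision, sensitivity, specificity, FPR, FNR, NPV, FDR, F1, MCC) together
with the detection fitness ``fr1 = 1 / (accuracy + precision)`` minimized by
the hyperparameter search.  Reconstruction quality of a retrieved signal
against its clean target uses MAE, RMSE and the Pearson correlation; the
mitigation fitness is the MAE itself.

Zero-denominator metrics are reported as NaN (undefined marker), never as an
exception.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "ConfusionCounts",
    "DetectionReport",
    "SignalPairScores",
    "confusion",
    "detection_report",
    "signal_scores",
    "fitness_detection",
]

#: large sentinel fitness used when accuracy + precision vanishes
FR1_SENTINEL = 1e6


@dataclass
class ConfusionCounts:
    ta_p: int  # true positives
    fa_p: int  # false positives
    ta_n: int  # true negatives
    fa_n: int  # false negatives

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{f.name} must be a nonnegative integer")

    @property
    def total(self) -> int:
        return self.ta_p + self.fa_p + self.ta_n + self.fa_n


@dataclass
class DetectionReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    fpr: float
    fnr: float
    npv: float
    fdr: float
    f1: float
    mcc: float
    fitness_fr1: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class SignalPairScores:
    mae: float
    rmse: float
    corr: float


def confusion(labels_true: np.ndarray, labels_pred: np.ndarray) -> ConfusionCounts:
    t = np.asarray(labels_true).astype(bool)
    p = np.asarray(labels_pred).astype(bool)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    return ConfusionCounts(
        ta_p=int(np.sum(t & p)),
        fa_p=int(np.sum(~t & p)),
        ta_n=int(np.sum(~t & ~p)),
        fa_n=int(np.sum(t & ~p)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def detection_report(c: ConfusionCounts) -> DetectionReport:
    if c.total < 1:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = c.ta_p, c.fa_p, c.ta_n, c.fa_n
    accuracy = _ratio(tp + tn, c.total)
    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    fpr = _ratio(fp, fp + tn)
    fnr = _ratio(fn, fn + tp)
    npv = _ratio(tn, tn + fn)
    fdr = _ratio(fp, fp + tp)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn)
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else float("nan")
    fr1 = fitness_detection(accuracy, precision)
    return DetectionReport(
        accuracy=accuracy,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        fpr=fpr,
        fnr=fnr,
        npv=npv,
        fdr=fdr,
        f1=f1,
        mcc=mcc,
        fitness_fr1=fr1,
    )


def fitness_detection(accuracy: float, precision: float) -> float:
    """Detection fitness ``fr1 = 1 / (accuracy + precision)``, minimized.

    An undefined precision (no positive predictions) contributes 0; a zero
    denominator yields the large sentinel rather than a division error.
    Since both rates are at most 1, fr1 is never below 0.5.
    """
    acc = 0.0 if np.isnan(accuracy) else accuracy
    prc = 0.0 if np.isnan(precision) else precision
    total = acc + prc
    if total <= 0:
        return FR1_SENTINEL
    fr1 = 1.0 / total
    assert fr1 >= 0.5 - 1e-12
    return fr1


def signal_scores(retrieved: np.ndarray, clean: np.ndarray) -> SignalPairScores:
    r = np.asarray(retrieved, dtype=float).ravel()
    c = np.asarray(clean, dtype=float).ravel()
    if r.shape != c.shape or r.size < 2:
        raise ValueError("signals must share a length of at least 2")
    diff = r - c
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff**2)))
    if np.ptp(c) == 0 or np.ptp(r) == 0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(r, c)[0, 1])
    return SignalPairScores(mae=mae, rmse=rmse, corr=corr)
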