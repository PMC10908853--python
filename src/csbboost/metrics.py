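"""Evaluation arithmetic: imbalance ratio, confusion-matrix scores, ROC/AUC,
and cross-dataset rank aggregation.

Undefined quantities (zero denominators, e.g. precision with no positive
predictions) are reported as NaN and listed in ``MetricsReport.undefined``,
never coerced to 0 — coercion silently deflates or inflates averages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "RocCurve",
    "imbalance_ratio",
    "confusion",
    "basic_metrics",
    "roc_auc",
    "evaluate_predictions",
    "rank_aggregate",
]


def imbalance_ratio(n_major: int, n_minor: int) -> float:
    """IR = majority count / minority count; IR = 1 means perfectly balanced."""
    if n_minor < 1:
        raise ValueError("minority count must be at least 1")
    return n_major / n_minor


@dataclass
class ConfusionMatrix:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricsReport:
    accuracy: float = math.nan
    precision: float = math.nan
    recall: float = math.nan
    f1: float = math.nan
    specificity: float = math.nan
    prevalence: float = math.nan
    detection_prevalence: float = math.nan
    kappa: float = math.nan
    auc: float = math.nan
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "accuracy", "precision", "recall", "f1", "specificity",
            "prevalence", "detection_prevalence", "kappa", "auc")}
        d["undefined"] = list(self.undefined)
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def confusion(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred differ in length")
    if y_true.size == 0:
        raise ValueError("need at least one observation")
    return ConfusionMatrix(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return num / den


def basic_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """All confusion-matrix derived scores.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean,
    specificity = TN/(TN+FP), prevalence = (TP+FN)/n (actual positive
    fraction), detection prevalence = (TP+FP)/n (predicted positive
    fraction), accuracy = (TP+TN)/n, and Cohen's kappa with chance agreement
    from the marginals.
    """
    undefined: list[str] = []
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    precision = _ratio(cm.TP, cm.TP + cm.FP, "precision", undefined)
    recall = _ratio(cm.TP, cm.TP + cm.FN, "recall", undefined)
    if math.isnan(precision) or math.isnan(recall):
        undefined.append("f1")
        f1 = math.nan
    elif precision + recall == 0:
        undefined.append("f1")
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    specificity = _ratio(cm.TN, cm.TN + cm.FP, "specificity", undefined)
    accuracy = (cm.TP + cm.TN) / n
    prevalence = (cm.TP + cm.FN) / n
    detection_prevalence = (cm.TP + cm.FP) / n
    p_o = accuracy
    p_e = ((cm.TP + cm.FP) * (cm.TP + cm.FN) + (cm.FN + cm.TN) * (cm.FP + cm.TN)) / (n * n)
    if p_e == 1.0:
        undefined.append("kappa")
        kappa = math.nan
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return MetricsReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        specificity=specificity, prevalence=prevalence,
        detection_prevalence=detection_prevalence, kappa=kappa,
        undefined=undefined,
    )


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(y_true, scores) -> RocCurve:
    """ROC curve by threshold sweep and trapezoidal AUC.

    Tied scores are grouped at one threshold, which makes the trapezoid area
    equal to the Mann-Whitney probability with half credit for ties.
    """
    y_true = np.asarray(y_true, dtype=int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if y_true.size != scores.size:
        raise ValueError("y_true and scores differ in length")
    if np.unique(y_true).size < 2:
        raise ValueError("AUC needs both classes present in y_true")
    fpr, tpr, thr = roc_curve(y_true, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def evaluate_predictions(y_true, y_pred, scores=None) -> MetricsReport:
    """One-call report: confusion metrics plus AUC when scores are given."""
    report = basic_metrics(confusion(y_true, y_pred))
    if scores is not None:
        try:
            report.auc = roc_auc(y_true, scores).auc
        except ValueError:
            report.undefined.append("auc")
    else:
        report.undefined.append("auc")
    return report


def rank_aggregate(score_table, higher_is_better: bool = True) -> pd.DataFrame:
    """Per-dataset ranks of algorithms with median-rank and mean-score summary.

    ``score_table``: rows = datasets, columns = algorithms (DataFrame or 2-D
    array). Rank 1 is best on each dataset; ties receive the average rank.
    Returns a DataFrame indexed by algorithm with columns ``median_rank`` and
    ``mean_score`` plus one ``rank_<dataset>`` column per dataset.
    """
    df = pd.DataFrame(score_table)
    if df.isna().any().any():
        raise ValueError("score table contains missing entries")
    values = df.to_numpy(float)
    signed = -values if higher_is_better else values
    ranks = rankdata(signed, axis=1, method="average")
    out = pd.DataFrame(
        {
            "median_rank": np.median(ranks, axis=0),
            "mean_score": values.mean(axis=0),
        },
        index=df.columns,
    )
    for i, ds in enumerate(df.index):
        out[f"rank_{ds}"] = ranks[i]
    return out
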