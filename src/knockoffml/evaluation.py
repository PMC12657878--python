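"""Prediction and clinical-utility metrics.

AUROC (Mann-Whitney with tie correction), confusion-matrix metrics at a
probability cutoff, the DeLong test for paired AUROC differences, RMSE/R^2
for quantitative traits, point-biserial correlation, and decision-curve net
benefit NB(p_t) = TP/n - (FP/n) * p_t / (1 - p_t).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, pointbiserialr, rankdata
from sklearn.metrics import mean_squared_error, r2_score, roc_auc_score

__all__ = [
    "DecisionCurve",
    "EvalReport",
    "auroc",
    "classification_metrics",
    "delong_test",
    "auroc_ci",
    "regression_metrics",
    "point_biserial",
    "net_benefit",
    "evaluate_binary",
]


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def auroc(y, scores) -> float:
    """Probability that a random case outscores a random control, ties
    counting one half."""
    y = _check_binary(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def classification_metrics(
    y, scores, threshold: float = 0.5
) -> tuple[float, float, float]:
    """(sensitivity, specificity, F1) from the confusion matrix at
    ``scores >= threshold``; F1 is 0 (with a warning) when nothing is
    predicted positive."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    y = _check_binary(y)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    if tp + fp == 0:
        warnings.warn("no predicted positives; F1 set to 0")
        return sens, spec, 0.0
    precision = tp / (tp + fp)
    f1 = 0.0 if precision + sens == 0 else 2 * precision * sens / (precision + sens)
    return sens, spec, f1


def _delong_components(y: np.ndarray, scores: np.ndarray):
    """Structural components V10 (cases) and V01 (controls) via midranks."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    r_all = rankdata(all_scores)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    auc = (np.sum(r_all[:m]) - m * (m + 1) / 2) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return float(auc), v10, v01


def delong_test(y, scores_a, scores_b) -> tuple[float, float, float]:
    """Two-sided DeLong test for the difference of two correlated AUROCs
    measured on the same samples. Returns (auroc_a, auroc_b, p)."""
    y = _check_binary(y)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != y.shape[0]:
        raise ValueError("paired score vectors must match y in length")
    auc_a, v10_a, v01_a = _delong_components(y, a)
    auc_b, v10_b, v01_b = _delong_components(y, b)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = float(2 * norm.sf(abs(z)))
    return auc_a, auc_b, p


def auroc_ci(y, scores, level: float = 0.95) -> tuple[float, float, float]:
    """AUROC with a DeLong-variance normal confidence interval."""
    y = _check_binary(y)
    auc, v10, v01 = _delong_components(y, np.asarray(scores, dtype=float))
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    half = norm.ppf(0.5 + level / 2) * np.sqrt(max(var, 0.0))
    return auc, max(0.0, auc - half), min(1.0, auc + half)


def regression_metrics(y, predictions) -> tuple[float, float]:
    """(RMSE, R^2)."""
    y = np.asarray(y, dtype=float)
    pred = np.asarray(predictions, dtype=float)
    if y.shape[0] < 2:
        raise ValueError("need at least two observations")
    if np.var(y) == 0:
        raise ValueError("zero-variance y: R^2 undefined")
    rmse = float(np.sqrt(mean_squared_error(y, pred)))
    return rmse, float(r2_score(y, pred))


def point_biserial(y, scores) -> float:
    """Pearson correlation between a 0/1 outcome and a continuous score."""
    y = _check_binary(y)
    scores = np.asarray(scores, dtype=float)
    if np.var(scores) == 0:
        warnings.warn("constant scores; point-biserial correlation set to 0")
        return 0.0
    return float(pointbiserialr(y, scores).statistic)


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    model: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "net_benefit": self.model,
                "treat_all": self.treat_all,
                "treat_none": self.treat_none,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def net_benefit(y, scores, thresholds=None) -> DecisionCurve:
    """Decision curve over a threshold-probability grid (default 0.01..0.60
    step 0.01), with treat-all and treat-none references."""
    y = _check_binary(y)
    scores = np.asarray(scores, dtype=float)
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.601, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie in (0, 1)")
    n = y.shape[0]
    prevalence = y.mean()
    nb = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        pred = scores >= pt
        tp = np.sum(pred & (y == 1)) / n
        fp = np.sum(pred & (y == 0)) / n
        nb[i] = tp - fp * pt / (1 - pt)
    treat_all = prevalence - (1 - prevalence) * thresholds / (1 - thresholds)
    return DecisionCurve(
        thresholds=thresholds,
        model=nb,
        treat_all=treat_all,
        treat_none=np.zeros_like(thresholds),
    )


@dataclass
class EvalReport:
    auroc: float | None = None
    auroc_ci: tuple[float, float] | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    f1: float | None = None
    rmse: float | None = None
    r2: float | None = None
    point_biserial: float | None = None
    delong_p: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=list))


def evaluate_binary(
    y, scores, threshold: float = 0.5, comparators: dict[str, np.ndarray] | None = None
) -> EvalReport:
    """One-stop report for a binary-outcome prediction."""
    auc, lo, hi = auroc_ci(y, scores)
    sens, spec, f1 = classification_metrics(y, scores, threshold)
    report = EvalReport(
        auroc=auc,
        auroc_ci=(lo, hi),
        sensitivity=sens,
        specificity=spec,
        f1=f1,
        point_biserial=point_biserial(y, scores),
    )
    for name, other in (comparators or {}).items():
        report.delong_p[name] = delong_test(y, scores, other)[2]
    return report
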