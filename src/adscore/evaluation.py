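"""Classifier evaluation: confusion metrics, AUC, uncertainty diagnostics,
and the hippocampus-plus-covariates linear baseline.

All metrics are computed at a score cutoff (default 0.5) with ties at the
cutoff classified negative. Ratios with a zero denominator are reported as
NaN with a warning, never silently imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

__all__ = [
    "MetricReport",
    "confusion_metrics",
    "auc",
    "uncertainty_report",
    "baseline_hippocampal_model",
]

BASELINE_PREDICTORS = [
    "lh_hippocampus_volume",
    "rh_hippocampus_volume",
    "age",
    "etiv",
    "sex",
]


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float = 0.5

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "accuracy", "auc", "sensitivity", "specificity", "ppv", "npv",
            "tp", "fp", "tn", "fn", "cutoff",
        )}


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN", stacklevel=3)
        return float("nan")
    return num / den


def confusion_metrics(
    scores, labels, cutoff: float = 0.5, with_auc: bool = True
) -> MetricReport:
    """Threshold scores at ``cutoff`` (positive iff score > cutoff) and
    summarize the 2x2 table. AUC is included when both classes are present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError(f"scores length {len(scores)} != labels length {len(labels)}")
    labels = labels.astype(int)
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    pred = scores > cutoff  # tie at the cutoff -> negative
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    auc_val = auc(scores, labels) if with_auc and len(np.unique(labels)) == 2 else float("nan")
    return MetricReport(
        accuracy=_ratio(tp + tn, tp + fp + tn + fn, "accuracy"),
        auc=auc_val,
        sensitivity=_ratio(tp, tp + fn, "sensitivity"),
        specificity=_ratio(tn, tn + fp, "specificity"),
        ppv=_ratio(tp, tp + fp, "PPV"),
        npv=_ratio(tn, tn + fn, "NPV"),
        tp=tp, fp=fp, tn=tn, fn=fn, cutoff=cutoff,
    )


def auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney probability P(score_pos > score_neg) + 0.5
    P(tie); delegated to scikit-learn's rank-based implementation (an
    exhaustive pairwise oracle cross-checks this in the test suite).
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def uncertainty_report(
    adscores: pd.DataFrame, labels, cutoff: float = 0.5
) -> dict:
    """Summarize uncertainty by correctness and by score bin.

    Expects the ``mc_predict`` output columns (``ad_score``,
    ``uncertainty``). Returns group summaries plus two diagnostic flags:
    ``error_uncertainty`` (misclassified subjects carry higher mean
    uncertainty) and ``inverted_u`` (mid-range scores in [0.4, 0.6] carry
    higher mean uncertainty than extreme scores in [0,0.1] or [0.9,1]).
    Flags are None when a group is empty.
    """
    scores = adscores["ad_score"].to_numpy()
    unc = adscores["uncertainty"].to_numpy()
    labels = np.asarray(labels).astype(int)
    if len(labels) != len(scores):
        raise ValueError("labels misaligned with score table")
    pred = (scores > cutoff).astype(int)
    correct = pred == labels

    def _summary(x: np.ndarray) -> dict:
        if len(x) == 0:
            return {"n": 0, "mean": None, "q25": None, "median": None, "q75": None}
        q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75])
        return {"n": int(len(x)), "mean": float(np.mean(x)),
                "q25": float(q25), "median": float(med), "q75": float(q75)}

    mid = (scores >= 0.4) & (scores <= 0.6)
    extreme = (scores <= 0.1) | (scores >= 0.9)

    report = {
        "correct": _summary(unc[correct]),
        "incorrect": _summary(unc[~correct]),
        "mid_scores": _summary(unc[mid]),
        "extreme_scores": _summary(unc[extreme]),
        "score_bins": _bin_curve(scores, unc),
    }
    if report["incorrect"]["n"] and report["correct"]["n"]:
        report["error_uncertainty"] = bool(
            report["incorrect"]["mean"] > report["correct"]["mean"]
        )
    else:
        report["error_uncertainty"] = None
    if report["mid_scores"]["n"] and report["extreme_scores"]["n"]:
        report["inverted_u"] = bool(report["mid_scores"]["mean"] > report["extreme_scores"]["mean"])
    else:
        report["inverted_u"] = None
    return report


def _bin_curve(scores: np.ndarray, unc: np.ndarray, n_bins: int = 10) -> list[dict]:
    edges = np.linspace(0, 1, n_bins + 1)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (scores >= lo) & (scores < hi if hi < 1 else scores <= hi)
        rows.append(
            {
                "bin": f"[{lo:.1f},{hi:.1f})",
                "n": int(m.sum()),
                "mean_uncertainty": float(np.mean(unc[m])) if m.any() else None,
            }
        )
    return rows


def baseline_hippocampal_model(
    train: pd.DataFrame, test: pd.DataFrame, cutoff: float = 0.5
) -> MetricReport:
    """Linear-probability comparator on five classical predictors.

    Fits OLS of the binary diagnosis on left/right hippocampal volume, age,
    eTIV and sex in the raw (non-residualized) training table, scores the
    test table with the fitted linear predictor, and evaluates at the same
    cutoff as the network. This anchors how much the 155-feature network
    adds over the best-known single-region risk factors.
    """
    for col in BASELINE_PREDICTORS:
        if col not in train.columns or col not in test.columns:
            raise ValueError(f"missing baseline predictor column '{col}'")
    Xtr = sm.add_constant(train[BASELINE_PREDICTORS].to_numpy(dtype=float), has_constant="add")
    ytr = (train["diagnosis"] == "AD").to_numpy(dtype=float)
    fit = sm.OLS(ytr, Xtr).fit()
    Xte = sm.add_constant(test[BASELINE_PREDICTORS].to_numpy(dtype=float), has_constant="add")
    scores = Xte @ fit.params
    yte = (test["diagnosis"] == "AD").to_numpy(dtype=int)
    return confusion_metrics(scores, yte, cutoff=cutoff)
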