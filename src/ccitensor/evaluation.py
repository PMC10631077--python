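"""Benchmark metrics for predicted CCIs against planted ground truth.

Continuous rankings are scored by AUCROC (mid-rank convention) and AUCPR
(average-precision convention); binary calls by F-measure, Matthews
correlation coefficient (MCC), positive rate PR = (TP+FP)/total, FPR and
FNR.  Because tensor decomposition is unsupervised, a CaH cannot be
matched to a ground-truth CCI type in advance; the max-over-CaH rule
therefore scores every CaH against each truth pattern and keeps the best.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .cah import BinarizedCaH, CaH, binarize_cah, reconstruct_cah
from .scoring import PermutationResult, binarize_by_pvalue


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricReport:
    aucroc: float | None
    aucpr: float | None
    f_measure: float
    mcc: float
    pr: float
    fpr: float
    fnr: float


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have the same shape")
    return ConfusionCounts(
        TP=int(np.sum(pred & truth)),
        FP=int(np.sum(pred & ~truth)),
        TN=int(np.sum(~pred & ~truth)),
        FN=int(np.sum(~pred & truth)),
    )


def f_measure(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when undefined."""
    prec = c.TP / (c.TP + c.FP) if c.TP + c.FP else 0.0
    rec = c.TP / (c.TP + c.FN) if c.TP + c.FN else 0.0
    if prec + rec == 0:
        return 0.0
    return 2 * prec * rec / (prec + rec)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom)


def rates(c: ConfusionCounts) -> tuple[float, float, float]:
    """(pr, fpr, fnr): predicted-positive fraction, FP/(FP+TN), FN/(FN+TP)."""
    pr = (c.TP + c.FP) / c.total if c.total else 0.0
    fpr = c.FP / (c.FP + c.TN) if c.FP + c.TN else 0.0
    fnr = c.FN / (c.FN + c.TP) if c.FN + c.TP else 0.0
    return pr, fpr, fnr


def aucroc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney AUCROC with mid-rank tie handling."""
    truth = np.asarray(truth).ravel().astype(int)
    if truth.min() == truth.max():
        raise ValueError("AUCROC requires both classes in the truth")
    return float(roc_auc_score(truth, np.asarray(scores, float).ravel()))


def aucpr(scores: np.ndarray, truth: np.ndarray) -> float:
    """Average-precision (step-wise) area under the PR curve."""
    truth = np.asarray(truth).ravel().astype(int)
    if truth.sum() == 0:
        raise ValueError("AUCPR requires at least one positive")
    return float(average_precision_score(truth, np.asarray(scores, float).ravel()))


def binary_report(pred: np.ndarray, truth: np.ndarray) -> MetricReport:
    c = confusion(pred, truth)
    pr, fpr, fnr = rates(c)
    return MetricReport(None, None, f_measure(c), mcc(c), pr, fpr, fnr)


_BINARY_METRICS = {
    "mcc": lambda pred, truth: mcc(confusion(pred, truth)),
    "f_measure": lambda pred, truth: f_measure(confusion(pred, truth)),
    "pr": lambda pred, truth: rates(confusion(pred, truth))[0],
    "fpr": lambda pred, truth: rates(confusion(pred, truth))[1],
    "fnr": lambda pred, truth: rates(confusion(pred, truth))[2],
}
_CONTINUOUS_METRICS = {"aucroc": aucroc, "aucpr": aucpr}


def evaluate_cahs(
    cahs: list[CaH] | list[BinarizedCaH],
    truths: list[np.ndarray],
    metric: str,
    thr_bin: float = 1.0,
) -> dict:
    """Best-over-CaH matching: per truth pattern, the best metric over CaHs.

    Continuous metrics score the CaH reconstruction (triple outer
    product); binary metrics score the MAD-binarized mask tensor.
    "Best" follows the metric's orientation (max for goodness measures,
    min for FPR/FNR; PR is taken from the MCC-matched CaH).  The summary
    reports both the mean over truth patterns ("mean_best") and the
    single best combination ("global_best").
    """
    if not cahs:
        raise ValueError("empty CaH list")
    if not truths:
        raise ValueError("need at least one ground-truth pattern")
    if metric in _CONTINUOUS_METRICS:
        fn = _CONTINUOUS_METRICS[metric]
        tensors = [
            c.predicted_tensor() if isinstance(c, BinarizedCaH) else reconstruct_cah(c)
            for c in cahs
        ]
    elif metric in _BINARY_METRICS:
        fn = _BINARY_METRICS[metric]
        tensors = [
            c.predicted_tensor()
            if isinstance(c, BinarizedCaH)
            else binarize_cah(c, thr_bin).predicted_tensor()
            for c in cahs
        ]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    # "best" over CaHs is metric-oriented: smallest for error rates,
    # largest for goodness measures; the positive rate is descriptive and
    # reported for the MCC-matched CaH
    if metric in ("fpr", "fnr"):
        per_truth = [min(fn(t, truth) for t in tensors) for truth in truths]
        agg = min
    elif metric == "pr":
        per_truth = []
        for truth in truths:
            i_best = int(
                np.argmax([mcc(confusion(t, truth)) for t in tensors])
            )
            per_truth.append(fn(tensors[i_best], truth))
        agg = max
    else:
        per_truth = [max(fn(t, truth) for t in tensors) for truth in truths]
        agg = max
    return {
        "per_truth_best": per_truth,
        "mean_best": float(np.mean(per_truth)),
        "global_best": float(agg(per_truth)),
    }


def evaluate_permutation_method(
    pr: PermutationResult, truth: np.ndarray, alpha: float = 0.05
) -> MetricReport:
    """Score a permutation test: 1 - p as the continuous score, p < alpha
    as the binary call."""
    scores = 1.0 - pr.pvalues
    pred = binarize_by_pvalue(pr, alpha)
    c = confusion(pred, truth)
    prr, fpr, fnr = rates(c)
    return MetricReport(
        aucroc=aucroc(scores, truth),
        aucpr=aucpr(scores, truth),
        f_measure=f_measure(c),
        mcc=mcc(c),
        pr=prr,
        fpr=fpr,
        fnr=fnr,
    )
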