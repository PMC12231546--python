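"""Evaluation metrics for residue-level disorder prediction.

Disordered is the positive class throughout. Unlabeled residues are excluded
from every count, curve and score. Threshold metrics follow the standard
confusion-matrix definitions:

    Sn  = TP / (TP + FN)                 (sensitivity, disordered recall)
    Sp  = TN / (TN + FP)                 (specificity, ordered recall)
    BACC = (Sn + Sp) / 2
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    F1   = 2 TP / (2 TP + FP + FN)

A metric whose denominator is zero is reported as 0 and flagged in
``MetricsReport.degenerate``. Ranking metrics: AUC is the rank-based
(Mann-Whitney) area, ties counted one half; APS is the step-wise
recall-weighted mean precision along the precision-recall curve; Fmax is the
peak F1 over all score thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score

from .io import DISORDERED, ORDERED, UNLABELED

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "threshold_metrics",
    "roc_auc",
    "pr_summary",
    "evaluate_scores",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    Sn: float
    Sp: float
    BACC: float
    MCC: float
    F1: float
    AUC: float
    APS: float
    Fmax: float
    fmax_threshold: float
    counts: ConfusionCounts
    threshold: float
    degenerate: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "Sn": self.Sn, "Sp": self.Sp, "BACC": self.BACC, "MCC": self.MCC,
            "F1": self.F1, "AUC": self.AUC, "APS": self.APS, "Fmax": self.Fmax,
            "fmax_threshold": self.fmax_threshold, "threshold": self.threshold,
            "TP": self.counts.TP, "FP": self.counts.FP,
            "TN": self.counts.TN, "FN": self.counts.FN,
            "degenerate": list(self.degenerate),
        }


def _labeled_mask(labels: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    keep = labels != UNLABELED
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    return keep


def confusion(labels: np.ndarray, calls: np.ndarray,
              mask: np.ndarray | None = None) -> ConfusionCounts:
    """Confusion counts over labeled residues (disordered positive)."""
    labels = np.asarray(labels)
    calls = np.asarray(calls)
    if labels.shape != calls.shape:
        raise ValueError("labels and calls must have equal length")
    keep = _labeled_mask(labels, mask)
    y = labels[keep] == DISORDERED
    c = calls[keep] == DISORDERED
    return ConfusionCounts(
        TP=int(np.sum(y & c)), FP=int(np.sum(~y & c)),
        TN=int(np.sum(~y & ~c)), FN=int(np.sum(y & ~c)),
    )


def threshold_metrics(counts: ConfusionCounts) -> tuple[dict, tuple[str, ...]]:
    """Sn, Sp, BACC, MCC, F1 from confusion counts.

    Returns the metric dict plus the names of metrics whose denominator was
    zero (reported as 0).
    """
    TP, FP, TN, FN = counts.TP, counts.FP, counts.TN, counts.FN
    degenerate: list[str] = []

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    sn = safe(TP, TP + FN, "Sn")
    sp = safe(TN, TN + FP, "Sp")
    bacc = (sn + sp) / 2.0
    mcc_den = float(TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    mcc = safe(TP * TN - FP * FN, np.sqrt(mcc_den), "MCC")
    f1 = safe(2 * TP, 2 * TP + FP + FN, "F1")
    return ({"Sn": sn, "Sp": sp, "BACC": bacc, "MCC": mcc, "F1": f1},
            tuple(degenerate))


def roc_auc(scores: np.ndarray, labels: np.ndarray,
            mask: np.ndarray | None = None) -> float:
    """Rank-based AUC (ties one half) over labeled residues."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    keep = _labeled_mask(labels, mask)
    y = (labels[keep] == DISORDERED).astype(int)
    if y.min(initial=1) == 1 or y.max(initial=0) == 0:
        raise ValueError("AUC requires both a positive and a negative residue")
    return float(roc_auc_score(y, scores[keep]))


def pr_summary(scores: np.ndarray, labels: np.ndarray,
               mask: np.ndarray | None = None) -> tuple[float, float, float]:
    """(APS, Fmax, maximizing threshold) over labeled residues."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    keep = _labeled_mask(labels, mask)
    y = (labels[keep] == DISORDERED).astype(int)
    s = scores[keep]
    if y.sum() == 0:
        raise ValueError("precision-recall metrics require at least one positive")
    aps = float(average_precision_score(y, s))
    prec, rec, thresholds = precision_recall_curve(y, s)
    # drop the final (P=1, R=0) bookkeeping point, which has no threshold
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    f1 = f1[:-1]
    k = int(np.argmax(f1))
    return aps, float(f1[k]), float(thresholds[k])


def evaluate_scores(
    scores_per_protein: Sequence[np.ndarray],
    labels_per_protein: Sequence[np.ndarray],
    threshold: float = 0.5,
    per_protein_average: bool = False,
) -> MetricsReport:
    """Pool residues across proteins and compute the full metric suite.

    By default evaluation is pooled dataset-wide (every labeled residue
    weighted equally, the convention for confusion-based reporting in this
    literature). ``per_protein_average`` instead averages Sn/Sp/BACC/MCC/F1/
    AUC over proteins that have both classes; the pooled confusion counts are
    still reported.
    """
    if len(scores_per_protein) != len(labels_per_protein):
        raise ValueError("scores and labels must pair one-to-one by protein")
    scores = np.concatenate([np.asarray(s, dtype=float)
                             for s in scores_per_protein])
    labels = np.concatenate([np.asarray(l) for l in labels_per_protein])
    calls = (scores >= threshold).astype(int)
    calls[labels == UNLABELED] = ORDERED  # excluded anyway; keep calls defined
    counts = confusion(labels, np.where(calls == 1, DISORDERED, ORDERED))
    tm, degenerate = threshold_metrics(counts)
    auc = roc_auc(scores, labels)
    aps, fmax, fmax_thr = pr_summary(scores, labels)

    if per_protein_average:
        per = []
        for s, l in zip(scores_per_protein, labels_per_protein):
            l = np.asarray(l)
            lab = l[l != UNLABELED]
            if len(set(lab.tolist())) < 2:
                continue
            c = confusion(l, np.where(np.asarray(s) >= threshold,
                                      DISORDERED, ORDERED))
            m, _ = threshold_metrics(c)
            m["AUC"] = roc_auc(np.asarray(s), l)
            per.append(m)
        if per:
            for key in ("Sn", "Sp", "BACC", "MCC", "F1"):
                tm[key] = float(np.mean([m[key] for m in per]))
            auc = float(np.mean([m["AUC"] for m in per]))

    return MetricsReport(
        Sn=tm["Sn"], Sp=tm["Sp"], BACC=tm["BACC"], MCC=tm["MCC"], F1=tm["F1"],
        AUC=auc, APS=aps, Fmax=fmax, fmax_threshold=fmax_thr,
        counts=counts, threshold=threshold, degenerate=degenerate,
    )
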