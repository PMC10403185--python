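"""Classification metrics, ROC/AUC, and the DeLong test for paired AUCs.

AUC uses the rank (Mann-Whitney) formulation with tie correction. The DeLong
comparison uses the fast placement-value covariance estimate and a two-sided
normal reference for z = (AUC_a - AUC_b) / sqrt(var of the difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ScoredCohort:
    """Per-lesion malignancy scores (P2) and true labels for one model."""

    case_ids: list[str]
    labels: np.ndarray         # 1 = malignant (positive), 0 = benign
    scores: np.ndarray         # P2 in [0, 1]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(int)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.case_ids) != len(set(self.case_ids)):
            raise ValueError("case_ids must be unique")
        if not (len(self.case_ids) == self.labels.size == self.scores.size):
            raise ValueError("case_ids, labels and scores must align")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("scores must lie in [0, 1]")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, threshold: float = 0.5) -> "ScoredCohort":
        labels = df["label"].map({"benign": 0, "malignant": 1}) \
            if df["label"].dtype == object else df["label"]
        return cls(case_ids=list(df["case_id"].astype(str)),
                   labels=np.asarray(labels), scores=np.asarray(df["p2"], dtype=float),
                   threshold=threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"case_id": self.case_ids,
                             "label": np.where(self.labels == 1, "malignant", "benign"),
                             "p1": 1.0 - self.scores, "p2": self.scores})


@dataclass
class EvaluationReport:
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    precision: float
    recall: float
    tp: int
    fp: int
    tn: int
    fn: int
    discrimination: str
    youden_threshold: float

    def to_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class DeLongComparison:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float
    degenerate: bool = False


def discrimination_band(auc: float) -> str:
    """Bands: < 0.6 poor, 0.6-0.75 a certain degree, > 0.75 good."""
    if auc < 0.6:
        return "poor"
    if auc <= 0.75:
        return "certain degree"
    return "good"


def _confusion(labels: np.ndarray, scores: np.ndarray,
               threshold: float) -> tuple[int, int, int, int]:
    pred = scores >= threshold  # ties (P1 == P2) classify as malignant
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


def auc_mann_whitney(labels: np.ndarray, scores: np.ndarray) -> float:
    """Tie-corrected rank AUC: mean rank of positives, scaled."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)  # average ranks handle ties (count 1/2)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def roc_curve_points(labels: np.ndarray, scores: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Threshold sweep over the distinct scores; returns (fpr, tpr, thresholds)."""
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-np.asarray(scores, dtype=float), kind="mergesort")
    sorted_scores = np.asarray(scores, dtype=float)[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(1 - sorted_labels)
    distinct = np.where(np.diff(sorted_scores))[0]
    idx = np.r_[distinct, sorted_labels.size - 1]
    tpr = np.r_[0.0, tps[idx] / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps[idx] / max(fps[-1], 1)]
    thresholds = np.r_[np.inf, sorted_scores[idx]]
    return fpr, tpr, thresholds


def confusion_metrics(scored: ScoredCohort,
                      threshold: float | None = None) -> EvaluationReport:
    """All tabulated metrics at a decision cutoff (default 0.5 on P2)."""
    if threshold is None:
        threshold = scored.threshold
    labels, scores = scored.labels, scored.scores
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("both classes must be present")
    tp, fp, tn, fn = _confusion(labels, scores, threshold)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    acc = (tp + tn) / labels.size
    auc = auc_mann_whitney(labels, scores)
    fpr, tpr, thr = roc_curve_points(labels, scores)
    youden = thr[np.argmax(tpr - fpr)]
    return EvaluationReport(auc=auc, sensitivity=sens, specificity=spec, ppv=ppv,
                            npv=npv, accuracy=acc, precision=ppv, recall=sens,
                            tp=tp, fp=fp, tn=tn, fn=fn,
                            discrimination=discrimination_band(auc),
                            youden_threshold=float(youden))


def roc_auc(scored: ScoredCohort) -> tuple[float, pd.DataFrame]:
    """Tie-corrected AUC plus the ROC curve as a (fpr, tpr, threshold) frame."""
    auc = auc_mann_whitney(scored.labels, scored.scores)
    fpr, tpr, thr = roc_curve_points(scored.labels, scored.scores)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def delong_variance(labels: np.ndarray, scores_a: np.ndarray,
                    scores_b: np.ndarray) -> tuple[float, float, float]:
    """(AUC_a, AUC_b, variance of the paired AUC difference)."""
    labels = np.asarray(labels).astype(int)
    pos, neg = labels == 1, labels == 0
    m, n = int(pos.sum()), int(neg.sum())
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for i, s in enumerate((scores_a, scores_b)):
        s = np.asarray(s, dtype=float)
        # placement values: per-subject means of the tie-corrected kernel
        diff = s[pos][:, None] - s[neg][None, :]
        kernel = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
        v10[i] = kernel.mean(axis=1)
        v01[i] = kernel.mean(axis=0)
        aucs[i] = kernel.mean()
    s10 = np.cov(v10)          # 2x2 covariance across positive subjects
    s01 = np.cov(v01)          # 2x2 covariance across negative subjects
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    return float(aucs[0]), float(aucs[1]), float(var)


def delong_test(scored_a: ScoredCohort, scored_b: ScoredCohort) -> DeLongComparison:
    """Paired DeLong z-test; degenerate (zero-variance) pairs report p = 1."""
    if scored_a.case_ids != scored_b.case_ids:
        raise ValueError("cohorts are not paired: case_id sequences differ")
    if not np.array_equal(scored_a.labels, scored_b.labels):
        raise ValueError("cohorts are not paired: labels differ")
    auc_a, auc_b, var = delong_variance(scored_a.labels, scored_a.scores,
                                        scored_b.scores)
    if var <= 0 or np.isclose(var, 0.0, atol=1e-15):
        return DeLongComparison(auc_a=auc_a, auc_b=auc_b, var_diff=max(var, 0.0),
                                z=0.0, p_value=1.0, degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongComparison(auc_a=auc_a, auc_b=auc_b, var_diff=var,
                            z=float(z), p_value=float(p))


def score_histogram(scored: ScoredCohort, bins: int = 10
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class counts over an equal-width partition of [0, 1].

    Returns (bin_edges, benign_counts, malignant_counts).
    """
    edges = np.linspace(0.0, 1.0, bins + 1)
    ben, _ = np.histogram(scored.scores[scored.labels == 0], bins=edges)
    mal, _ = np.histogram(scored.scores[scored.labels == 1], bins=edges)
    return edges, ben, mal


def comparison_matrix(cohorts: dict[str, ScoredCohort]) -> pd.DataFrame:
    """Pairwise DeLong results across named models (long format)."""
    rows = []
    names = list(cohorts)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            cmp = delong_test(cohorts[a], cohorts[b])
            rows.append({"model_a": a, "model_b": b, "auc_a": cmp.auc_a,
                         "auc_b": cmp.auc_b, "z": cmp.z, "p_value": cmp.p_value,
                         "degenerate": cmp.degenerate})
    return pd.DataFrame(rows)
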