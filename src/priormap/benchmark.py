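"""Benchmarking prioritizations against proof-of-concept targets.

Performance is the ability of a per-gene score to separate clinical
proof-of-concept targets (positives) from sampled controls: ROC/AUC with the
half-credit tie convention (AUC = Mann-Whitney P(score_pos > score_neg) +
0.5 P(tie)), a precision-recall sweep with the F-max operating point, and a
naive drug-count baseline for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .combine import LabelSet

__all__ = ["RocResult", "PrResult", "roc_auc", "pr_fmax", "naive_scores"]


@dataclass(frozen=True)
class RocResult:
    auc: float
    curve: np.ndarray  # (n_points, 2) ordered (FPR, TPR), (0,0) -> (1,1)


@dataclass(frozen=True)
class PrResult:
    curve: np.ndarray  # (n_points, 2) ordered (recall, precision)
    fmax: float
    precision_at_fmax: float
    recall_at_fmax: float


def _split_scores(scores: pd.Series, labels: LabelSet) -> tuple[np.ndarray, np.ndarray]:
    pos = scores[scores.index.isin(labels.positives)].to_numpy(dtype=float)
    neg = scores[scores.index.isin(labels.controls)].to_numpy(dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both positives and controls must be present among scored genes")
    return pos, neg


def roc_auc(scores: pd.Series, labels: LabelSet) -> RocResult:
    """ROC curve and AUC with ties given half credit."""
    pos, neg = _split_scores(scores, labels)
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    order = np.argsort(-s, kind="mergesort")
    y, s = y[order], s[order]
    # cumulative TP/FP at each distinct threshold (process tied scores jointly)
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    last_of_tie = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[last_of_tie] / pos.size]
    fpr = np.r_[0.0, fp[last_of_tie] / neg.size]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(auc=auc, curve=np.column_stack([fpr, tpr]))


def pr_fmax(scores: pd.Series, labels: LabelSet) -> PrResult:
    """Precision-recall at every distinct score threshold, with F-max.

    Tied scores enter a threshold together.  F-max is the maximum harmonic
    mean of precision and recall over thresholds.
    """
    pos, neg = _split_scores(scores, labels)
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    order = np.argsort(-s, kind="mergesort")
    y, s = y[order], s[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    last_of_tie = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last_of_tie], fp[last_of_tie]
    precision = tp / (tp + fp)
    recall = tp / pos.size
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
    best = int(np.argmax(f1))
    return PrResult(
        curve=np.column_stack([recall, precision]),
        fmax=float(f1[best]),
        precision_at_fmax=float(precision[best]),
        recall_at_fmax=float(recall[best]),
    )


def naive_scores(drug_targets: pd.DataFrame, universe: list[str]) -> pd.Series:
    """Drug-repurposing baseline: number of distinct drugs targeting each gene."""
    counts = drug_targets.groupby("gene")["drug"].nunique()
    return pd.Series(
        [int(counts.get(g, 0)) for g in universe], index=list(universe), name="naive", dtype=float
    )
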