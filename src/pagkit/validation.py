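"""Hybrid validation framework: ground-truth labeling against a reference
method, ROC/AUC over ranked pathways, and the top-n% vs bottom-(100-n)%
t-test curve over literature co-citation scores."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ArgumentError, InputError

__all__ = [
    "GroundTruthLabel",
    "RocResult",
    "TTestCurve",
    "label_ground_truth",
    "roc_auc",
    "ttest_curve",
    "rank_pathways",
]


@dataclass(frozen=True)
class GroundTruthLabel:
    pathway_id: str
    label: str  # "true" | "false" | "excluded"
    reference_adjusted_p: float
    overlap_with_input: int


@dataclass(frozen=True)
class RocResult:
    points: list[tuple[float, float]]  # (FPR, TPR), (0,0) .. (1,1)
    auc: float


@dataclass(frozen=True)
class TTestCurve:
    fractions: list[int]  # 10, 20, ..., 90
    p_values: list[float]
    average_p: float


def label_ground_truth(
    reference: Iterable[tuple[str, float, int]],
) -> list[GroundTruthLabel]:
    """Label pathways from a reference method's (id, adjusted_p, overlap) rows.

    ``true`` when the reference adjusted p-value is at most 0.05; ``false``
    when it exceeds 0.05 but at least one input gene overlaps the pathway;
    ``excluded`` otherwise (no overlap, not significant).
    """
    labels: list[GroundTruthLabel] = []
    seen: set[str] = set()
    for pid, adj_p, overlap in reference:
        if pid in seen:
            raise InputError(f"duplicate pathway_id {pid!r} in reference table")
        seen.add(pid)
        if not (0.0 < adj_p <= 1.0):
            raise InputError(f"adjusted_p for {pid!r} outside (0, 1]: {adj_p}")
        if overlap < 0:
            raise InputError(f"negative overlap for {pid!r}")
        if adj_p <= 0.05:
            lab = "true"
        elif overlap >= 1:
            lab = "false"
        else:
            lab = "excluded"
        labels.append(
            GroundTruthLabel(
                pathway_id=pid,
                label=lab,
                reference_adjusted_p=adj_p,
                overlap_with_input=overlap,
            )
        )
    return labels


def roc_auc(
    scores: Mapping[str, float], labels: Sequence[GroundTruthLabel]
) -> RocResult:
    """ROC curve and AUC of a tool's adjusted p-values against truth labels.

    Ranking score is the negated adjusted p-value (smaller p ranks more
    positive).  Labeled pathways the tool did not retrieve get adjusted
    p = 1.0 so every tool is evaluated on the identical label set.  Tied
    scores advance the curve diagonally in a single step, and the
    trapezoidal AUC then equals the Mann-Whitney U statistic normalized by
    ``n_true * n_false``.
    """
    used = [l for l in labels if l.label in ("true", "false")]
    y = np.array([1 if l.label == "true" else 0 for l in used])
    n_t, n_f = int(y.sum()), int(len(y) - y.sum())
    if n_t == 0 or n_f == 0:
        raise ArgumentError("roc_auc requires at least one true and one false label")
    s = np.array([-float(scores.get(l.pathway_id, 1.0)) for l in used])

    # AUC via average ranks (handles ties as half-concordant)
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_t * (n_t + 1) / 2.0) / (n_t * n_f)

    # curve: descend through unique thresholds, ties collapsed to one step
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s_sorted):
        j = i
        while j < len(s_sorted) and s_sorted[j] == s_sorted[i]:
            tp += int(y_sorted[j])
            fp += int(1 - y_sorted[j])
            j += 1
        points.append((fp / n_f, tp / n_t))
        i = j
    return RocResult(points=points, auc=float(auc))


def ttest_curve(
    ranked_scores: Sequence[float],
    equal_var: bool = False,
    alternative: str = "two-sided",
) -> TTestCurve:
    """Two-sample t-test curve over rank-split literature scores.

    ``ranked_scores`` are co-citation scores ordered by ascending adjusted
    p-value.  For each n in 10, 20, ..., 90 the first ``ceil(n% * length)``
    scores are compared to the remainder with a t-test (Welch by default;
    ``alternative='greater'`` tests top > bottom).  A comparison that is
    undefined — either group with fewer than two values or zero variance in
    both groups with equal means — contributes p = 1.0.
    """
    scores = np.asarray(list(ranked_scores), dtype=float)
    if len(scores) < 10:
        raise ArgumentError("ttest_curve requires at least 10 scores")
    fractions = list(range(10, 100, 10))
    p_values: list[float] = []
    for n in fractions:
        cut = math.ceil(n * len(scores) / 100)
        top, bottom = scores[:cut], scores[cut:]
        p_values.append(_safe_ttest(top, bottom, equal_var, alternative))
    return TTestCurve(
        fractions=fractions,
        p_values=p_values,
        average_p=float(np.mean(p_values)),
    )


def _safe_ttest(
    top: np.ndarray, bottom: np.ndarray, equal_var: bool, alternative: str
) -> float:
    if len(top) < 2 or len(bottom) < 2:
        return 1.0
    if np.var(top) == 0.0 and np.var(bottom) == 0.0:
        if top.mean() == bottom.mean():
            return 1.0
        return 0.0 if (alternative != "greater" or top.mean() > bottom.mean()) else 1.0
    res = stats.ttest_ind(top, bottom, equal_var=equal_var, alternative=alternative)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


def rank_pathways(adjusted_p: Mapping[str, float]) -> list[str]:
    """Pathway ids ordered by ascending adjusted p-value, ties by id."""
    return [pid for pid, _ in sorted(adjusted_p.items(), key=lambda kv: (kv[1], kv[0]))]
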