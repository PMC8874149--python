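"""ROC/AUC evaluation with Hanley-McNeil confidence intervals.

Pathogenic is the positive class throughout, and a record counts as a
positive call when its score is >= the threshold (so the exact 1.0 assigned
to very large SVs is always called pathogenic).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class EvalResult:
    """ROC points (fpr, tpr, threshold), trapezoidal AUC, Hanley-McNeil SE
    and the 95% normal-approximation CI (clipped to [0, 1])."""

    roc_points: list[tuple[float, float, float]]
    auc: float
    se: float
    ci95: tuple[float, float]


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Standard error of an AUC A for n_pos positives and n_neg negatives:

        SE^2 = [A(1-A) + (n_pos-1)(Q1 - A^2) + (n_neg-1)(Q2 - A^2)] / (n_pos * n_neg)

    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one positive and one negative")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    return math.sqrt(max(var, 0.0))


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> EvalResult:
    """ROC by descending threshold sweep with tied scores grouped.

    The AUC is the trapezoidal area under the sweep, identical to the
    Mann-Whitney statistic with 1/2 credit for ties. CI = A +/- 1.96 SE,
    clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC")

    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # group ties: cumulative counts at each distinct score
    distinct = np.where(np.diff(sorted_scores))[0]  # last index of each tie group
    idx = np.r_[distinct, len(sorted_scores) - 1]
    tps = np.cumsum(sorted_labels)[idx]
    fps = (idx + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    se = hanley_mcneil_se(auc, n_pos, n_neg)
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    points = [(float(f), float(t), float(th)) for f, t, th in zip(fpr, tpr, thresholds)]
    return EvalResult(roc_points=points, auc=auc, se=se, ci95=ci)


def sensitivity_threshold(
    scores: Sequence[float], labels: Sequence[bool], target_sensitivity: float = 0.9
) -> tuple[float, float, float]:
    """Largest threshold t with sensitivity(score >= t) >= target.

    Returns (threshold, achieved sensitivity, FPR at that threshold). If no
    threshold attains the target (only possible for target > 1 numerically),
    the minimum pathogenic score is returned with a warning.
    """
    if not 0.0 < target_sensitivity <= 1.0:
        raise ValueError("target sensitivity must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = np.sort(scores[labels])[::-1]
    if len(pos) == 0:
        raise ValueError("no pathogenic records")
    k = math.ceil(target_sensitivity * len(pos))
    if k > len(pos):
        logger.warning("sensitivity target %.3f unattainable; using minimum score", target_sensitivity)
        k = len(pos)
    threshold = float(pos[k - 1])
    achieved = float(np.mean(scores[labels] >= threshold))
    neg = scores[~labels]
    fpr = float(np.mean(neg >= threshold)) if len(neg) else float("nan")
    return threshold, achieved, fpr


def per_genome_elimination(
    genomes: Mapping[str, Sequence[float]], threshold: float
) -> tuple[dict[str, float], float]:
    """Fraction of putatively benign SVs per genome scored below threshold.

    Returns ({genome: fraction}, mean over genomes). Genomes with no SVs are
    excluded with a warning.
    """
    fractions: dict[str, float] = {}
    for genome_id, scores in genomes.items():
        scores = np.asarray(scores, dtype=float)
        if len(scores) == 0:
            logger.warning("genome %s has no SVs; excluded", genome_id)
            continue
        fractions[genome_id] = float(np.mean(scores < threshold))
    if not fractions:
        raise ValueError("no genome with >= 1 SV")
    return fractions, float(np.mean(list(fractions.values())))


def paired_rank_test(fractions_a: Sequence[float], fractions_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-genome fractions.

    Zero differences are dropped (Wilcoxon's method). All-tied input returns
    p = 1 with a warning; a single informative pair is an error.
    """
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples differ in length")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        logger.warning("all pairs tied; p = 1")
        return 1.0
    if len(nonzero) < 2:
        raise ValueError("fewer than 2 informative pairs: signed-rank test undefined")
    return float(stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided").pvalue)
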