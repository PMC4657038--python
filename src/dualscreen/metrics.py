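"""Screening evaluation: confusion statistics, ROC score, enrichment factors,
leader clustering and per-cluster score–activity correlation.

Conventions
-----------
Ranked lists order compounds best-first by *ascending* score (docking
convention: lower is better).  Callers ranking by a "higher is better" score
negate it before ranking.  The ROC score is computed through the Mann–Whitney
identity — the probability that a randomly chosen active outranks a randomly
chosen inactive, ties counted one half — which equals the area under the
TPR-vs-FPR curve and is exact under ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .compounds import tanimoto

__all__ = [
    "EvaluationReport",
    "RankedCompound",
    "ClusterCorrelationReport",
    "rank_order",
    "confusion",
    "roc_score",
    "enrichment",
    "evaluate_ranking",
    "leader_cluster",
    "cluster_correlation",
]


@dataclass(frozen=True)
class RankedCompound:
    compound_id: str
    score: float
    is_active: bool


@dataclass
class EvaluationReport:
    """Confusion counts and the derived rates.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/N.  roc_score and ef are filled by
    :func:`evaluate_ranking` when a ranking is available.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    roc_score: float | None = None
    ef: dict[float, float] | None = None


@dataclass
class ClusterCorrelationReport:
    """Per-cluster Pearson R² between consensus docking score and potency."""

    clusters: dict[int, dict]  # cluster id -> {members, n, r2 (None if undefined)}


def rank_order(
    ids: Sequence[str],
    scores: Sequence[float],
    labels: Sequence[bool],
) -> list[RankedCompound]:
    """Deterministic best-first ranking: ascending score, ties by compound id."""
    if not (len(ids) == len(scores) == len(labels)):
        raise ValueError("ids, scores and labels must be aligned")
    order = sorted(range(len(ids)), key=lambda i: (scores[i], ids[i]))
    return [RankedCompound(ids[i], float(scores[i]), bool(labels[i])) for i in order]


def confusion(predicted: Sequence[bool], actual: Sequence[bool]) -> EvaluationReport:
    """Confusion counts plus sensitivity, specificity and accuracy."""
    if len(predicted) != len(actual):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(actual)} labels"
        )
    if not predicted:
        raise ValueError("empty input")
    p = np.asarray(predicted, dtype=bool)
    a = np.asarray(actual, dtype=bool)
    tp = int(np.sum(p & a))
    fp = int(np.sum(p & ~a))
    tn = int(np.sum(~p & ~a))
    fn = int(np.sum(~p & a))
    n = len(a)
    return EvaluationReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        accuracy=(tp + tn) / n,
    )


def roc_score(ranked: Sequence[RankedCompound]) -> float:
    """Area under the ROC curve via the Mann–Whitney rank identity.

    Equals P(random active ranks better than random inactive), ties 1/2.
    """
    labels = np.array([r.is_active for r in ranked], dtype=bool)
    n_act = int(labels.sum())
    n_inact = len(labels) - n_act
    if n_act == 0 or n_inact == 0:
        raise ValueError("ROC requires at least one active and one inactive")
    # "goodness" ranks: best (lowest) score gets the highest rank
    goodness = -np.array([r.score for r in ranked])
    ranks = sps.rankdata(goodness)  # average ranks under ties
    auc = (ranks[labels].sum() - n_act * (n_act + 1) / 2.0) / (n_act * n_inact)
    return float(auc)


def enrichment(ranked: Sequence[RankedCompound], fraction: float) -> float:
    """Enrichment factor: active rate in the top fraction over the global rate.

    EF = [TP(subset)/n(subset)] / [P(total)/n(total)]; subset size is
    ceil(fraction·N).  EF = 1 is random; the upper bound is
    min(1/fraction, N/P).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(ranked)
    p_total = sum(r.is_active for r in ranked)
    if p_total == 0:
        raise ValueError("enrichment undefined: no actives in the ranking")
    n_sub = math.ceil(fraction * n)
    tp_sub = sum(r.is_active for r in ranked[:n_sub])
    return (tp_sub / n_sub) / (p_total / n)


def evaluate_ranking(
    ranked: Sequence[RankedCompound],
    score_cutoff: float,
    ef_fractions: Sequence[float] = (0.001, 0.01, 0.2),
) -> EvaluationReport:
    """Full screening evaluation at a score cutoff (score ≤ cutoff → predicted
    active) with ROC from the full ranking and EF at the given fractions."""
    predicted = [r.score <= score_cutoff for r in ranked]
    actual = [r.is_active for r in ranked]
    report = confusion(predicted, actual)
    report.roc_score = roc_score(ranked)
    report.ef = {f: enrichment(ranked, f) for f in ef_fractions}
    return report


def leader_cluster(
    fingerprints: Sequence[Iterable[int]], sim_cutoff: float
) -> list[int]:
    """Sphere-exclusion (leader) clustering on Tanimoto similarity.

    Compounds are visited in input order; each joins the first existing
    leader with similarity ≥ `sim_cutoff`, otherwise it founds a new cluster.
    Returns a cluster index per compound.  Deterministic given input order.
    """
    if not 0 < sim_cutoff < 1:
        raise ValueError(f"sim_cutoff must be in (0, 1), got {sim_cutoff}")
    if not fingerprints:
        raise ValueError("empty input")
    leaders: list[set[int]] = []
    assignment: list[int] = []
    for fp in fingerprints:
        fp = set(fp)
        for k, leader in enumerate(leaders):
            if (fp or leader) and tanimoto(fp, leader) >= sim_cutoff:
                assignment.append(k)
                break
        else:
            leaders.append(fp)
            assignment.append(len(leaders) - 1)
    return assignment


def cluster_correlation(
    assignment: Sequence[int],
    scores: Sequence[float],
    p_activities: Sequence[float],
    ids: Sequence[str] | None = None,
    min_size: int = 3,
) -> ClusterCorrelationReport:
    """Pearson R² of consensus docking score vs potency, per cluster.

    Clusters with fewer than `min_size` members are skipped; zero variance in
    either variable yields r2=None (undefined) for that cluster.
    """
    if not (len(assignment) == len(scores) == len(p_activities)):
        raise ValueError("assignment, scores and p_activities must be aligned")
    if ids is None:
        ids = [str(i) for i in range(len(assignment))]
    members: dict[int, list[int]] = {}
    for i, k in enumerate(assignment):
        members.setdefault(int(k), []).append(i)
    report: dict[int, dict] = {}
    for k in sorted(members):
        idx = members[k]
        if len(idx) < min_size:
            continue
        x = np.asarray([scores[i] for i in idx], dtype=float)
        y = np.asarray([p_activities[i] for i in idx], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r2 = None
        else:
            r2 = float(sps.pearsonr(x, y).statistic ** 2)
        report[k] = {"members": [ids[i] for i in idx], "n": len(idx), "r2": r2}
    return ClusterCorrelationReport(clusters=report)
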