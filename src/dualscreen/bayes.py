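"""Laplacian-modified Naïve Bayes activity classifier.

The classifier scores a compound by summing per-feature log weights

    w(f) = ln[ (A_f + 1) / (T_f · P(active) + 1) ]

where A_f is the number of active training compounds containing feature f,
T_f the total number of training compounds containing f, and P(active) the
class prior.  The Laplacian correction pulls rare features toward a neutral
weight of zero, which is what makes the method robust in very sparse, very
high-dimensional fingerprint spaces.  Features never seen in training
contribute exactly zero.

On top of the raw score the model provides:

* ``est_p_good`` — a normalized probability of membership in the active
  class, obtained from Gaussians fitted to the training-score distribution of
  each class (comparable across models trained on different data);
* a binary class call at a threshold chosen on the training scores to
  minimize false positives + false negatives;
* repeated stratified-split cross-validation reporting ROC score and
  enrichment factors.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .compounds import LabeledDataset
from . import metrics

logger = logging.getLogger(__name__)

__all__ = [
    "BayesModel",
    "PredictionRecord",
    "CrossValidationReport",
    "TrainingError",
    "DegenerateFitError",
    "train",
    "score",
    "est_p_good",
    "predict",
    "cross_validate",
    "save_model",
    "load_model",
]

SIGMA_FLOOR = 1e-6


class TrainingError(ValueError):
    """Raised when a dataset cannot support training (e.g. single class)."""


class DegenerateFitError(ValueError):
    """Raised when the per-class score Gaussians are degenerate."""


@dataclass
class BayesModel:
    n_total: int
    n_active: int
    prior: float
    feature_stats: dict[int, tuple[int, int]]  # f -> (A_f, T_f)
    weights: dict[int, float]
    mu_active: float
    sigma_active: float
    mu_inactive: float
    sigma_inactive: float
    class_threshold: float
    activity_cutoff: float | None = None


@dataclass(frozen=True)
class PredictionRecord:
    compound_id: str
    raw_score: float
    est_p_good: float
    predicted_class: bool


@dataclass
class CrossValidationReport:
    n_runs: int
    split_fraction: float
    roc_scores: list[float]
    ef: dict[float, list[float]]  # fraction -> per-run EF
    roc_mean: float = field(init=False)
    roc_sd: float = field(init=False)
    ef_mean: dict[float, float] = field(init=False)
    ef_sd: dict[float, float] = field(init=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.roc_scores, dtype=float)
        self.roc_mean = float(r.mean())
        self.roc_sd = float(r.std(ddof=1)) if len(r) > 1 else 0.0
        self.ef_mean = {f: float(np.mean(v)) for f, v in self.ef.items()}
        self.ef_sd = {
            f: (float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
            for f, v in self.ef.items()
        }


def _laplacian_weight(a_f: int, t_f: int, prior: float) -> float:
    return math.log((a_f + 1.0) / (t_f * prior + 1.0))


def _choose_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Raw-score cutoff minimizing FP+FN on the training set.

    A compound is called active when its score ≥ threshold.  Candidate
    thresholds are midpoints between adjacent distinct scores plus the two
    open ends; ties in FP+FN break toward the lower (more sensitive) cutoff.
    """
    uniq = np.unique(scores)
    if len(uniq) == 1:
        candidates = np.array([uniq[0]])
    else:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    best_t, best_err = None, None
    for t in candidates:  # ascending, so first minimum is the lowest cutoff
        pred = scores >= t
        err = int(np.sum(pred & ~labels) + np.sum(~pred & labels))
        if best_err is None or err < best_err:
            best_t, best_err = float(t), err
    return best_t


def train(data: LabeledDataset) -> BayesModel:
    """Fit the Laplacian-corrected weights and the EstPGood score Gaussians."""
    labels = np.asarray(data.labels, dtype=bool)
    n_total = len(data)
    n_active = int(labels.sum())
    if n_active == 0 or n_active == n_total:
        raise TrainingError("training requires at least one active and one inactive")
    prior = n_active / n_total

    stats: dict[int, list[int]] = {}
    for fp, active in zip(data.fingerprints, labels):
        for f in fp:
            s = stats.get(f)
            if s is None:
                s = stats[f] = [0, 0]
            s[0] += int(active)
            s[1] += 1
    feature_stats = {f: (a, t) for f, (a, t) in stats.items()}
    weights = {f: _laplacian_weight(a, t, prior) for f, (a, t) in feature_stats.items()}

    raw = np.array(
        [sum(weights.get(f, 0.0) for f in fp) for fp in data.fingerprints]
    )
    act, inact = raw[labels], raw[~labels]
    mu_a, mu_i = float(act.mean()), float(inact.mean())
    sd_a = max(float(act.std(ddof=1)) if len(act) > 1 else 0.0, SIGMA_FLOOR)
    sd_i = max(float(inact.std(ddof=1)) if len(inact) > 1 else 0.0, SIGMA_FLOOR)

    return BayesModel(
        n_total=n_total,
        n_active=n_active,
        prior=prior,
        feature_stats=feature_stats,
        weights=weights,
        mu_active=mu_a,
        sigma_active=sd_a,
        mu_inactive=mu_i,
        sigma_inactive=sd_i,
        class_threshold=_choose_threshold(raw, labels),
        activity_cutoff=data.activity_cutoff,
    )


def score(model: BayesModel, fp: Iterable[int]) -> float:
    """Raw Bayesian score: sum of log weights over the compound's features."""
    w = model.weights
    return sum(w.get(f, 0.0) for f in fp)


def est_p_good(model: BayesModel, raw_score: float) -> float:
    """Normalized probability that a score belongs to the active class.

    Posterior from the two fitted class Gaussians:
    prior·g_A(s) / [prior·g_A(s) + (1−prior)·g_I(s)], computed in log space
    for numerical stability far in the tails.
    """
    if model.sigma_active <= 0 or model.sigma_inactive <= 0:
        raise DegenerateFitError("score Gaussians have non-positive sigma")
    la = (
        math.log(model.prior)
        - math.log(model.sigma_active)
        - 0.5 * ((raw_score - model.mu_active) / model.sigma_active) ** 2
    )
    li = (
        math.log(1.0 - model.prior)
        - math.log(model.sigma_inactive)
        - 0.5 * ((raw_score - model.mu_inactive) / model.sigma_inactive) ** 2
    )
    # p = e^la / (e^la + e^li) = 1 / (1 + e^(li - la))
    d = li - la
    if d > 700:
        return 0.0
    return 1.0 / (1.0 + math.exp(d))


def predict(
    model: BayesModel,
    ids: Sequence[str],
    fingerprints: Sequence[Iterable[int]],
) -> list[PredictionRecord]:
    """Score a library: raw score, EstPGood and binary class call per compound."""
    out = []
    for cid, fp in zip(ids, fingerprints):
        s = score(model, fp)
        out.append(
            PredictionRecord(
                compound_id=cid,
                raw_score=s,
                est_p_good=est_p_good(model, s),
                predicted_class=s >= model.class_threshold,
            )
        )
    return out


def _stratified_split(
    labels: np.ndarray, split: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Index split preserving the active fraction in both halves."""
    train_idx, test_idx = [], []
    for cls in (True, False):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        k = int(round(split * len(idx)))
        train_idx.append(idx[:k])
        test_idx.append(idx[k:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def cross_validate(
    data: LabeledDataset,
    n_runs: int = 20,
    split: float = 0.5,
    seed: int | None = None,
    ef_fractions: Sequence[float] = (0.01,),
) -> CrossValidationReport:
    """Repeated random stratified-split validation (default 20 × 50/50).

    Each run trains on `split` of the data and evaluates ROC score and
    enrichment factors on the held-out remainder, ranking held-out compounds
    by descending raw score.  Reproducible under a fixed seed.
    """
    labels = np.asarray(data.labels, dtype=bool)
    n_act = int(labels.sum())
    if n_act < 2 or (len(labels) - n_act) < 2:
        raise TrainingError("too few compounds per class for a stratified split")
    rng = np.random.default_rng(seed)

    roc_scores: list[float] = []
    ef: dict[float, list[float]] = {f: [] for f in ef_fractions}
    for _ in range(n_runs):
        tr, te = _stratified_split(labels, split, rng)
        sub = LabeledDataset(
            ids=[data.ids[i] for i in tr],
            fingerprints=[data.fingerprints[i] for i in tr],
            labels=[bool(labels[i]) for i in tr],
            activity_cutoff=data.activity_cutoff,
        )
        model = train(sub)
        test_scores = [score(model, data.fingerprints[i]) for i in te]
        # higher raw score = more likely active; ranked lists order best first
        ranked = metrics.rank_order(
            ids=[data.ids[i] for i in te],
            scores=[-s for s in test_scores],
            labels=[bool(labels[i]) for i in te],
        )
        roc_scores.append(metrics.roc_score(ranked))
        for f in ef_fractions:
            ef[f].append(metrics.enrichment(ranked, f))
    return CrossValidationReport(
        n_runs=n_runs, split_fraction=split, roc_scores=roc_scores, ef=ef
    )


def leave_one_out(data: LabeledDataset) -> list[float]:
    """Leave-one-out raw scores (optional validation mode).

    Returns, for each compound, its score under the model trained on all
    other compounds.  O(n²) in the number of compounds; intended for small
    curated sets.
    """
    out = []
    for i in range(len(data)):
        keep = [j for j in range(len(data)) if j != i]
        sub = LabeledDataset(
            ids=[data.ids[j] for j in keep],
            fingerprints=[data.fingerprints[j] for j in keep],
            labels=[data.labels[j] for j in keep],
            activity_cutoff=data.activity_cutoff,
        )
        out.append(score(train(sub), data.fingerprints[i]))
    return out


# --- persistence -----------------------------------------------------------

def save_model(model: BayesModel, path: str | Path) -> None:
    """Serialize a model to JSON; round-trips scores bit-exactly."""
    payload = {
        "format": "dualscreen-bayes/1",
        "n_total": model.n_total,
        "n_active": model.n_active,
        "prior": model.prior,
        "feature_stats": {str(f): list(at) for f, at in model.feature_stats.items()},
        "weights": {str(f): w for f, w in model.weights.items()},
        "mu_active": model.mu_active,
        "sigma_active": model.sigma_active,
        "mu_inactive": model.mu_inactive,
        "sigma_inactive": model.sigma_inactive,
        "class_threshold": model.class_threshold,
        "activity_cutoff": model.activity_cutoff,
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_model(path: str | Path) -> BayesModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "dualscreen-bayes/1":
        raise ValueError(f"{path}: not a dualscreen Bayes model file")
    return BayesModel(
        n_total=payload["n_total"],
        n_active=payload["n_active"],
        prior=payload["prior"],
        feature_stats={
            int(f): (a, t) for f, (a, t) in payload["feature_stats"].items()
        },
        weights={int(f): w for f, w in payload["weights"].items()},
        mu_active=payload["mu_active"],
        sigma_active=payload["sigma_active"],
        mu_inactive=payload["mu_inactive"],
        sigma_inactive=payload["sigma_inactive"],
        class_threshold=payload["class_threshold"],
        activity_cutoff=payload["activity_cutoff"],
    )
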