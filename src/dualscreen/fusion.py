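"""Hierarchical consensus ("data fusion") of ensemble-docking scores.

Per-pose scores from docking one library against several receptor
conformations are aggregated in three stages into one consensus score per
compound:

1. *pose level* — within each (protein model, ligand representation), the
   pose scores are reduced by Top1, MeanTop3 or MeanTop5;
2. *representation level* — within each protein model, the per-representation
   scores of a compound are reduced by Top (best) or Mean (of all);
3. *protein level* — the per-protein scores are reduced by Top1, MeanTop3 or
   MeanTop5.

All 3 × 2 × 3 = 18 operator triples form the scheme family; a scheme is named
by joining its operators, e.g. ``Top1_Top_Top1`` (the all-best scheme, which
equals the global minimum pose score of a compound).

Scores are minimized throughout: **"top" always means the minimum**, because
docking scores are better when lower.  MeanTopK with fewer than K available
values falls back to the mean of all of them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AggOp",
    "FusionScheme",
    "POSE_OPS",
    "REP_OPS",
    "PROTEIN_OPS",
    "enumerate_schemes",
    "get_scheme",
    "read_score_table",
    "validate_score_table",
    "fuse",
    "fuse_all",
    "score_thresholds",
]

SCORE_COLUMNS = ["protein_model", "compound_id", "representation_id", "pose_id", "score"]


@dataclass(frozen=True)
class AggOp:
    """One aggregation operator: the best value, or the mean of the k best."""

    name: str
    kind: str  # "top" | "mean_top" | "mean_all"
    k: int = 1

    def __call__(self, values: np.ndarray) -> float:
        v = np.sort(np.asarray(values, dtype=float))
        if self.kind == "top":
            return float(v[0])
        if self.kind == "mean_all":
            return float(v.mean())
        if len(v) < self.k:
            logger.debug("mean_top%d on %d values: using mean of all", self.k, len(v))
        return float(v[: self.k].mean())


POSE_OPS = (
    AggOp("Top1", "top"),
    AggOp("MeanTop3", "mean_top", 3),
    AggOp("MeanTop5", "mean_top", 5),
)
REP_OPS = (
    AggOp("Top", "top"),
    AggOp("Mean", "mean_all"),
)
PROTEIN_OPS = (
    AggOp("Top1", "top"),
    AggOp("MeanTop3", "mean_top", 3),
    AggOp("MeanTop5", "mean_top", 5),
)


@dataclass(frozen=True)
class FusionScheme:
    pose_op: AggOp
    rep_op: AggOp
    protein_op: AggOp

    @property
    def name(self) -> str:
        return f"{self.pose_op.name}_{self.rep_op.name}_{self.protein_op.name}"


def enumerate_schemes() -> list[FusionScheme]:
    """All 18 aggregation schemes, in deterministic operator order."""
    return [
        FusionScheme(p, r, m)
        for p, r, m in itertools.product(POSE_OPS, REP_OPS, PROTEIN_OPS)
    ]


def get_scheme(name: str) -> FusionScheme:
    """Look up a scheme by its joined-triple name, e.g. ``Top1_Top_Top1``.

    Accepts hyphens and any case (``top1-top-top1``) for CLI convenience.
    """
    wanted = name.replace("-", "_").lower()
    for scheme in enumerate_schemes():
        if scheme.name.lower() == wanted:
            return scheme
    raise KeyError(f"unknown fusion scheme {name!r}")


def read_score_table(path) -> pd.DataFrame:
    """Read a delimited per-pose score table with the standard header."""
    df = pd.read_csv(path, sep=None, engine="python")
    return validate_score_table(df)


def validate_score_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(SCORE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"score table missing columns {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("empty score table")
    if not np.isfinite(table["score"]).all():
        raise ValueError("score table contains non-finite scores")
    key = ["protein_model", "compound_id", "representation_id", "pose_id"]
    if table.duplicated(subset=key).any():
        raise ValueError("duplicate (protein, compound, representation, pose) rows")
    return table


def _aggregate(df: pd.DataFrame, by: list[str], op: AggOp) -> pd.DataFrame:
    grouped = df.sort_values("score", kind="stable").groupby(by, sort=False)
    if op.kind == "top":
        out = grouped["score"].min()
    elif op.kind == "mean_all":
        out = grouped["score"].mean()
    else:  # mean of the k best; groups smaller than k use all their values
        out = grouped.head(op.k).groupby(by, sort=False)["score"].mean()
    return out.reset_index()


def fuse(table: pd.DataFrame, scheme: FusionScheme) -> pd.DataFrame:
    """Apply one scheme to a per-pose score table.

    Returns a frame with columns ``compound_id, scheme, fused_score`` sorted
    ascending by fused score (ties by compound id).  Compounds appear once
    each; a compound with no rows in the table simply cannot appear.
    """
    table = validate_score_table(table)
    lvl1 = _aggregate(table, ["compound_id", "protein_model", "representation_id"], scheme.pose_op)
    lvl2 = _aggregate(lvl1, ["compound_id", "protein_model"], scheme.rep_op)
    lvl3 = _aggregate(lvl2, ["compound_id"], scheme.protein_op)
    out = lvl3.rename(columns={"score": "fused_score"})
    out["scheme"] = scheme.name
    out = out[["compound_id", "scheme", "fused_score"]]
    return out.sort_values(
        ["fused_score", "compound_id"], kind="stable", ignore_index=True
    )


def fuse_all(table: pd.DataFrame) -> pd.DataFrame:
    """Apply every scheme; concatenation of :func:`fuse` over all 18."""
    return pd.concat(
        [fuse(table, scheme) for scheme in enumerate_schemes()], ignore_index=True
    )


def score_thresholds(
    fused_scores: Sequence[float] | pd.Series, sds: Sequence[float]
) -> dict[float, float]:
    """Selection thresholds at z-scores below the consensus-score mean.

    threshold(k) = mean − k·SD of the fused-score distribution (sample SD).
    """
    x = np.asarray(fused_scores, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two fused scores")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance in fused scores; thresholds undefined")
    mean = float(x.mean())
    return {float(k): mean - float(k) * sd for k in sds}
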