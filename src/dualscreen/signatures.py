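"""Transcriptional-signature population statistics.

Given z-score expression signatures of drug perturbations (rows =
perturbations, columns = genes) and a perturbation → target annotation, this
module computes all pairwise Pearson correlations between signatures,
partitions the unordered pairs into four target-defined populations —
pairs within target A, pairs within target B, cross A–B pairs, and all other
pairs — and compares populations with Welch's two-sample t-test.  Elevated
within-target correlation relative to the background population is evidence
that inhibitors of that target produce a shared, distinctive transcriptional
response.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairPopulation",
    "PopulationComparison",
    "POPULATION_LABELS",
    "read_signature_matrix",
    "read_annotations",
    "pairwise_pearson",
    "partition_pairs",
    "welch_test",
    "compare_populations",
    "plot_populations",
]

POPULATION_LABELS = ("A_only", "B_only", "A_B_cross", "Other")


@dataclass
class PairPopulation:
    label: str
    values: np.ndarray  # pairwise Pearson r

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PopulationComparison:
    population_a: str
    population_b: str
    t: float
    df: float
    p_value: float


def read_signature_matrix(path) -> pd.DataFrame:
    """Read a delimited signature matrix: first column = perturbation id,
    remaining columns = gene z-scores."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: signature matrix contains missing values")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two gene columns")
    return df.astype(float)


def read_annotations(path) -> dict[str, str]:
    """Read a ``perturbation_id,target`` annotation table."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"perturbation_id", "target"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(df["perturbation_id"].astype(str), df["target"].astype(str)))


def pairwise_pearson(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson r for every unordered pair of signatures.

    Returns a frame with columns ``id_a, id_b, r`` covering the strict upper
    triangle in row order.  A zero-variance signature is an error (its
    correlation is undefined) and is reported by perturbation id.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two perturbations")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1)
    flat = matrix.index[np.flatnonzero(sd == 0)]
    if len(flat):
        raise ValueError(f"zero-variance signature(s): {list(flat)}")
    corr = np.corrcoef(values)
    iu, ju = np.triu_indices(len(matrix), k=1)
    ids = matrix.index.to_numpy()
    return pd.DataFrame(
        {"id_a": ids[iu], "id_b": ids[ju], "r": corr[iu, ju]}
    )


def partition_pairs(
    pairs: pd.DataFrame,
    annotation: Mapping[str, str],
    target_a: str,
    target_b: str,
) -> dict[str, PairPopulation]:
    """Partition pairwise correlations into the four target populations.

    A_only: both members annotated to target A; B_only: both to target B;
    A_B_cross: one member each; Other: every remaining pair.  The annotation
    must cover all perturbations, and no perturbation may carry both targets
    (the populations would no longer partition the pairs).
    """
    members = set(pairs["id_a"]).union(pairs["id_b"])
    unannotated = sorted(m for m in members if m not in annotation)
    if unannotated:
        raise ValueError(f"unannotated perturbation(s): {unannotated}")

    def group(pid: str) -> str:
        t = annotation[pid]
        targets = {t} if isinstance(t, str) else set(t)
        in_a, in_b = target_a in targets, target_b in targets
        if in_a and in_b:
            raise ValueError(f"perturbation {pid!r} annotated with both targets")
        return "A" if in_a else "B" if in_b else "O"

    buckets: dict[str, list[float]] = {label: [] for label in POPULATION_LABELS}
    ga = pairs["id_a"].map(group)
    gb = pairs["id_b"].map(group)
    for a, b, r in zip(ga, gb, pairs["r"]):
        pair = frozenset((a, b)) if a != b else {a}
        if pair == {"A"}:
            buckets["A_only"].append(r)
        elif pair == {"B"}:
            buckets["B_only"].append(r)
        elif pair == {"A", "B"}:
            buckets["A_B_cross"].append(r)
        else:
            buckets["Other"].append(r)
    return {
        label: PairPopulation(label, np.asarray(vals, dtype=float))
        for label, vals in buckets.items()
    }


def welch_test(x: Sequence[float], y: Sequence[float]) -> PopulationComparison:
    """Welch two-sample t-test (unequal variances), two-sided.

    t = (x̄ − ȳ) / sqrt(s²_x/n_x + s²_y/n_y) with Welch–Satterthwaite
    degrees of freedom; p from the t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        # identical constant samples: no evidence of any difference
        return PopulationComparison("x", "y", 0.0, float(nx + ny - 2), 1.0)
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return PopulationComparison("x", "y", float(t), float(df), float(p))


def compare_populations(
    populations: Mapping[str, PairPopulation],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Welch tests between populations of pairwise correlations.

    By default compares every unordered pair of the populations present
    (with ≥ 2 values each).  Returns a frame with columns
    ``population_a, population_b, t, df, p_value``.
    """
    if pairs is None:
        labels = [l for l in POPULATION_LABELS if l in populations]
        pairs = list(itertools.combinations(labels, 2))
    rows = []
    for a, b in pairs:
        pa, pb = populations[a], populations[b]
        if pa.n < 2 or pb.n < 2:
            continue
        cmp = welch_test(pa.values, pb.values)
        rows.append((a, b, cmp.t, cmp.df, cmp.p_value))
    return pd.DataFrame(
        rows, columns=["population_a", "population_b", "t", "df", "p_value"]
    )


def plot_populations(populations: Mapping[str, PairPopulation], out_path) -> None:
    """Box plot of the four pairwise-correlation populations (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [l for l in POPULATION_LABELS if l in populations]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([populations[l].values for l in labels], tick_labels=labels)
    ax.set_ylabel("pairwise Pearson r")
    ax.set_xlabel("signature pair population")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
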