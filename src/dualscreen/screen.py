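"""End-to-end dual-target screening cascade.

The cascade mirrors a high-throughput dual-inhibitor screening funnel:

1. a compound library (fingerprints + physicochemical profiles) is scored by
   two activity classifiers for the first target (trained at two potency
   cutoffs) and only compounds called active by *both* survive;
2. survivors must clear a normalized-probability (EstPGood) floor and a set
   of drug-likeness property caps;
3. survivors are ranked by a consensus ensemble-docking score against the
   second target, and hits are selected below a statistical threshold of
   mean − k·SD of the survivors' consensus-score distribution.

Default filter thresholds: EstPGood ≥ 0.05, MW ≤ 500 Da, HBA ≤ 10, HBD ≤ 5,
rotatable bonds ≤ 10, PSA ≤ 250 Å², ALogP ≤ 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import bayes, fusion, metrics
from .compounds import PhyschemProfile

logger = logging.getLogger(__name__)

__all__ = [
    "FilterPolicy",
    "LibraryEntry",
    "ScreenResult",
    "apply_cascade",
    "select_hits",
    "read_library",
    "write_library",
]

LIBRARY_COLUMNS = ["id", "mw", "hba", "hbd", "rotb", "psa", "alogp", "features"]


@dataclass(frozen=True)
class FilterPolicy:
    """Probability and drug-likeness thresholds for the pre-docking cascade."""

    est_p_good_min: float = 0.05
    mw_max: float = 500.0
    hba_max: int = 10
    hbd_max: int = 5
    rotb_max: int = 10
    psa_max: float = 250.0
    alogp_max: float = 5.0
    require_dual_active: bool = True

    def passes_properties(self, p: PhyschemProfile) -> bool:
        return (
            p.mw <= self.mw_max
            and p.hba <= self.hba_max
            and p.hbd <= self.hbd_max
            and p.rotb <= self.rotb_max
            and p.psa <= self.psa_max
            and p.alogp <= self.alogp_max
        )


@dataclass(frozen=True)
class LibraryEntry:
    """A screening-library compound: fingerprint plus property profile.

    `profile` may be None (e.g. descriptor failure upstream); such compounds
    fail the property stage closed.
    """

    id: str
    fingerprint: frozenset[int]
    profile: PhyschemProfile | None = None


@dataclass
class ScreenResult:
    """Per-compound cascade outcome plus per-stage attrition counts."""

    table: pd.DataFrame  # id, active_a, active_b, dual_active, est_p_good_a/b, prob_pass, physchem_pass, survivor
    stage_counts: dict[str, int]


def apply_cascade(
    library: Sequence[LibraryEntry],
    model_a: bayes.BayesModel,
    model_b: bayes.BayesModel,
    policy: FilterPolicy | None = None,
) -> ScreenResult:
    """Run the pre-docking stages: dual class call → EstPGood → properties.

    The EstPGood floor applies to model_a (the model trained at the lower,
    more inclusive potency cutoff); both probabilities are reported.
    Survivor flags are conjunctive: a survivor passed every prior stage.
    """
    policy = policy or FilterPolicy()
    rows = []
    for entry in library:
        sa = bayes.score(model_a, entry.fingerprint)
        sb = bayes.score(model_b, entry.fingerprint)
        active_a = sa >= model_a.class_threshold
        active_b = sb >= model_b.class_threshold
        dual = active_a and active_b
        epg_a = bayes.est_p_good(model_a, sa)
        epg_b = bayes.est_p_good(model_b, sb)
        stage1 = dual if policy.require_dual_active else True
        stage2 = stage1 and epg_a >= policy.est_p_good_min
        if entry.profile is None:
            physchem_ok = False
            if stage2:
                logger.warning("compound %s has no property profile; fails closed", entry.id)
        else:
            physchem_ok = policy.passes_properties(entry.profile)
        stage3 = stage2 and physchem_ok
        rows.append(
            (entry.id, active_a, active_b, dual, epg_a, epg_b, stage2, physchem_ok, stage3)
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "id",
            "active_a",
            "active_b",
            "dual_active",
            "est_p_good_a",
            "est_p_good_b",
            "prob_pass",
            "physchem_pass",
            "survivor",
        ],
    )
    stage_counts = {
        "input": len(table),
        "dual_active": int(table["dual_active"].sum())
        if policy.require_dual_active
        else len(table),
        "est_p_good": int(table["prob_pass"].sum()),
        "physchem": int(table["survivor"].sum()),
    }
    logger.info("cascade attrition: %s", stage_counts)
    return ScreenResult(table=table, stage_counts=stage_counts)


def merge_results(primary: ScreenResult, secondary: ScreenResult) -> ScreenResult:
    """Union of survivors from two filter policies over the same library.

    Emulates sampling both "high probability, relaxed properties" and
    "relaxed probability, strict properties" selection regimes.
    """
    if not primary.table["id"].equals(secondary.table["id"]):
        raise ValueError("results must cover the same library in the same order")
    table = primary.table.copy()
    table["survivor"] = primary.table["survivor"] | secondary.table["survivor"]
    counts = dict(primary.stage_counts)
    counts["physchem"] = int(table["survivor"].sum())
    return ScreenResult(table=table, stage_counts=counts)


def select_hits(
    result: ScreenResult,
    fused: pd.DataFrame | Mapping[str, float],
    sd_cutoff: float = 2.0,
    max_hits: int | None = None,
    allow_list: Iterable[str] | None = None,
    diversity_cutoff: float | None = None,
    fingerprints: Mapping[str, frozenset[int]] | None = None,
) -> pd.DataFrame:
    """Rank cascade survivors by consensus docking score and select hits.

    The selection threshold is mean − sd_cutoff·SD of the survivors'
    fused-score distribution (the docked-compound distribution).  Survivors
    lacking a fused score are dropped with a warning.  Optional stages: an
    external allow-list (e.g. vendor availability) and a
    pick-one-per-cluster diversity pass (leader clustering at
    `diversity_cutoff`; requires `fingerprints`).

    Returns a frame ``id, fused_score`` ranked ascending (best first).
    """
    if isinstance(fused, pd.DataFrame):
        fused_map = dict(zip(fused["compound_id"], fused["fused_score"]))
    else:
        fused_map = dict(fused)
    survivors = result.table.loc[result.table["survivor"], "id"].tolist()
    if not survivors:
        logger.warning("empty survivor set; no hits selected")
        return pd.DataFrame(columns=["id", "fused_score"])
    scored = [(cid, fused_map[cid]) for cid in survivors if cid in fused_map]
    dropped = len(survivors) - len(scored)
    if dropped:
        logger.warning("%d survivors lack fused docking scores; dropped", dropped)
    if len(scored) < 2:
        logger.warning("fewer than two docked survivors; no hits selected")
        return pd.DataFrame(columns=["id", "fused_score"])
    scores = [s for _, s in scored]
    threshold = fusion.score_thresholds(scores, [sd_cutoff])[sd_cutoff]
    hits = sorted(
        ((cid, s) for cid, s in scored if s <= threshold), key=lambda t: (t[1], t[0])
    )
    if allow_list is not None:
        allowed = set(allow_list)
        hits = [(cid, s) for cid, s in hits if cid in allowed]
    if diversity_cutoff is not None:
        if fingerprints is None:
            raise ValueError("diversity pruning requires fingerprints")
        fps = [fingerprints[cid] for cid, _ in hits]
        if fps:
            assignment = metrics.leader_cluster(fps, diversity_cutoff)
            seen: set[int] = set()
            pruned = []
            for (cid, s), k in zip(hits, assignment):
                if k not in seen:
                    seen.add(k)
                    pruned.append((cid, s))
            hits = pruned
    if max_hits is not None:
        hits = hits[:max_hits]
    return pd.DataFrame(hits, columns=["id", "fused_score"])


# --- library table I/O -----------------------------------------------------

def write_library(entries: Sequence[LibraryEntry], path) -> None:
    """Write a library as TSV: id, six properties, space-separated features."""
    with open(path, "w") as fh:
        fh.write("\t".join(LIBRARY_COLUMNS) + "\n")
        for e in entries:
            p = e.profile
            props = (
                ["", "", "", "", "", ""]
                if p is None
                else [
                    f"{p.mw:.4f}",
                    str(p.hba),
                    str(p.hbd),
                    str(p.rotb),
                    f"{p.psa:.4f}",
                    f"{p.alogp:.4f}",
                ]
            )
            feats = " ".join(str(f) for f in sorted(e.fingerprint))
            fh.write("\t".join([e.id, *props, feats]) + "\n")


def read_library(path) -> list[LibraryEntry]:
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != LIBRARY_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            cid, mw, hba, hbd, rotb, psa, alogp, feats = line.rstrip("\n").split("\t")
            profile = (
                None
                if mw == ""
                else PhyschemProfile(
                    mw=float(mw),
                    hba=int(hba),
                    hbd=int(hbd),
                    rotb=int(rotb),
                    psa=float(psa),
                    alogp=float(alogp),
                )
            )
            fp = frozenset(int(f) for f in feats.split()) if feats else frozenset()
            entries.append(LibraryEntry(id=cid, fingerprint=fp, profile=profile))
    return entries
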