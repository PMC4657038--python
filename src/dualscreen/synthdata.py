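"""Seedable synthetic-data generators for offline pipeline testing.

Every stage of the screening pipeline assumes inputs with a particular
statistical structure; these generators produce miniature datasets with that
structure planted, so the whole pipeline can be exercised and validated
without proprietary activity databases, a commercial docking engine, or
external decoy/signature services:

* labeled fingerprint sets whose actives are enriched in a small block of
  marker features (knowledge-base-style training data);
* property-matched but topologically dissimilar decoys (DUD-E-style);
* per-pose ensemble-docking score tables where planted actives draw from a
  lower (better) score distribution (docking-engine-style output);
* z-score signature matrices with block correlation by target group
  (L1000-style transcriptional signatures).

All generators are pure functions of (config, seed).  Fingerprints here are
abstract integer feature sets with no underlying structures; every
downstream module accepts them as such.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compounds import LabeledDataset, PhyschemProfile, tanimoto
from .screen import LibraryEntry

__all__ = [
    "GeneratorConfig",
    "DecoyGenerationError",
    "ScreenScenario",
    "gen_labeled_compounds",
    "gen_physchem_profiles",
    "gen_decoys",
    "gen_docking_table",
    "gen_signatures",
    "gen_screen_scenario",
    "write_labeled_dataset",
    "read_labeled_dataset",
]


class DecoyGenerationError(RuntimeError):
    """Raised when the tolerance/similarity-ceiling combination is infeasible."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for all synthetic generators.

    The defaults are the conditions under which the pipeline is validated:
    a clearly separable (but not noise-free) planted feature signal for the
    classifier, a four-sigma class separation in per-pose docking scores, and
    signature groups of 12 and 4 perturbations with within-group correlation
    0.4 over a background of 0.05.
    """

    seed: int = 0
    # labeled fingerprint sets
    n_active: int = 100
    n_inactive: int = 900
    n_features: int = 600
    n_marker_features: int = 25
    baseline_feature_rate: float = 0.05
    marker_enrichment: float = 10.0  # active marker rate = enrichment × baseline
    # docking score tables
    n_protein_models: int = 9
    max_representations: int = 3
    max_poses: int = 5
    docking_mu_active: float = -9.0
    docking_mu_inactive: float = -5.0
    docking_sigma: float = 1.0
    # signature matrices
    n_genes: int = 200
    signature_groups: tuple[tuple[str, int], ...] = (
        ("EGFR", 12),
        ("BRD4", 4),
        ("Other", 50),
    )
    within_correlation: float = 0.4
    between_correlation: float = 0.05
    # decoys
    decoy_mw_tolerance: float = 25.0
    decoy_hba_tolerance: int = 1
    decoy_hbd_tolerance: int = 1
    decoy_similarity_ceiling: float = 0.35
    decoy_max_retries: int = 50
    # end-to-end screen scenario
    library_n_dual: int = 40
    library_n_classifier_only: int = 760
    library_n_background: int = 1200

    def __post_init__(self) -> None:
        if not 0 <= self.baseline_feature_rate <= 1:
            raise ValueError("baseline_feature_rate must be in [0, 1]")
        if not 0 <= self.between_correlation <= self.within_correlation <= 1:
            raise ValueError(
                "need 0 <= between_correlation <= within_correlation <= 1"
            )
        if self.n_marker_features > self.n_features:
            raise ValueError("n_marker_features cannot exceed n_features")
        if self.marker_enrichment < 0:
            raise ValueError("marker_enrichment must be non-negative")


def _rng(cfg: GeneratorConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(cfg.seed if seed is None else seed)


def _feature_rates(cfg: GeneratorConfig, active: bool) -> np.ndarray:
    rates = np.full(cfg.n_features, cfg.baseline_feature_rate)
    if active:
        rates[: cfg.n_marker_features] = min(
            1.0, cfg.marker_enrichment * cfg.baseline_feature_rate
        )
    return rates


def _draw_fingerprints(
    n: int, rates: np.ndarray, rng: np.random.Generator
) -> list[frozenset[int]]:
    hits = rng.random((n, len(rates))) < rates
    return [frozenset(np.flatnonzero(row).tolist()) for row in hits]


def gen_labeled_compounds(
    cfg: GeneratorConfig, seed: int | None = None, id_prefix: str = "CPD"
) -> LabeledDataset:
    """Binary-fingerprint training set with an active-enriched marker block.

    Marker features (ids 0 .. n_marker_features−1) occur in actives at
    ``marker_enrichment × baseline_feature_rate`` (capped at 1) and in
    inactives at the baseline rate; all other features are baseline noise.
    """
    rng = _rng(cfg, seed)
    fps = _draw_fingerprints(
        cfg.n_active, _feature_rates(cfg, True), rng
    ) + _draw_fingerprints(cfg.n_inactive, _feature_rates(cfg, False), rng)
    n = cfg.n_active + cfg.n_inactive
    return LabeledDataset(
        ids=[f"{id_prefix}-{i:06d}" for i in range(n)],
        fingerprints=fps,
        labels=[i < cfg.n_active for i in range(n)],
    )


def gen_physchem_profiles(
    n: int, rng: np.random.Generator
) -> list[PhyschemProfile]:
    """Drug-like property profiles for synthetic library compounds.

    Distributions emulate a lead-like commercial catalogue: most compounds
    sit comfortably inside the standard drug-likeness caps, with realistic
    tails that a property filter will remove.
    """
    mw = np.clip(rng.normal(350.0, 60.0, n), 100.0, None)
    hba = rng.poisson(5.0, n)
    hbd = rng.poisson(2.0, n)
    rotb = rng.poisson(5.0, n)
    psa = np.clip(rng.normal(90.0, 40.0, n), 0.0, None)
    alogp = rng.normal(2.5, 1.2, n)
    return [
        PhyschemProfile(
            mw=float(mw[i]),
            hba=int(hba[i]),
            hbd=int(hbd[i]),
            rotb=int(rotb[i]),
            psa=float(psa[i]),
            alogp=float(alogp[i]),
        )
        for i in range(n)
    ]


def gen_decoys(
    actives: Sequence[tuple[PhyschemProfile, frozenset[int]]],
    per_active: int,
    cfg: GeneratorConfig,
    seed: int | None = None,
    id_prefix: str = "DCY",
) -> list[LibraryEntry]:
    """Property-matched, topologically dissimilar decoys (DUD-E style).

    Each decoy matches its seed active's MW/HBA/HBD within the configured
    tolerances but keeps maximum Tanimoto similarity to *every* active at or
    below the similarity ceiling.  Decoy fingerprints are drawn from a
    feature pool mostly disjoint from the library pool, with a sprinkle of
    shared background features so the similarity check is non-trivial.
    """
    if per_active < 1:
        raise ValueError("per_active must be >= 1")
    rng = _rng(cfg, seed)
    # inverted index over active features for fast max-Tanimoto checks
    feature_owners: dict[int, list[int]] = {}
    for ai, (_, fp) in enumerate(actives):
        for f in fp:
            feature_owners.setdefault(f, []).append(ai)
    active_sizes = [len(fp) for _, fp in actives]

    def max_tanimoto(decoy_fp: frozenset[int]) -> float:
        inter: dict[int, int] = {}
        for f in decoy_fp:
            for ai in feature_owners.get(f, ()):
                inter[ai] = inter.get(ai, 0) + 1
        nd = len(decoy_fp)
        best = 0.0
        for ai, c in inter.items():
            best = max(best, c / (active_sizes[ai] + nd - c))
        return best

    decoy_pool = np.arange(cfg.n_features, 6 * cfg.n_features)
    shared_pool = np.arange(cfg.n_features)
    out: list[LibraryEntry] = []
    for ai, (profile, fp) in enumerate(actives):
        size = max(len(fp), 4)
        for j in range(per_active):
            for attempt in range(cfg.decoy_max_retries):
                n_shared = int(rng.integers(0, max(2, size // 8)))
                feats = frozenset(
                    rng.choice(decoy_pool, size=size - n_shared, replace=False).tolist()
                    + rng.choice(shared_pool, size=n_shared, replace=False).tolist()
                )
                if max_tanimoto(feats) <= cfg.decoy_similarity_ceiling:
                    break
            else:
                raise DecoyGenerationError(
                    f"could not generate a decoy under similarity ceiling "
                    f"{cfg.decoy_similarity_ceiling} for active {ai}"
                )
            decoy_profile = PhyschemProfile(
                mw=max(1.0, profile.mw + float(rng.uniform(-cfg.decoy_mw_tolerance, cfg.decoy_mw_tolerance))),
                hba=max(0, profile.hba + int(rng.integers(-cfg.decoy_hba_tolerance, cfg.decoy_hba_tolerance + 1))),
                hbd=max(0, profile.hbd + int(rng.integers(-cfg.decoy_hbd_tolerance, cfg.decoy_hbd_tolerance + 1))),
                rotb=profile.rotb,
                psa=max(0.0, profile.psa + float(rng.uniform(-10.0, 10.0))),
                alogp=profile.alogp + float(rng.uniform(-0.5, 0.5)),
            )
            out.append(
                LibraryEntry(
                    id=f"{id_prefix}-{ai:04d}-{j:04d}",
                    fingerprint=feats,
                    profile=decoy_profile,
                )
            )
    return out


def gen_docking_table(
    ids: Sequence[str],
    labels: Sequence[bool],
    cfg: GeneratorConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-pose ensemble-docking score table with planted class separation.

    Each compound gets 1–3 ligand representations; each (protein model,
    representation) gets 1–5 poses.  Pose scores are drawn from a normal with
    the class mean (actives lower/better) and common sigma.
    """
    if len(ids) != len(labels):
        raise ValueError("ids and labels must be aligned")
    rng = _rng(cfg, seed)
    proteins = [f"P{k + 1}" for k in range(cfg.n_protein_models)]
    rows_protein, rows_cid, rows_rep, rows_pose, rows_mu = [], [], [], [], []
    for cid, active in zip(ids, labels):
        mu = cfg.docking_mu_active if active else cfg.docking_mu_inactive
        n_reps = int(rng.integers(1, cfg.max_representations + 1))
        for protein in proteins:
            for r in range(n_reps):
                n_poses = int(rng.integers(1, cfg.max_poses + 1))
                for p in range(n_poses):
                    rows_protein.append(protein)
                    rows_cid.append(cid)
                    rows_rep.append(f"{cid}-R{r + 1}")
                    rows_pose.append(p + 1)
                    rows_mu.append(mu)
    scores = np.asarray(rows_mu) + cfg.docking_sigma * rng.standard_normal(len(rows_mu))
    return pd.DataFrame(
        {
            "protein_model": rows_protein,
            "compound_id": rows_cid,
            "representation_id": rows_rep,
            "pose_id": rows_pose,
            "score": scores,
        }
    )


def gen_signatures(
    cfg: GeneratorConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Z-score signature matrix with block correlation by target group.

    Shared-factor model: every signature loads on a global factor (between-
    group correlation), members of a named group additionally load on a group
    factor raising within-group correlation to the configured value; the
    ``Other`` group carries no group factor.  All variances are 1, so entries
    behave like z-scores.
    """
    rng = _rng(cfg, seed)
    rb, rw = cfg.between_correlation, cfg.within_correlation
    g = rng.standard_normal(cfg.n_genes)
    rows, ids, annotation = [], [], {}
    for group, size in cfg.signature_groups:
        u = rng.standard_normal(cfg.n_genes)
        grouped = group != "Other"
        for i in range(size):
            e = rng.standard_normal(cfg.n_genes)
            if grouped:
                z = np.sqrt(rb) * g + np.sqrt(rw - rb) * u + np.sqrt(1 - rw) * e
            else:
                z = np.sqrt(rb) * g + np.sqrt(1 - rb) * e
            pid = f"SIG-{group}-{i:03d}"
            ids.append(pid)
            annotation[pid] = group
            rows.append(z)
    matrix = pd.DataFrame(
        np.vstack(rows),
        index=ids,
        columns=[f"G{j:04d}" for j in range(cfg.n_genes)],
    )
    return matrix, annotation


@dataclass
class ScreenScenario:
    """A complete planted-signal screening problem.

    ``training_a``/``training_b`` are independent draws of the labeled
    training set (same marker block) for the two classifier models; the
    library mixes planted dual actives (classifier markers *and* good docking
    scores), classifier-only actives (markers, ordinary docking scores) and
    background compounds.
    """

    training_a: LabeledDataset
    training_b: LabeledDataset
    library: list[LibraryEntry]
    docking_table: pd.DataFrame
    dual_active_ids: frozenset[str]


def gen_screen_scenario(
    cfg: GeneratorConfig, seed: int | None = None
) -> ScreenScenario:
    rng = _rng(cfg, seed)
    s = rng.integers(0, 2**31 - 1, size=4)
    training_a = gen_labeled_compounds(cfg, seed=int(s[0]), id_prefix="TRA")
    training_b = gen_labeled_compounds(cfg, seed=int(s[1]), id_prefix="TRB")

    lib_rng = np.random.default_rng(int(s[2]))
    n_marked = cfg.library_n_dual + cfg.library_n_classifier_only
    n_total = n_marked + cfg.library_n_background
    fps = _draw_fingerprints(
        n_marked, _feature_rates(cfg, True), lib_rng
    ) + _draw_fingerprints(cfg.library_n_background, _feature_rates(cfg, False), lib_rng)
    profiles = gen_physchem_profiles(n_total, lib_rng)
    ids = [f"LIB-{i:06d}" for i in range(n_total)]
    library = [
        LibraryEntry(id=ids[i], fingerprint=fps[i], profile=profiles[i])
        for i in range(n_total)
    ]
    docking_labels = [i < cfg.library_n_dual for i in range(n_total)]
    docking_table = gen_docking_table(ids, docking_labels, cfg, seed=int(s[3]))
    return ScreenScenario(
        training_a=training_a,
        training_b=training_b,
        library=library,
        docking_table=docking_table,
        dual_active_ids=frozenset(ids[: cfg.library_n_dual]),
    )


# --- plain-text round-trip for labeled sets --------------------------------

def write_labeled_dataset(data: LabeledDataset, path) -> None:
    """Write a labeled set as TSV: id, label, space-separated feature ids."""
    with open(path, "w") as fh:
        fh.write("id\tlabel\tfeatures\n")
        for cid, label, fp in zip(data.ids, data.labels, data.fingerprints):
            feats = " ".join(str(f) for f in sorted(fp))
            fh.write(f"{cid}\t{int(label)}\t{feats}\n")


def read_labeled_dataset(path, activity_cutoff: float | None = None) -> LabeledDataset:
    ids, labels, fps = [], [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["id", "label", "features"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            cid, label, feats = line.rstrip("\n").split("\t")
            ids.append(cid)
            labels.append(bool(int(label)))
            fps.append(frozenset(int(f) for f in feats.split()) if feats else frozenset())
    return LabeledDataset(ids=ids, fingerprints=fps, labels=labels, activity_cutoff=activity_cutoff)
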