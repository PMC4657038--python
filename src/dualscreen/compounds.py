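"""Compound ingestion, standardization, fingerprinting and activity handling.

Structures are carried as canonical SMILES of the largest organic fragment
(salt/addend stripping), with the toolkit's canonical tautomer applied so that
re-standardizing is idempotent.  Fingerprints are sparse ECFP-style circular
substructure feature sets (radius 2, i.e. ECFP4); downstream modules treat them
as plain integer sets, so synthetic libraries without underlying structures are
first-class citizens.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Compound",
    "PhyschemProfile",
    "ActivityRecord",
    "LabeledDataset",
    "StandardizationError",
    "DescriptorError",
    "UndefinedSimilarityError",
    "standardize",
    "fingerprint",
    "physchem",
    "tanimoto",
    "p_transform",
    "aggregate_activities",
    "read_smiles_file",
    "read_sdf",
    "read_activity_table",
]


class StandardizationError(ValueError):
    """Raised when a structure string cannot be parsed or standardized."""


class DescriptorError(ValueError):
    """Raised when descriptor calculation fails for a compound."""


class UndefinedSimilarityError(ValueError):
    """Tanimoto similarity of two empty feature sets is undefined."""


@dataclass(frozen=True)
class Compound:
    """A standardized compound: canonical SMILES of the largest organic fragment."""

    id: str
    structure: str
    source: str = ""


@dataclass(frozen=True)
class PhyschemProfile:
    """Basic physicochemical profile used by the drug-likeness filter cascade.

    mw in Daltons, psa in Å²; hba/hbd/rotb are counts; alogp is the
    Crippen octanol–water partition coefficient (unitless).
    """

    mw: float
    hba: int
    hbd: int
    rotb: int
    psa: float
    alogp: float

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise ValueError(f"mw must be positive, got {self.mw}")
        if min(self.hba, self.hbd, self.rotb) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class ActivityRecord:
    """One potency measurement, p-transformed: p_activity = −log10(molar value)."""

    compound_id: str
    target: str
    activity_type: str  # IC50 | Kd | Ki
    p_activity: float
    source: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.p_activity):
            raise ValueError(
                f"non-finite p_activity for compound {self.compound_id!r}"
            )


@dataclass
class LabeledDataset:
    """Fingerprinted compounds with binary active/inactive labels.

    When derived from an activity table, label = (median p_activity ≥ cutoff).
    Fingerprints are plain feature-id sets; no structures are required.
    """

    ids: list[str]
    fingerprints: list[frozenset[int]]
    labels: list[bool]
    activity_cutoff: float | None = None

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.fingerprints) == len(self.labels)):
            raise ValueError("ids, fingerprints and labels must be aligned")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_active(self) -> int:
        return sum(self.labels)


# --- standardization -------------------------------------------------------

_TAUTOMER_CANONICALIZER = rdMolStandardize.TautomerEnumerator()


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the fragment with the most heavy atoms; prefer carbon-containing
    fragments; break ties by lexicographic canonical SMILES."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    organic = [f for f in frags if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
    candidates = organic or list(frags)
    return min(
        candidates,
        key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)),
    )


def standardize(raw: str, id: str = "", source: str = "") -> Compound:
    """Standardize a structure string into a :class:`Compound`.

    Removes salts and other addends (largest organic fragment), applies the
    canonical tautomer, and returns the canonical SMILES.  Idempotent:
    ``standardize(standardize(s).structure).structure == standardize(s).structure``.

    Raises
    ------
    StandardizationError
        If `raw` cannot be parsed.
    """
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise StandardizationError(f"unparseable structure: {raw!r}")
    frag = _largest_organic_fragment(mol)
    try:
        frag = _TAUTOMER_CANONICALIZER.Canonicalize(frag)
    except Exception as exc:  # pragma: no cover - rare RDKit corner cases
        raise StandardizationError(f"tautomer canonicalization failed: {raw!r}") from exc
    return Compound(id=id, structure=Chem.MolToSmiles(frag), source=source)


# --- fingerprints ----------------------------------------------------------

_MORGAN_GENERATORS: dict[int, rdFingerprintGenerator.FingerprintGenerator64] = {}


def fingerprint(compound: Compound | str, radius: int = 2) -> frozenset[int]:
    """Sparse circular-fingerprint feature set (hashed environment ids).

    radius 2 corresponds to ECFP4.  Deterministic: the same canonical
    structure always yields the same feature set.
    """
    structure = compound.structure if isinstance(compound, Compound) else compound
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StandardizationError(f"unparseable structure: {structure!r}")
    gen = _MORGAN_GENERATORS.get(radius)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
        _MORGAN_GENERATORS[radius] = gen
    sparse = gen.GetSparseCountFingerprint(mol)
    return frozenset(sparse.GetNonzeroElements())


def physchem(compound: Compound | str) -> PhyschemProfile:
    """Compute the six-descriptor profile (MW, HBA, HBD, RotB, TPSA, logP)."""
    structure = compound.structure if isinstance(compound, Compound) else compound
    cid = compound.id if isinstance(compound, Compound) else ""
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise DescriptorError(f"descriptor failure for compound {cid!r}: unparseable")
    try:
        return PhyschemProfile(
            mw=Descriptors.MolWt(mol),
            hba=Lipinski.NumHAcceptors(mol),
            hbd=Lipinski.NumHDonors(mol),
            rotb=Lipinski.NumRotatableBonds(mol),
            psa=Descriptors.TPSA(mol),
            alogp=Crippen.MolLogP(mol),
        )
    except Exception as exc:  # pragma: no cover
        raise DescriptorError(f"descriptor failure for compound {cid!r}") from exc


def tanimoto(a: Iterable[int], b: Iterable[int]) -> float:
    """Tanimoto similarity |a∩b| / |a∪b| of two feature sets, in [0, 1]."""
    sa, sb = set(a), set(b)
    union = len(sa | sb)
    if union == 0:
        raise UndefinedSimilarityError("Tanimoto of two empty feature sets")
    return len(sa & sb) / union


# --- activities ------------------------------------------------------------

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}
_ACTIVITY_TYPES = {"IC50", "Kd", "Ki"}


def p_transform(value: float, units: str = "nM") -> float:
    """p-transform a potency: −log10 of the value in molar units."""
    try:
        factor = _UNIT_TO_MOLAR[units]
    except KeyError:
        raise ValueError(f"unknown units {units!r}; expected one of {sorted(_UNIT_TO_MOLAR)}")
    if not (value > 0 and math.isfinite(value)):
        raise ValueError(f"potency must be positive and finite, got {value}")
    return -math.log10(value * factor)


def aggregate_activities(records: Sequence[ActivityRecord]) -> dict[str, float]:
    """Collapse multiple measurements per compound to the median p_activity."""
    if not records:
        raise ValueError("no activity records given")
    for i, rec in enumerate(records):
        if not math.isfinite(rec.p_activity):
            raise ValueError(f"non-finite p_activity in record {i}")
    by_compound: dict[str, list[float]] = {}
    for rec in records:
        by_compound.setdefault(rec.compound_id, []).append(rec.p_activity)
    return {cid: statistics.median(vals) for cid, vals in by_compound.items()}


# --- file I/O --------------------------------------------------------------

def read_smiles_file(path: str | Path, source: str = "") -> list[Compound]:
    """Read a ``SMILES<TAB>id`` file, standardizing every record."""
    compounds = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"line{lineno}"
            try:
                c = standardize(smiles, id=cid, source=source or str(path))
            except StandardizationError as exc:
                raise StandardizationError(f"{path}:{lineno}: {exc}") from exc
            compounds.append(c)
    return compounds


def read_sdf(path: str | Path, id_property: str | None = None, source: str = "") -> list[Compound]:
    """Read a V2000 SDF; compound ids from the title line or `id_property`."""
    compounds = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            raise StandardizationError(f"{path}: unparseable record {i}")
        if id_property is not None and mol.HasProp(id_property):
            cid = mol.GetProp(id_property)
        else:
            cid = mol.GetProp("_Name") or f"record{i}"
        compounds.append(
            standardize(Chem.MolToSmiles(mol), id=cid, source=source or str(path))
        )
    return compounds


def read_activity_table(path: str | Path) -> list[ActivityRecord]:
    """Read a delimited activity table.

    Requires header ``compound_id,target,activity_type,value,units`` with
    units one of nM|µM|uM|mM|M; values are p-transformed on read.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"compound_id", "target", "activity_type", "value", "units"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        atype = str(row["activity_type"])
        if atype not in _ACTIVITY_TYPES:
            raise ValueError(f"{path}: row {idx}: unknown activity type {atype!r}")
        records.append(
            ActivityRecord(
                compound_id=str(row["compound_id"]),
                target=str(row["target"]),
                activity_type=atype,
                p_activity=p_transform(float(row["value"]), str(row["units"])),
                source=str(path),
            )
        )
    return records


def labeled_dataset_from_activities(
    fingerprints: Mapping[str, frozenset[int]],
    activities: Sequence[ActivityRecord],
    target: str,
    cutoff: float,
) -> LabeledDataset:
    """Build a labeled training set: active iff median p_activity ≥ cutoff.

    Compounds present in `fingerprints` but absent from the activity table are
    treated as presumed inactive, mirroring how large kinase knowledge bases
    label compounds with no reported activity against a target.
    """
    relevant = [r for r in activities if r.target == target]
    medians = aggregate_activities(relevant) if relevant else {}
    ids = sorted(fingerprints)
    return LabeledDataset(
        ids=ids,
        fingerprints=[fingerprints[i] for i in ids],
        labels=[medians.get(i, -math.inf) >= cutoff for i in ids],
        activity_cutoff=cutoff,
    )
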