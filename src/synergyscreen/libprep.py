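"""Compound-library preparation for similarity-based virtual screening.

Reads raw compound collections (SMILES, CSV or SDF), standardizes
structures, applies the screening-deck filters (salt stripping, molecular
weight window, allowed elements, stereo completeness for active
candidates), assigns activity labels from bioactivity records, and
extracts Bemis–Murcko scaffolds used for scaffold-recovery evaluation.

Activity labelling follows the common potency-threshold convention:
a compound measured in a dose–response type (Kd, AC50, IC50, Ki, EC50 or
Potency) at below 10 µM (10,000 nM) is *active*; anything above 20 µM is
*inactive*; the gap between the two thresholds, and any other measurement
type, is left *unlabeled* and excluded from both classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

__all__ = [
    "ACTIVE",
    "INACTIVE",
    "PRESUMED_INACTIVE",
    "UNLABELED",
    "ACYCLIC",
    "ALLOWED_ELEMENTS",
    "ALLOWED_STANDARD_TYPES",
    "CompoundRecord",
    "BioactivityRecord",
    "FilterVerdict",
    "LibPrepError",
    "label_activity",
    "strip_salts",
    "filter_compound",
    "murcko_scaffold",
    "canonical_smiles",
    "prepare_library",
    "read_compounds",
    "write_library",
]

# Activity labels
ACTIVE = "active"
INACTIVE = "inactive"
PRESUMED_INACTIVE = "presumed_inactive"
UNLABELED = "unlabeled"
ACTIVITY_LABELS = frozenset({ACTIVE, INACTIVE, PRESUMED_INACTIVE, UNLABELED})

#: Sentinel scaffold key for molecules without any ring system.
ACYCLIC = "ACYCLIC"

#: Elements tolerated in screening compounds; anything else is rejected.
ALLOWED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

#: Bioactivity measurement types accepted for activity labelling.
ALLOWED_STANDARD_TYPES = frozenset({"Kd", "AC50", "IC50", "Ki", "EC50", "Potency"})

ACTIVE_THRESHOLD_NM = 10_000.0
INACTIVE_THRESHOLD_NM = 20_000.0

MW_MIN = 250.0
MW_MAX = 1500.0


class LibPrepError(ValueError):
    """Raised for unusable input records (unparseable, inorganic-only ...)."""


@dataclass
class CompoundRecord:
    """One member of a screening library.

    ``structure`` is canonicalized on ingest; ``scaffold_key`` is the
    canonical SMILES of the Bemis–Murcko framework or :data:`ACYCLIC`.
    """

    compound_id: str
    structure: str
    activity: str = UNLABELED
    scaffold_key: Optional[str] = None
    mw: Optional[float] = None

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITY_LABELS:
            raise ValueError(f"unknown activity label: {self.activity!r}")


@dataclass(frozen=True)
class BioactivityRecord:
    """A single bioactivity measurement (concentration in nanomolar)."""

    compound_id: str
    standard_type: str
    standard_value: float


@dataclass(frozen=True)
class FilterVerdict:
    keep: bool
    reason: Optional[str] = None  # mw_out_of_range | disallowed_element |
    #                               undefined_stereo | parse_error


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES of ``smiles``; raises :class:`LibPrepError` on parse failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise LibPrepError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def label_activity(record: BioactivityRecord) -> str:
    """Map a bioactivity measurement to an activity label.

    Returns :data:`ACTIVE` for values strictly below 10,000 nM in an
    accepted measurement type, :data:`INACTIVE` for values strictly above
    20,000 nM, and :data:`UNLABELED` otherwise (including the
    [10,000, 20,000] nM gap and disallowed measurement types).
    """
    value = float(record.standard_value)
    if math.isnan(value) or value < 0:
        raise LibPrepError(
            f"{record.compound_id}: invalid standard_value {record.standard_value!r}"
        )
    if record.standard_type not in ALLOWED_STANDARD_TYPES:
        return UNLABELED
    if value < ACTIVE_THRESHOLD_NM:
        return ACTIVE
    if value > INACTIVE_THRESHOLD_NM:
        return INACTIVE
    return UNLABELED


def _is_organic(frag: Chem.Mol) -> bool:
    return any(atom.GetSymbol() == "C" for atom in frag.GetAtoms())


def strip_salts(structure: str) -> str:
    """Keep the major component of a salt / multi-fragment structure.

    The retained component is the largest *organic* (carbon-containing)
    fragment by heavy-atom count; ties are broken by lexicographic order
    of canonical SMILES. Single-fragment inputs are returned unchanged up
    to canonicalization. Counter-ions are not neutralized; the charge
    state of the retained fragment is preserved as given.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise LibPrepError(f"unparseable SMILES: {structure!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return Chem.MolToSmiles(mol)
    organic = [f for f in frags if _is_organic(f)]
    if not organic:
        raise LibPrepError(f"no organic fragment in {structure!r}")
    best = min(organic, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    return Chem.MolToSmiles(best)


def _has_undefined_stereocenter(mol: Chem.Mol) -> bool:
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    return any(assignment == "?" for _, assignment in centers)


def filter_compound(
    record: CompoundRecord, is_active_candidate: bool = False
) -> FilterVerdict:
    """Apply the screening-deck preparation filters to one compound.

    Salt stripping is applied before any check. Reject reasons:

    - ``parse_error`` — SMILES unparseable or inorganic-only;
    - ``mw_out_of_range`` — molecular weight outside [250, 1500] Da;
    - ``disallowed_element`` — atom outside :data:`ALLOWED_ELEMENTS`;
    - ``undefined_stereo`` — tetrahedral stereocenter without assigned
      configuration; only enforced when ``is_active_candidate`` is set,
      since only actives may serve as 3D queries and must be fully
      stereo-defined (library compounds with undefined centers can be
      enumerated at conformer-generation time instead).
    """
    try:
        stripped = strip_salts(record.structure)
    except LibPrepError:
        return FilterVerdict(False, "parse_error")
    mol = Chem.MolFromSmiles(stripped)
    if mol is None:  # pragma: no cover - strip_salts already parsed it
        return FilterVerdict(False, "parse_error")
    mw = Descriptors.MolWt(mol)
    if not (MW_MIN <= mw <= MW_MAX):
        return FilterVerdict(False, "mw_out_of_range")
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ALLOWED_ELEMENTS:
            return FilterVerdict(False, "disallowed_element")
    if is_active_candidate and _has_undefined_stereocenter(mol):
        return FilterVerdict(False, "undefined_stereo")
    return FilterVerdict(True, None)


def murcko_scaffold(structure: str) -> str:
    """Canonical Bemis–Murcko framework (ring systems plus linkers).

    Atom and bond types are retained (plain framework, not the generic
    carbon-skeleton variant). Acyclic molecules map to :data:`ACYCLIC`.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise LibPrepError(f"unparseable SMILES: {structure!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    smiles = Chem.MolToSmiles(scaffold)
    return smiles if smiles else ACYCLIC


# ---------------------------------------------------------------------------
# File-level preparation
# ---------------------------------------------------------------------------


def read_compounds(path: str | Path) -> Iterator[CompoundRecord]:
    """Read raw compounds from ``.smi``/``.smiles``, ``.csv`` or ``.sdf``.

    SMILES files are whitespace-separated ``smiles id`` lines; CSV files
    need ``compound_id`` and ``smiles`` columns (``activity`` optional);
    SDF records use the molecule title (or ``_Name``) as identifier.
    Structures are passed through as written — canonicalization and
    validation happen in :func:`prepare_library`.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".smi", ".smiles", ".txt"}:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                smiles = parts[0]
                cid = parts[1] if len(parts) > 1 else f"line{lineno}"
                yield CompoundRecord(cid, smiles)
    elif suffix == ".csv":
        df = pd.read_csv(path, dtype={"compound_id": str})
        required = {"compound_id", "smiles"}
        if not required.issubset(df.columns):
            raise LibPrepError(f"{path}: CSV needs columns {sorted(required)}")
        has_activity = "activity" in df.columns
        for row in df.itertuples(index=False):
            activity = getattr(row, "activity", UNLABELED) if has_activity else UNLABELED
            if not isinstance(activity, str) or not activity:
                activity = UNLABELED
            yield CompoundRecord(str(row.compound_id), row.smiles, activity)
    elif suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                yield CompoundRecord(f"sdf_record_{i}", "")  # flagged as parse_error later
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf_record_{i}"
            yield CompoundRecord(cid or f"sdf_record_{i}", Chem.MolToSmiles(mol))
    else:
        raise LibPrepError(f"unsupported input format: {path}")


def prepare_library(
    records: Iterable[CompoundRecord],
    bioactivities: Optional[Iterable[BioactivityRecord]] = None,
) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Standardize, label, filter and annotate a raw compound collection.

    Per compound: canonicalize and strip salts, derive the activity label
    from ``bioactivities`` when given (otherwise keep the incoming label),
    apply :func:`filter_compound` (stereo rule for active candidates
    only), and attach molecular weight and scaffold key.

    Returns the kept records plus a rejection log
    (``compound_id, reason``). Duplicate compound identifiers raise.
    """
    label_by_id: dict[str, str] = {}
    if bioactivities is not None:
        for bio in bioactivities:
            label_by_id[bio.compound_id] = label_activity(bio)

    kept: list[CompoundRecord] = []
    rejected: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        if rec.compound_id in seen:
            raise LibPrepError(f"duplicate compound_id: {rec.compound_id!r}")
        seen.add(rec.compound_id)
        activity = label_by_id.get(rec.compound_id, rec.activity)
        try:
            structure = strip_salts(rec.structure)
        except LibPrepError:
            rejected.append((rec.compound_id, "parse_error"))
            continue
        verdict = filter_compound(
            CompoundRecord(rec.compound_id, structure, activity),
            is_active_candidate=(activity == ACTIVE),
        )
        if not verdict.keep:
            rejected.append((rec.compound_id, verdict.reason or "rejected"))
            continue
        mol = Chem.MolFromSmiles(structure)
        kept.append(
            CompoundRecord(
                compound_id=rec.compound_id,
                structure=structure,
                activity=activity,
                scaffold_key=murcko_scaffold(structure),
                mw=Descriptors.MolWt(mol),
            )
        )
    log = pd.DataFrame(rejected, columns=["compound_id", "reason"])
    return kept, log


def write_library(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write a prepared library as ``compound_id,smiles,activity,scaffold_key,mw``."""
    df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "smiles": r.structure,
                "activity": r.activity,
                "scaffold_key": r.scaffold_key,
                "mw": r.mw,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)


def read_library(path: str | Path) -> list[CompoundRecord]:
    """Read a prepared-library CSV back into records."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    return [
        CompoundRecord(
            compound_id=str(row.compound_id),
            structure=row.smiles,
            activity=getattr(row, "activity", UNLABELED),
            scaffold_key=getattr(row, "scaffold_key", None),
            mw=getattr(row, "mw", None),
        )
        for row in df.itertuples(index=False)
    ]
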