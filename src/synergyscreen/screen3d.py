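"""Shape-channel screening behind a pluggable scorer interface.

The 3D channel ranks library compounds by a two-component similarity
score in [0, 2]: a *shape* component and a pharmacophoric *color*
component, each in [0, 1] — the score contract used by aligning shape
engines. The reference scorer shipped here is rotation/translation
invariant and alignment-free: it compares USR-style distance-distribution
moments (four reference points, three moments each) computed over all
atoms (shape) and over pharmacophore-class subsets (color, in the spirit
of USRCAT). Scores from an external shape engine can be substituted via
:func:`load_external_scores` without touching anything downstream.

Library molecules are represented by conformer ensembles (at most 200
conformers); a compound's score against a query is the best score over
its ensemble. Queries are single low-energy conformations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from rdkit import Chem

from .screen2d import ScoreMatrix

__all__ = [
    "MAX_CONFORMERS",
    "Conformer",
    "ConformerSet",
    "ShapeDescriptor",
    "ComboScore",
    "pharmacophore_classes",
    "assign_pharmacophores",
    "conformers_from_mol",
    "read_conformer_sdf",
    "shape_descriptor",
    "combo_similarity",
    "screen_3d",
    "load_external_scores",
]

#: Cap on ensemble size per library compound.
MAX_CONFORMERS = 200

PHARMACOPHORE_CLASSES = ("donor", "acceptor", "aromatic", "hydrophobe")


@dataclass(frozen=True)
class Conformer:
    """One 3D geometry: coordinates in Å plus pharmacophore atom masks."""

    coords: np.ndarray  # (n_atoms, 3)
    feature_masks: dict  # class name -> boolean mask over atoms

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {coords.shape}")
        if coords.shape[0] < 3:
            raise ValueError("a conformer needs at least 3 atoms")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")


@dataclass
class ConformerSet:
    """Conformer ensemble for one compound (1..200 conformers)."""

    compound_id: str
    conformers: list
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.conformers) <= MAX_CONFORMERS:
            raise ValueError(
                f"{self.compound_id}: ensemble size {len(self.conformers)} "
                f"outside [1, {MAX_CONFORMERS}]"
            )


@dataclass(frozen=True)
class ShapeDescriptor:
    """Rigid-motion-invariant moment descriptor of one conformer."""

    shape_moments: np.ndarray  # (12,)
    feature_moments: dict  # class -> (12,) array
    version: int = 1


@dataclass(frozen=True)
class ComboScore:
    """Two-component similarity: total = shape + color, each in [0, 1]."""

    shape_component: float
    color_component: float

    @property
    def total(self) -> float:
        return self.shape_component + self.color_component


def pharmacophore_classes() -> dict:
    """Load the versioned SMARTS pharmacophore definitions shipped with the package."""
    with resources.files("synergyscreen.data").joinpath("pharmacophores.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    patterns = {
        cls: [Chem.MolFromSmarts(s) for s in smarts_list]
        for cls, smarts_list in cfg["classes"].items()
    }
    return {"version": cfg["version"], "patterns": patterns}


_PHARMACOPHORES: Optional[dict] = None


def _pharmacophores() -> dict:
    global _PHARMACOPHORES
    if _PHARMACOPHORES is None:
        _PHARMACOPHORES = pharmacophore_classes()
    return _PHARMACOPHORES


def assign_pharmacophores(mol: Chem.Mol) -> dict:
    """Boolean atom masks per pharmacophore class for ``mol``."""
    n = mol.GetNumAtoms()
    masks = {}
    for cls, patterns in _pharmacophores()["patterns"].items():
        mask = np.zeros(n, dtype=bool)
        for patt in patterns:
            for match in mol.GetSubstructMatches(patt):
                mask[list(match)] = True
        masks[cls] = mask
    return masks


def conformers_from_mol(mol: Chem.Mol, compound_id: Optional[str] = None) -> ConformerSet:
    """Extract all embedded conformers of an RDKit molecule."""
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D conformers")
    masks = assign_pharmacophores(mol)
    conformers = [
        Conformer(conf.GetPositions(), masks) for conf in mol.GetConformers()
    ]
    cid = compound_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "unnamed")
    return ConformerSet(cid, conformers)


def read_conformer_sdf(path: str | Path) -> list[ConformerSet]:
    """Read a multi-conformer SDF; consecutive records sharing a title form one ensemble."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    sets: list[ConformerSet] = []
    current_mol: Optional[Chem.Mol] = None
    current_id: Optional[str] = None
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: unreadable SDF record {i}")
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf_record_{i}"
        if current_mol is not None and cid == current_id:
            current_mol.AddConformer(mol.GetConformer(), assignId=True)
        else:
            if current_mol is not None:
                sets.append(conformers_from_mol(current_mol, current_id))
            current_mol, current_id = mol, cid
    if current_mol is not None:
        sets.append(conformers_from_mol(current_mol, current_id))
    return sets


def _usr_moments(coords: np.ndarray, subset: Optional[np.ndarray] = None) -> np.ndarray:
    """Twelve distance-distribution moments from four reference points.

    Reference points (classic USR choice): molecular centroid, the atom
    closest to the centroid, the atom farthest from the centroid, and the
    atom farthest from that one. For each, the mean, standard deviation
    and cube-rooted third central moment of its distances to the selected
    atoms. An empty subset yields all zeros (a molecule without e.g.
    donors is legitimately featureless in that class).
    """
    points = coords if subset is None else coords[subset]
    if points.shape[0] == 0:
        return np.zeros(12)
    centroid = coords.mean(axis=0)
    d_centroid = np.linalg.norm(coords - centroid, axis=1)
    ctd = centroid
    cst = coords[int(np.argmin(d_centroid))]
    fct = coords[int(np.argmax(d_centroid))]
    d_fct = np.linalg.norm(coords - fct, axis=1)
    ftf = coords[int(np.argmax(d_fct))]
    out = np.empty(12)
    for k, ref in enumerate((ctd, cst, fct, ftf)):
        dists = np.linalg.norm(points - ref, axis=1)
        mean = dists.mean()
        var = ((dists - mean) ** 2).mean()
        third = ((dists - mean) ** 3).mean()
        out[3 * k : 3 * k + 3] = (mean, np.sqrt(var), np.cbrt(third))
    return out


def shape_descriptor(conformer: Conformer) -> ShapeDescriptor:
    """Moment descriptor of one conformer; invariant under rigid motion.

    Reflection (improper rotation) is *not* a symmetry: the skew moments
    may distinguish a chiral conformer from its mirror image.
    """
    shape = _usr_moments(conformer.coords)
    features = {
        cls: _usr_moments(conformer.coords, np.flatnonzero(mask))
        for cls, mask in conformer.feature_masks.items()
    }
    version = _pharmacophores()["version"]
    return ShapeDescriptor(shape, features, version=version)


def combo_similarity(a: ShapeDescriptor, b: ShapeDescriptor) -> ComboScore:
    """Two-component similarity between moment descriptors.

    shape = 1 / (1 + mean |Δ shape_moments|); color is the analogous
    expression over the concatenated pharmacophore-class moments.
    Symmetric; self-similarity is (1, 1) with total 2.
    """
    if a.version != b.version:
        raise ValueError(
            f"descriptor version mismatch: {a.version} vs {b.version}"
        )
    if set(a.feature_moments) != set(b.feature_moments):
        raise ValueError("descriptors carry different pharmacophore classes")
    shape = 1.0 / (1.0 + float(np.abs(a.shape_moments - b.shape_moments).mean()))
    classes = sorted(a.feature_moments)
    fa = np.concatenate([a.feature_moments[c] for c in classes])
    fb = np.concatenate([b.feature_moments[c] for c in classes])
    color = 1.0 / (1.0 + float(np.abs(fa - fb).mean()))
    return ComboScore(shape, color)


def screen_3d(query: ConformerSet, library: Sequence[ConformerSet]) -> ScoreMatrix:
    """Rank a library of conformer ensembles against a single-conformer query.

    A compound's score is the maximum combo total over its ensemble
    (best-overlay convention).
    """
    if len(query.conformers) != 1:
        raise ValueError(
            f"query {query.compound_id} must have exactly one conformer, "
            f"got {len(query.conformers)}"
        )
    qdesc = shape_descriptor(query.conformers[0])
    scores = np.empty((1, len(library)), dtype=float)
    lids = []
    for j, cset in enumerate(library):
        lids.append(cset.compound_id)
        scores[0, j] = max(
            combo_similarity(qdesc, shape_descriptor(conf)).total
            for conf in cset.conformers
        )
    return ScoreMatrix((query.compound_id,), tuple(lids), scores, method_tag="shape3d")


def load_external_scores(path: str | Path, method_tag: str = "shape3d") -> ScoreMatrix:
    """Validate a score CSV produced by an external engine into a ScoreMatrix.

    Expects the same dialect as :meth:`ScoreMatrix.to_csv` (first column
    ``compound_id``, one column per query). Non-finite values and
    duplicate identifiers are reported with their row numbers.
    """
    import pandas as pd

    df = pd.read_csv(path, dtype={"compound_id": str})
    if "compound_id" not in df.columns:
        raise ValueError(f"{path}: missing compound_id column")
    dupes = df[df["compound_id"].duplicated(keep=False)]
    if len(dupes):
        raise ValueError(
            f"{path}: duplicate compound ids at rows {list(dupes.index + 2)}"
        )
    qcols = [c for c in df.columns if c != "compound_id"]
    values = df[qcols].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values).all(axis=1))
    if bad.size:
        raise ValueError(
            f"{path}: non-finite scores at rows {list((bad + 2).tolist())}"
        )
    return ScoreMatrix(
        tuple(qcols), tuple(df["compound_id"]), values.T, method_tag=method_tag
    )
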