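"""2D fingerprint similarity screening.

Morgan circular fingerprints (radius 2, 1024 bits) with Tanimoto ranking
against one or more query molecules. The bit patterns themselves are an
implementation detail of the underlying toolkit — only similarity values
and the resulting rankings are part of the interchange contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .libprep import CompoundRecord, LibPrepError

__all__ = ["Fingerprint", "ScoreMatrix", "morgan_fingerprint", "tanimoto", "screen_2d"]

#: Valid score ranges per screening method tag.
SCORE_RANGES = {"fp2d": (0.0, 1.0), "shape3d": (0.0, 2.0)}


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary Morgan fingerprint."""

    bits: "DataStructs.ExplicitBitVect"
    radius: int = 2

    @property
    def nbits(self) -> int:
        return self.bits.GetNumBits()

    @property
    def popcount(self) -> int:
        return self.bits.GetNumOnBits()


@dataclass
class ScoreMatrix:
    """Queries x library similarity scores for one screening method.

    Rows are queries, columns are library compounds. ``method_tag``
    declares the score scale: ``fp2d`` scores live in [0, 1], ``shape3d``
    scores in [0, 2]. Query identifiers must never appear among the
    library identifiers (queries are removed from the screening deck
    before any screen — the leakage guard enforces this).
    """

    query_ids: tuple[str, ...]
    library_ids: tuple[str, ...]
    scores: np.ndarray
    method_tag: str

    def __post_init__(self) -> None:
        self.query_ids = tuple(str(q) for q in self.query_ids)
        self.library_ids = tuple(str(c) for c in self.library_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.method_tag not in SCORE_RANGES:
            raise ValueError(f"unknown method_tag: {self.method_tag!r}")
        if self.scores.shape != (len(self.query_ids), len(self.library_ids)):
            raise ValueError(
                f"score shape {self.scores.shape} does not match "
                f"{len(self.query_ids)} queries x {len(self.library_ids)} library"
            )
        if len(set(self.query_ids)) != len(self.query_ids):
            raise ValueError("duplicate query ids")
        if len(set(self.library_ids)) != len(self.library_ids):
            raise ValueError("duplicate library ids")
        leaked = set(self.query_ids) & set(self.library_ids)
        if leaked:
            raise ValueError(f"query ids present in library (leakage): {sorted(leaked)}")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite scores")
        lo, hi = SCORE_RANGES[self.method_tag]
        if self.scores.size and (self.scores.min() < lo or self.scores.max() > hi):
            raise ValueError(
                f"{self.method_tag} scores outside [{lo}, {hi}]: "
                f"range [{self.scores.min()}, {self.scores.max()}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def subset_queries(self, n: int) -> "ScoreMatrix":
        """First ``n`` query rows (used for nested query-set screening)."""
        if not 1 <= n <= len(self.query_ids):
            raise ValueError(f"cannot take {n} of {len(self.query_ids)} queries")
        return ScoreMatrix(
            self.query_ids[:n], self.library_ids, self.scores[:n], self.method_tag
        )

    def to_csv(self, path: str | Path) -> None:
        """Serialize as CSV: first column ``compound_id``, one column per query."""
        df = pd.DataFrame(self.scores.T, columns=list(self.query_ids))
        df.insert(0, "compound_id", list(self.library_ids))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, method_tag: str) -> "ScoreMatrix":
        df = pd.read_csv(path, dtype={"compound_id": str})
        if "compound_id" not in df.columns:
            raise ValueError(f"{path}: missing compound_id column")
        library_ids = tuple(df["compound_id"])
        query_ids = tuple(c for c in df.columns if c != "compound_id")
        scores = df[list(query_ids)].to_numpy(dtype=float).T
        return cls(query_ids, library_ids, scores, method_tag)


_GENERATOR_CACHE: dict[tuple[int, int], object] = {}


def _generator(radius: int, nbits: int):
    key = (radius, nbits)
    if key not in _GENERATOR_CACHE:
        _GENERATOR_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits
        )
    return _GENERATOR_CACHE[key]


def morgan_fingerprint(structure: str, radius: int = 2, nbits: int = 1024) -> Fingerprint:
    """Hashed circular-substructure fingerprint of a molecule.

    Deterministic: identical canonical structures give bit-identical
    fingerprints regardless of the SMILES spelling used.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise LibPrepError(f"unparseable SMILES: {structure!r}")
    return Fingerprint(_generator(radius, nbits).GetFingerprint(mol), radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient c / (|a| + |b| - c) in [0, 1].

    Two empty fingerprints compare as 0.0 by convention.
    """
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint length mismatch: {a.nbits} vs {b.nbits}")
    if a.popcount == 0 and b.popcount == 0:
        return 0.0
    return DataStructs.TanimotoSimilarity(a.bits, b.bits)


def screen_2d(
    queries: Sequence[CompoundRecord],
    library: Sequence[CompoundRecord],
    radius: int = 2,
    nbits: int = 1024,
) -> ScoreMatrix:
    """Rank a library by Morgan/Tanimoto similarity to each query.

    ``scores[i, j]`` is the Tanimoto similarity between query ``i`` and
    library compound ``j``. Queries must be disjoint (by identifier) from
    the library.
    """
    if not queries:
        raise ValueError("at least one query is required")
    qids = [q.compound_id for q in queries]
    lids = [c.compound_id for c in library]
    qfps = [morgan_fingerprint(q.structure, radius, nbits) for q in queries]
    lfps = [morgan_fingerprint(c.structure, radius, nbits) for c in library]
    scores = np.empty((len(qfps), len(lfps)), dtype=float)
    for i, qfp in enumerate(qfps):
        scores[i, :] = DataStructs.BulkTanimotoSimilarity(
            qfp.bits, [fp.bits for fp in lfps]
        )
    return ScoreMatrix(tuple(qids), tuple(lids), scores, method_tag="fp2d")
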