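"""Hit-list combination: MAX fusion, parallel selection, integration.

Three strategies for squeezing more out of similarity screens:

1. *MAX fusion* merges the per-query hit lists of a multi-query screen by
   giving each library compound the best score it obtained with any
   query, then re-ranking.
2. *Parallel selection* merges the hit lists of two different methods
   (typically a 2D fingerprint screen and a 3D shape screen) by
   alternately transferring the next not-yet-included compounds from each
   list, at a chosen ratio (1:1 balanced, 9:1 weighted, ...). Duplicates
   are skipped and replaced by the next unique entry from the same list.
3. The *integrated* strategy applies balanced parallel selection to the
   MAX-fused multi-query lists of the two methods.

Combined lists are rank-only: scores from different methods live on
incommensurable scales, so downstream evaluation of a combined list uses
positions. Running the selection to full library size yields a complete
permutation, which is what rank-based AUC needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .screen2d import ScoreMatrix

__all__ = [
    "RankedList",
    "SelectionRatio",
    "rank_list",
    "max_fuse",
    "parallel_select",
    "integrated",
    "ratio_sweep",
]

TIE_BREAK_RULE = "score desc, compound_id asc"


@dataclass
class RankedList:
    """A total ordering of a compound universe.

    Ranks are implicit: position ``i`` holds rank ``i + 1``. ``scores``,
    when present, are non-increasing along the list. ``provenance``
    records which strategy produced the ordering.
    """

    ids: tuple[str, ...]
    scores: Optional[tuple[float, ...]] = None
    provenance: str = "unknown"
    tie_break_rule: str = TIE_BREAK_RULE

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate compound ids in ranked list")
        if self.scores is not None:
            self.scores = tuple(float(s) for s in self.scores)
            if len(self.scores) != len(self.ids):
                raise ValueError("scores/ids length mismatch")
            if any(
                self.scores[i] < self.scores[i + 1]
                for i in range(len(self.scores) - 1)
            ):
                raise ValueError("scores must be non-increasing with rank")

    def __len__(self) -> int:
        return len(self.ids)

    def rank_of(self, compound_id: str) -> int:
        """1-based rank of a compound."""
        return self.ids.index(compound_id) + 1

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"rank": np.arange(1, len(self.ids) + 1), "compound_id": self.ids})
        if self.scores is not None:
            df["score"] = self.scores
        df["provenance"] = self.provenance
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RankedList":
        df = pd.read_csv(path, dtype={"compound_id": str})
        df = df.sort_values("rank") if "rank" in df.columns else df
        scores = tuple(df["score"]) if "score" in df.columns else None
        provenance = str(df["provenance"].iloc[0]) if "provenance" in df.columns else "unknown"
        return cls(tuple(df["compound_id"]), scores, provenance)


@dataclass(frozen=True)
class SelectionRatio:
    """Block sizes per interleaving round: ``from_a`` entries from list A,
    then ``from_b`` from list B."""

    from_a: int
    from_b: int

    def __post_init__(self) -> None:
        if self.from_a < 0 or self.from_b < 0:
            raise ValueError("ratio components must be non-negative")
        if self.from_a + self.from_b < 1:
            raise ValueError("ratio 0:0 is not a selection")

    def __str__(self) -> str:
        return f"{self.from_a}:{self.from_b}"

    @classmethod
    def parse(cls, text: str) -> "SelectionRatio":
        parts = text.split(":")
        if len(parts) != 2:
            raise ValueError(f"invalid ratio {text!r}, expected 'A:B'")
        try:
            return cls(int(parts[0]), int(parts[1]))
        except ValueError as exc:
            raise ValueError(f"invalid ratio {text!r}: {exc}") from None


def rank_list(
    scores: Mapping[str, float], provenance: str = "unknown"
) -> RankedList:
    """Order compounds by descending score; ties broken by ascending id."""
    items = list(scores.items())
    if len({cid for cid, _ in items}) != len(items):
        raise ValueError("duplicate compound ids")
    if not all(np.isfinite(s) for _, s in items):
        raise ValueError("non-finite scores")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return RankedList(
        tuple(cid for cid, _ in items),
        tuple(s for _, s in items),
        provenance=provenance,
    )


def max_fuse(matrix: ScoreMatrix) -> RankedList:
    """MAX-fuse a multi-query score matrix into one hit list.

    Each library compound receives the best score it obtained with any of
    the queries (column maximum), then compounds are ranked. With a
    single query this reduces to the single-query ranking. Invariant to
    the order of the query rows.
    """
    if matrix.shape[0] < 1 or matrix.shape[1] < 1:
        raise ValueError("empty score matrix")
    fused = matrix.scores.max(axis=0)
    provenance = {"fp2d": "fused2d", "shape3d": "fused3d"}.get(
        matrix.method_tag, f"fused_{matrix.method_tag}"
    )
    return rank_list(dict(zip(matrix.library_ids, fused)), provenance=provenance)


def parallel_select(
    list_a: RankedList,
    list_b: RankedList,
    ratio: SelectionRatio | tuple[int, int] = (1, 1),
    size: Optional[int] = None,
) -> RankedList:
    """Fill a combined hit list by alternating block transfers from two lists.

    Per round, the next ``ratio.from_a`` not-yet-included compounds of
    ``list_a`` are transferred, then the next ``ratio.from_b`` of
    ``list_b``; compounds already present are skipped and replaced by the
    next unique entry from the same source. Rounds repeat until ``size``
    slots are filled (default: the full universe). When one source is
    exhausted the remaining slots are filled from the other. The output
    is rank-only: scores from different methods are not comparable.
    """
    if not isinstance(ratio, SelectionRatio):
        ratio = SelectionRatio(*ratio)
    universe = set(list_a.ids)
    if universe != set(list_b.ids):
        diff = sorted(universe.symmetric_difference(set(list_b.ids)))
        raise ValueError(f"lists rank different universes; difference: {diff[:10]}")
    n = len(universe)
    if size is None:
        size = n
    if not 1 <= size <= n:
        raise ValueError(f"size {size} outside [1, {n}]")

    chosen: list[str] = []
    seen: set[str] = set()
    pointers = [0, 0]
    sources = [list_a.ids, list_b.ids]
    blocks = [ratio.from_a, ratio.from_b]

    while len(chosen) < size:
        for s in (0, 1):
            taken = 0
            src = sources[s]
            while taken < blocks[s] and len(chosen) < size and pointers[s] < n:
                cid = src[pointers[s]]
                pointers[s] += 1
                if cid in seen:
                    continue  # duplicate: replaced by next unique entry from same list
                chosen.append(cid)
                seen.add(cid)
                taken += 1
            if len(chosen) >= size:
                break

    return RankedList(tuple(chosen), scores=None, provenance="parallel")


def integrated(m2d: ScoreMatrix, m3d: ScoreMatrix, size: Optional[int] = None) -> RankedList:
    """Balanced parallel selection of the MAX-fused 2D and 3D hit lists.

    With single-query matrices this is exactly balanced parallel
    selection of the two baseline lists.
    """
    if set(m2d.library_ids) != set(m3d.library_ids):
        diff = sorted(set(m2d.library_ids) ^ set(m3d.library_ids))
        raise ValueError(f"library mismatch between channels; difference: {diff[:10]}")
    if m2d.shape[0] != m3d.shape[0]:
        raise ValueError(
            f"query count mismatch: {m2d.shape[0]} (2D) vs {m3d.shape[0]} (3D)"
        )
    fused = parallel_select(max_fuse(m2d), max_fuse(m3d), SelectionRatio(1, 1), size)
    fused.provenance = "integrated"
    return fused


def ratio_sweep(
    list_a: RankedList,
    list_b: RankedList,
    ratios: Sequence[SelectionRatio | tuple[int, int]],
    size: Optional[int] = None,
) -> dict:
    """Parallel selection at each ratio; endpoints 1:0 / 0:1 reproduce the
    source lists' prefixes."""
    out = {}
    for ratio in ratios:
        if not isinstance(ratio, SelectionRatio):
            ratio = SelectionRatio(*ratio)
        out[ratio] = parallel_select(list_a, list_b, ratio, size)
    return out
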