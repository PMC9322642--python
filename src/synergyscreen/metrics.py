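"""Evaluation of screening rankings.

- ROC AUC (rank-based / Mann–Whitney form; exact pair counting),
- enrichment factors EFk% at percentage cutoffs,
- scaffold recovery rates SRRk% (fraction of distinct active scaffolds
  represented among the actives in the top k%),
- the two-list scaffold-overlap decomposition (scaffolds found
  exclusively by method A, exclusively by B, by both, by at least one),
- the paired Wilcoxon signed-rank test for method comparison.

Compounds present in a ranking but absent from the label map (e.g.
queries, which are removed from the screening deck) are ignored: metrics
are computed over the labeled universe in its induced order. The top-k%
cutoff is ``ceil(n * k / 100)`` with a minimum of one compound, so small
libraries always have a non-empty top list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .fusion import RankedList

__all__ = [
    "MetricsReport",
    "OverlapReport",
    "topk_size",
    "auc",
    "enrichment_factor",
    "scaffold_recovery",
    "scaffold_overlap",
    "wilcoxon_signed_rank",
    "evaluate",
]


@dataclass(frozen=True)
class OverlapReport:
    """Decomposition of the active scaffolds recovered by two rankings.

    All four numbers are fractions of the total count of distinct active
    scaffolds; exclusive_a + exclusive_b + both == at_least_one.
    """

    exclusive_a: float
    exclusive_b: float
    both: float
    at_least_one: float


@dataclass
class MetricsReport:
    """AUC, EF and SRR for one ranking, with provenance of the screen."""

    auc: float
    ef: dict  # k% -> EF value
    srr: dict  # k% -> SRR value
    n_actives: int
    n_library: int
    provenance: dict = field(default_factory=dict)  # seed, query-set size, strategy...


def topk_size(n_library: int, k_percent: float) -> int:
    """Number of compounds in the top k% (ceiling, at least 1)."""
    if k_percent <= 0 or k_percent > 100:
        raise ValueError(f"k_percent must be in (0, 100], got {k_percent}")
    if n_library < 1:
        raise ValueError("empty library")
    return max(1, math.ceil(n_library * k_percent / 100.0))


def _labeled_flags(ranking: RankedList, labels: Mapping[str, str]) -> np.ndarray:
    """Active/decoy flags of the labeled compounds in rank order.

    Every labeled compound must appear in the ranking; unlabeled entries
    of the ranking are dropped.
    """
    missing = set(labels) - set(ranking.ids)
    if missing:
        raise ValueError(
            f"ranking does not cover {len(missing)} labeled compounds, "
            f"e.g. {sorted(missing)[:5]}"
        )
    flags = [labels[cid] == "active" for cid in ranking.ids if cid in labels]
    return np.asarray(flags, dtype=bool)


def auc(ranking: RankedList, labels: Mapping[str, str]) -> float:
    """Probability that a random active outranks a random decoy.

    Computed by exact integer pair counting over the total order (a
    ranked list has no ties), which equals the trapezoidal area under
    the ROC curve.
    """
    is_active = _labeled_flags(ranking, labels)
    n_a = int(is_active.sum())
    n_d = int(len(is_active) - n_a)
    if n_a == 0 or n_d == 0:
        raise ValueError("need at least one active and one decoy")
    # concordant pairs: decoys ranked after each active
    decoys_before = np.cumsum(~is_active)
    concordant = int((n_d - decoys_before[is_active]).sum())
    return concordant / (n_a * n_d)


def enrichment_factor(
    ranking: RankedList, labels: Mapping[str, str], k_percent: float
) -> float:
    """EFk% = (active rate in the top k%) / (active rate in the library)."""
    is_active = _labeled_flags(ranking, labels)
    n = len(is_active)
    n_a = int(is_active.sum())
    if n_a == 0 or n_a == n:
        raise ValueError("need at least one active and one decoy")
    n_k = topk_size(n, k_percent)
    hits = int(is_active[:n_k].sum())
    return (hits / n_k) / (n_a / n)


def _recovered_scaffolds(
    ranking: RankedList,
    labels: Mapping[str, str],
    scaffold_map: Mapping[str, str],
    k_percent: float,
) -> tuple[set, set]:
    """(scaffolds of actives in the top k%, scaffolds of all library actives)."""
    labeled = [cid for cid in ranking.ids if cid in labels]
    n_k = topk_size(len(labeled), k_percent)
    all_scaffolds = set()
    for cid in labeled:
        if labels[cid] == "active":
            if cid not in scaffold_map:
                raise ValueError(f"active {cid!r} has no scaffold key")
            all_scaffolds.add(scaffold_map[cid])
    if not all_scaffolds:
        raise ValueError("no active scaffolds in the evaluated library")
    top = {
        scaffold_map[cid]
        for cid in labeled[:n_k]
        if labels[cid] == "active"
    }
    return top, all_scaffolds


def scaffold_recovery(
    ranking: RankedList,
    labels: Mapping[str, str],
    scaffold_map: Mapping[str, str],
    k_percent: float,
) -> float:
    """SRRk%: fraction of distinct active scaffolds found among the
    actives in the top k% of the ranking."""
    top, total = _recovered_scaffolds(ranking, labels, scaffold_map, k_percent)
    return len(top) / len(total)


def scaffold_overlap(
    rank_a: RankedList,
    rank_b: RankedList,
    labels: Mapping[str, str],
    scaffold_map: Mapping[str, str],
    k_percent: float,
) -> OverlapReport:
    """Set decomposition of the active scaffolds recovered by two rankings."""
    top_a, total = _recovered_scaffolds(rank_a, labels, scaffold_map, k_percent)
    top_b, total_b = _recovered_scaffolds(rank_b, labels, scaffold_map, k_percent)
    if total != total_b:
        raise ValueError("rankings evaluate different active-scaffold universes")
    t = len(total)
    return OverlapReport(
        exclusive_a=len(top_a - top_b) / t,
        exclusive_b=len(top_b - top_a) / t,
        both=len(top_a & top_b) / t,
        at_least_one=len(top_a | top_b) / t,
    )


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


def _exact_signed_rank_p(ranks2: np.ndarray, w2_obs: int) -> float:
    """Two-sided exact p via the signed-rank sum distribution.

    ``ranks2`` are midranks doubled (integers even with ties); the null
    distribution of the doubled positive-rank sum is built by dynamic
    programming over all 2^n sign assignments, conditional on the
    observed |difference| ranks. The distribution is symmetric, so the
    two-sided p is twice the lower tail of min(W+, W-).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n = len(ranks2)
    w2_min = min(w2_obs, total - w2_obs)
    p = 2.0 * counts[: w2_min + 1].sum() / (2.0 ** n)
    return min(p, 1.0)


def _midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks of ``values`` (1-based, ties share the mean rank)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def wilcoxon_signed_rank(
    paired_values_a: Sequence[float],
    paired_values_b: Sequence[float],
    exact_threshold: int = 25,
) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon convention). For at most
    ``exact_threshold`` non-zero pairs the p-value is exact (full
    enumeration of sign assignments via dynamic programming, valid with
    tied |differences|); beyond that, the normal approximation with tie
    correction is used. Returns ``(statistic, p_value)`` where the
    statistic is min(W+, W-).
    """
    a = np.asarray(paired_values_a, dtype=float)
    b = np.asarray(paired_values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    if len(a) < 6:
        raise ValueError("need at least 6 pairs")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero (degenerate comparison)")
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    if n <= exact_threshold:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        w2_obs = int(round(2.0 * w_plus))
        p = _exact_signed_rank_p(ranks2, w2_obs)
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        from scipy.stats import norm

        z = (statistic - mean) / math.sqrt(var)
        p = min(1.0, 2.0 * norm.cdf(z))
    return statistic, p


def evaluate(
    ranking: RankedList,
    labels: Mapping[str, str],
    scaffold_map: Optional[Mapping[str, str]] = None,
    k_list: Sequence[float] = (1, 3, 5, 10),
    provenance: Optional[dict] = None,
) -> MetricsReport:
    """AUC plus EF and SRR at each cutoff in ``k_list`` for one ranking."""
    is_active = _labeled_flags(ranking, labels)
    ef = {k: enrichment_factor(ranking, labels, k) for k in k_list}
    srr = (
        {k: scaffold_recovery(ranking, labels, scaffold_map, k) for k in k_list}
        if scaffold_map is not None
        else {}
    )
    return MetricsReport(
        auc=auc(ranking, labels),
        ef=ef,
        srr=srr,
        n_actives=int(is_active.sum()),
        n_library=int(len(is_active)),
        provenance=provenance or {},
    )
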