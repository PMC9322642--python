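"""Synthetic screening benchmark with planted scaffold families.

Real screening decks for method comparison are built from confirmed
actives diluted into tens of thousands of presumed-inactive purchasable
compounds. This module emulates the statistical structure of such a deck
without any external data, at two levels:

**Latent library.** Every compound carries latent feature vectors in two
similarity channels — channel A standing in for a 2D fingerprint space
and channel B (two sub-vectors, mirroring the shape + color
decomposition of a combo score in [0, 2]) for a 3D shape space. Actives
belong to scaffold families drawn tightly around family centroids, but a
family is *recognizable* (clustered) only in a subset of the channels:
a fraction ``channel_overlap`` of families in both, the remainder split
between A-only and B-only. This planted partial orthogonality is what
makes combining the channels pay off, mirroring the low (~5%) overlap
between the active scaffolds retrieved early by 2D and 3D methods on
real decks. Family centroids share a weak common direction per channel
(``activity_bias``), so actives of other recognizable families score
slightly above background — which is what lifts AUC above chance even
for families a query does not belong to.

**SMILES fixture.** A small, fully synthetic chemistry deck: active
families enumerated as scaffold-plus-R-group combinations from shipped
templates (one shared Murcko scaffold per family, all structures
parseable and preparation-filter-passing) and decoys from a disjoint
template set. This drives the real 2D screening stack end to end.

The experiment runner reproduces the multi-query screening protocol:
nested query sets of sizes 1..5 drawn per repeat (the smaller sets are
always prefixes of the five-query draw), 30 repeats with seeds 0..29,
queries removed from the evaluated deck, per-strategy AUC/EF/SRR, and
mean/stdev summaries with paired Wilcoxon comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import fusion, metrics
from .fusion import RankedList, SelectionRatio
from .screen2d import ScoreMatrix

__all__ = [
    "DEFAULT_DATASET_SEED",
    "SyntheticLibraryConfig",
    "LatentLibrary",
    "QueryPlan",
    "generate_latent_library",
    "generate_smiles_fixture",
    "select_query_pool",
    "make_query_plan",
    "run_experiment",
    "scaffold_overlap_table",
    "summarize",
    "compare_strategies",
]

#: Default seed for dataset-level sampling (query-pool selection etc.).
DEFAULT_DATASET_SEED = 2506

STRATEGIES = ("2d", "3d", "2d_multi", "3d_multi", "parallel", "integrated")


@dataclass(frozen=True)
class SyntheticLibraryConfig:
    """Study conditions for the latent benchmark library.

    ``channel_overlap`` is the fraction of scaffold families recognizable
    in both similarity channels; the remainder is split equally between
    A-only (2D-only) and B-only (3D-only) families. ``family_tightness``
    and ``noise_sd`` are per-coordinate dispersions of family members
    around their centroid; ``activity_bias`` is the weight of the shared
    actives direction in each channel's centroids.
    """

    n_active: int = 200
    n_decoy: int = 5000
    n_families: int = 20
    channel_overlap: float = 0.2
    latent_dim: int = 32
    family_tightness: float = 0.05
    noise_sd: float = 0.02
    seed: int = DEFAULT_DATASET_SEED
    activity_bias: float = 0.3
    contamination: float = 0.0  # fraction of decoys that are latent actives

    def __post_init__(self) -> None:
        if not 1 <= self.n_families <= self.n_active:
            raise ValueError("need n_active >= n_families >= 1")
        if not 0.0 <= self.channel_overlap <= 1.0:
            raise ValueError("channel_overlap must be in [0, 1]")
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination must be in [0, 1]")
        if self.latent_dim < 2 or self.n_decoy < 1:
            raise ValueError("invalid latent_dim or n_decoy")


@dataclass
class LatentLibrary:
    """A generated screening deck plus its two channel scorers.

    ``scorer_a(query_ids, library_ids)`` returns similarities in [0, 1]
    (fingerprint-channel contract); ``scorer_b`` returns two-component
    scores in [0, 2] (shape-channel contract). ``family_channels`` maps
    family index -> subset of {"a", "b"} where the family clusters.
    """

    config: SyntheticLibraryConfig
    compound_ids: tuple[str, ...]
    labels: dict
    scaffold_map: dict
    family_of: dict
    family_channels: dict
    scorer_a: Callable[[Sequence[str], Sequence[str]], np.ndarray]
    scorer_b: Callable[[Sequence[str], Sequence[str]], np.ndarray]

    @property
    def actives(self) -> list[str]:
        return [c for c in self.compound_ids if self.labels[c] == "active"]

    def score_matrix(
        self, channel: str, query_ids: Sequence[str], library_ids: Sequence[str]
    ) -> ScoreMatrix:
        """ScoreMatrix for one channel; enforces the leakage guard."""
        if channel in ("a", "2d"):
            scores, tag = self.scorer_a(query_ids, library_ids), "fp2d"
        elif channel in ("b", "3d"):
            scores, tag = self.scorer_b(query_ids, library_ids), "shape3d"
        else:
            raise ValueError(f"unknown channel {channel!r}")
        return ScoreMatrix(tuple(query_ids), tuple(library_ids), scores, tag)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def generate_latent_library(config: SyntheticLibraryConfig) -> LatentLibrary:
    """Draw a deck of actives-with-families and background decoys.

    Deterministic for a given config (one RNG seeded by ``config.seed``
    drives every draw). Family channel assignment: the first
    ``round(channel_overlap * n_families)`` families cluster in both
    channels; the remainder alternates A-only / B-only.
    """
    rng = np.random.default_rng(config.seed)
    d = config.latent_dim

    # shared actives direction per channel (a; b split into shape/color halves)
    u_a = _unit(rng.standard_normal(d))
    u_bs = _unit(rng.standard_normal(d))
    u_bc = _unit(rng.standard_normal(d))

    n_both = int(round(config.channel_overlap * config.n_families))
    rest = config.n_families - n_both
    family_channels: dict[int, frozenset] = {}
    for f in range(config.n_families):
        if f < n_both:
            chans = frozenset({"a", "b"})
        elif (f - n_both) % 2 == 0:
            chans = frozenset({"a"})
        else:
            chans = frozenset({"b"})
        family_channels[f] = chans

    def centroid(u: np.ndarray) -> np.ndarray:
        g = _unit(rng.standard_normal(d))
        return _unit(config.activity_bias * u + g)

    cent_a = np.stack([centroid(u_a) for _ in range(config.n_families)])
    cent_bs = np.stack([centroid(u_bs) for _ in range(config.n_families)])
    cent_bc = np.stack([centroid(u_bc) for _ in range(config.n_families)])

    def member(center: np.ndarray) -> np.ndarray:
        wobble = config.family_tightness * rng.standard_normal(d)
        noise = config.noise_sd * rng.standard_normal(d)
        return _unit(center + wobble + noise)

    def background() -> np.ndarray:
        return _unit(rng.standard_normal(d))

    ids: list[str] = []
    labels: dict[str, str] = {}
    scaffold_map: dict[str, str] = {}
    family_of: dict[str, int] = {}
    vec_a = np.empty((config.n_active + config.n_decoy, d))
    vec_bs = np.empty_like(vec_a)
    vec_bc = np.empty_like(vec_a)

    families = [f % config.n_families for f in range(config.n_active)]
    for i, f in enumerate(families):
        cid = f"ACT{i:05d}"
        ids.append(cid)
        labels[cid] = "active"
        scaffold_map[cid] = f"FAM{f:03d}"
        family_of[cid] = f
        chans = family_channels[f]
        # In a channel where the family does not cluster, the active still
        # carries the weak shared actives direction (every molecular
        # representation sees actives as mildly self-similar); only the
        # family-level clustering is channel-specific.
        vec_a[i] = member(cent_a[f]) if "a" in chans else centroid(u_a)
        vec_bs[i] = member(cent_bs[f]) if "b" in chans else centroid(u_bs)
        vec_bc[i] = member(cent_bc[f]) if "b" in chans else centroid(u_bc)

    n_contaminated = int(round(config.contamination * config.n_decoy))
    for j in range(config.n_decoy):
        i = config.n_active + j
        cid = f"DEC{j:05d}"
        ids.append(cid)
        labels[cid] = "decoy"
        if j < n_contaminated:
            # a presumed inactive that is in fact a latent family member
            f = int(rng.integers(config.n_families))
            chans = family_channels[f]
            vec_a[i] = member(cent_a[f]) if "a" in chans else centroid(u_a)
            vec_bs[i] = member(cent_bs[f]) if "b" in chans else centroid(u_bs)
            vec_bc[i] = member(cent_bc[f]) if "b" in chans else centroid(u_bc)
        else:
            vec_a[i] = background()
            vec_bs[i] = background()
            vec_bc[i] = background()

    index = {cid: i for i, cid in enumerate(ids)}

    def rows(id_list: Sequence[str]) -> np.ndarray:
        return np.asarray([index[c] for c in id_list], dtype=int)

    def scorer_a(query_ids: Sequence[str], library_ids: Sequence[str]) -> np.ndarray:
        q, l = rows(query_ids), rows(library_ids)
        cos = vec_a[q] @ vec_a[l].T
        return np.clip((1.0 + cos) / 2.0, 0.0, 1.0)

    def scorer_b(query_ids: Sequence[str], library_ids: Sequence[str]) -> np.ndarray:
        q, l = rows(query_ids), rows(library_ids)
        shape = np.clip((1.0 + vec_bs[q] @ vec_bs[l].T) / 2.0, 0.0, 1.0)
        color = np.clip((1.0 + vec_bc[q] @ vec_bc[l].T) / 2.0, 0.0, 1.0)
        return shape + color

    return LatentLibrary(
        config=config,
        compound_ids=tuple(ids),
        labels=labels,
        scaffold_map=scaffold_map,
        family_of=family_of,
        family_channels=family_channels,
        scorer_a=scorer_a,
        scorer_b=scorer_b,
    )


# ---------------------------------------------------------------------------
# SMILES fixture
# ---------------------------------------------------------------------------

#: Active-family scaffold templates ({R} is the substitution point). All are
#: synthetic constructions chosen so that every R-group combination parses,
#: passes the preparation filters (MW >= 250 Da, allowed elements, no
#: stereocenters) and shares a single Murcko scaffold per template.
FAMILY_TEMPLATES = (
    "O=C(Nc1ccc({R})cc1)c1ccc2ccccc2c1",
    "O=C(N1CCN(c2ccccn2)CC1)c1ccc({R})cc1",
    "O=S(=O)(c1ccc({R})cc1)N1CCc2ccccc2C1",
    "O=C(Nc1nc2ccccc2s1)c1ccc({R})cc1",
    "O=C(N1CCOCC1)c1ccc(-c2ccccc2{R})cc1",
    "O=C(Cc1ccccc1)Nc1ccc2oc(-c3ccc({R})cc3)nc2c1",
)

#: Decoy scaffold templates, disjoint from the family scaffolds.
DECOY_TEMPLATES = (
    "O=C(N1CCN(C)CC1)c1cc2ccccc2nc1{R}",
    "O=C(c1ccc2[nH]ccc2c1)N1CCC(CC1)c1ccc({R})cc1",
    "O=S(=O)(N1CCOCC1)c1ccc(-c2nc3ccccc3o2)cc1{R}",
    "O=C(Nc1ccc({R})cn1)c1ccc2c(c1)OCO2",
    "Cc1ccc(-c2cc(C(=O)NCc3cccnc3)on2)cc1{R}",
    "O=C(NCCc1c[nH]c2ccccc12)c1ccc({R})nc1",
    "O=c1[nH]c2ccccc2n1-c1ccc(CN2CCCCC2)cc1{R}",
    "O=C(N1CCCCC1)c1ccc2ncccc2c1{R}",
    "O=S(=O)(Nc1ccc2ccccc2c1)c1cccc({R})c1",
    "O=C(COc1ccc2ccccc2c1)N1CCN(c2ccc({R})cc2)CC1",
)

#: Acyclic substituents (ring substituents would change the Murcko scaffold).
R_GROUPS = (
    "C", "CC", "CCC", "OC", "OCC", "N(C)C", "CC(C)C", "C(F)(F)F",
    "CCN(C)C", "OCCO",
)


def generate_smiles_fixture(
    n_families: int = 3,
    r_groups_per_family: int = 5,
    n_decoys: int = 50,
    seed: int = DEFAULT_DATASET_SEED,
) -> pd.DataFrame:
    """Enumerate a small chemistry deck: family actives plus template decoys.

    Returns a DataFrame with columns ``compound_id, smiles, activity``.
    Actives are scaffold-plus-R-group enumerations (``r_groups_per_family``
    substituents sampled per family); decoys are sampled from the decoy
    template x R-group product. Deterministic for a given seed.
    """
    if n_families > len(FAMILY_TEMPLATES):
        raise ValueError(f"at most {len(FAMILY_TEMPLATES)} families available")
    if r_groups_per_family > len(R_GROUPS):
        raise ValueError(f"at most {len(R_GROUPS)} R-groups available")
    max_decoys = len(DECOY_TEMPLATES) * len(R_GROUPS)
    if n_decoys > max_decoys:
        raise ValueError(f"at most {max_decoys} decoys available")
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_families):
        rs = rng.choice(len(R_GROUPS), size=r_groups_per_family, replace=False)
        for j, ri in enumerate(sorted(rs)):
            rows.append(
                {
                    "compound_id": f"ACT_F{f}_{j}",
                    "smiles": FAMILY_TEMPLATES[f].format(R=R_GROUPS[ri]),
                    "activity": "active",
                }
            )
    combos = [(t, r) for t in range(len(DECOY_TEMPLATES)) for r in range(len(R_GROUPS))]
    picks = rng.choice(len(combos), size=n_decoys, replace=False)
    for j, p in enumerate(sorted(picks)):
        t, r = combos[p]
        rows.append(
            {
                "compound_id": f"DEC_{j:03d}",
                "smiles": DECOY_TEMPLATES[t].format(R=R_GROUPS[r]),
                "activity": "presumed_inactive",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Query plans and the experiment runner
# ---------------------------------------------------------------------------


@dataclass
class QueryPlan:
    """Nested query sets per repeat.

    ``draws[r]`` is repeat ``r``'s full query draw; the size-``s`` query
    set is its first ``s`` entries, so smaller sets are always subsets of
    the largest one. ``pool`` is the candidate set the draws came from;
    the whole pool is removed from the evaluated library so the deck is
    identical across repeats and sizes.
    """

    sizes: tuple[int, ...]
    seeds: tuple[int, ...]
    draws: tuple[tuple[str, ...], ...]
    pool: tuple[str, ...]

    @property
    def repeats(self) -> int:
        return len(self.seeds)

    def query_set(self, repeat: int, size: int) -> tuple[str, ...]:
        if size not in self.sizes:
            raise ValueError(f"size {size} not in plan sizes {self.sizes}")
        return self.draws[repeat][:size]


def select_query_pool(
    actives: Sequence[str], pool_size: int = 30, seed: int = DEFAULT_DATASET_SEED
) -> tuple[str, ...]:
    """Randomly select the actives reserved as screening queries."""
    actives = sorted(actives)
    if pool_size > len(actives):
        raise ValueError(f"pool_size {pool_size} exceeds {len(actives)} actives")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(actives), size=pool_size, replace=False)
    return tuple(actives[i] for i in picks)


def make_query_plan(
    actives: Sequence[str],
    sizes: Sequence[int] = (1, 2, 3, 4, 5),
    repeats: int = 30,
    seeds: Optional[Sequence[int]] = None,
) -> QueryPlan:
    """Draw per-repeat nested query sets from a pool of actives.

    Each repeat draws ``max(sizes)`` actives without replacement with its
    own seed (defaults: seeds 0..repeats-1); the size-``s`` set is the
    first ``s`` entries of the draw.
    """
    pool = sorted(set(actives))
    sizes = tuple(sorted(set(int(s) for s in sizes)))
    smax = max(sizes)
    if smax > len(pool):
        raise ValueError(f"cannot draw {smax} queries from {len(pool)} actives")
    if seeds is None:
        seeds = range(repeats)
    seeds = tuple(int(s) for s in seeds)
    if len(seeds) != repeats:
        raise ValueError("one seed per repeat is required")
    draws = []
    for s in seeds:
        rng = np.random.default_rng(s)
        picks = rng.choice(len(pool), size=smax, replace=False)
        draws.append(tuple(pool[i] for i in picks))
    return QueryPlan(sizes=sizes, seeds=seeds, draws=tuple(draws), pool=tuple(pool))


def _metric_row(
    ranking: RankedList,
    labels: dict,
    scaffold_map: dict,
    k_list: Sequence[float],
    **meta,
) -> dict:
    report = metrics.evaluate(ranking, labels, scaffold_map, k_list)
    row = dict(meta)
    row["auc"] = report.auc
    for k in k_list:
        row[f"ef_{k:g}"] = report.ef[k]
        row[f"srr_{k:g}"] = report.srr[k]
    row["n_actives"] = report.n_actives
    row["n_library"] = report.n_library
    return row


def run_experiment(
    lib: LatentLibrary,
    plan: QueryPlan,
    strategies: Sequence[str] = ("2d", "3d", "parallel", "integrated"),
    ratios: Optional[Sequence[SelectionRatio | tuple[int, int]]] = None,
    k_list: Sequence[float] = (1,),
) -> pd.DataFrame:
    """Run the full screening protocol and return a tidy metrics table.

    One row per repeat x query-set size x strategy (x ratio for parallel
    selection). Strategies ``2d``/``3d`` are the per-channel screens,
    MAX-fused over the size-``s`` query set (size 1 is the single-query
    baseline; ``2d_multi``/``3d_multi`` are accepted aliases). Parallel
    selection combines the two single-query baselines and is therefore
    reported at size 1 only; the integrated strategy combines the fused
    lists at every size (at size 1 it coincides with balanced parallel
    selection). Queries (the whole pool) are excluded from every metric.
    """
    canonical = {"2d_multi": "2d", "3d_multi": "3d"}
    strategies = [canonical.get(s, s) for s in strategies]
    unknown = set(strategies) - set(STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")

    pool = set(plan.pool)
    library_ids = [c for c in lib.compound_ids if c not in pool]
    labels = {c: lib.labels[c] for c in library_ids}
    scaffold_map = lib.scaffold_map
    ratio_list = [
        r if isinstance(r, SelectionRatio) else SelectionRatio(*r)
        for r in (ratios or [(1, 1)])
    ]

    rows = []
    for r in range(plan.repeats):
        queries = list(plan.draws[r])
        m2d = lib.score_matrix("a", queries, library_ids)
        m3d = lib.score_matrix("b", queries, library_ids)
        for size in plan.sizes:
            meta = {"repeat": r, "seed": plan.seeds[r], "size": size}
            f2d = fusion.max_fuse(m2d.subset_queries(size))
            f3d = fusion.max_fuse(m3d.subset_queries(size))
            if "2d" in strategies:
                rows.append(
                    _metric_row(f2d, labels, scaffold_map, k_list,
                                strategy="2d", ratio="", **meta)
                )
            if "3d" in strategies:
                rows.append(
                    _metric_row(f3d, labels, scaffold_map, k_list,
                                strategy="3d", ratio="", **meta)
                )
            if "parallel" in strategies and size == 1:
                for ratio in ratio_list:
                    combined = fusion.parallel_select(f2d, f3d, ratio)
                    rows.append(
                        _metric_row(combined, labels, scaffold_map, k_list,
                                    strategy="parallel", ratio=str(ratio), **meta)
                    )
            if "integrated" in strategies:
                combined = fusion.integrated(
                    m2d.subset_queries(size), m3d.subset_queries(size)
                )
                rows.append(
                    _metric_row(combined, labels, scaffold_map, k_list,
                                strategy="integrated", ratio="1:1", **meta)
                )
    return pd.DataFrame(rows)


def scaffold_overlap_table(
    lib: LatentLibrary, plan: QueryPlan, k_percent: float = 1.0, size: int = 1
) -> pd.DataFrame:
    """Per-repeat scaffold-overlap decomposition of the two channels.

    Uses the size-``size`` query set of each repeat (default: the
    single-query baselines, the setting under which the exclusive/both
    decomposition of recovered active scaffolds is usually reported).
    """
    pool = set(plan.pool)
    library_ids = [c for c in lib.compound_ids if c not in pool]
    labels = {c: lib.labels[c] for c in library_ids}
    rows = []
    for r in range(plan.repeats):
        queries = list(plan.query_set(r, size))
        f2d = fusion.max_fuse(lib.score_matrix("a", queries, library_ids))
        f3d = fusion.max_fuse(lib.score_matrix("b", queries, library_ids))
        rep = metrics.scaffold_overlap(f2d, f3d, labels, lib.scaffold_map, k_percent)
        rows.append(
            {
                "repeat": r,
                "seed": plan.seeds[r],
                "size": size,
                "k": k_percent,
                "srr_2d": metrics.scaffold_recovery(f2d, labels, lib.scaffold_map, k_percent),
                "srr_3d": metrics.scaffold_recovery(f3d, labels, lib.scaffold_map, k_percent),
                "exclusive_2d": rep.exclusive_a,
                "exclusive_3d": rep.exclusive_b,
                "both": rep.both,
                "at_least_one": rep.at_least_one,
            }
        )
    return pd.DataFrame(rows)


def summarize(reports: pd.DataFrame) -> pd.DataFrame:
    """Mean and stdev per strategy/size(/ratio) over repeats.

    When a ``target`` column is present, values are first averaged within
    each target over its repeats and then across targets, so every target
    contributes one value regardless of its repeat count.
    """
    metric_cols = [
        c for c in reports.columns
        if c == "auc" or c.startswith("ef_") or c.startswith("srr_")
    ]
    keys = [c for c in ("strategy", "size", "ratio") if c in reports.columns]
    if "target" in reports.columns:
        per_target = reports.groupby(keys + ["target"], sort=True)[metric_cols].mean()
        grouped = per_target.groupby(keys, sort=True)
    else:
        grouped = reports.groupby(keys, sort=True)[metric_cols]
    mean = grouped.mean().add_suffix("_mean")
    std = grouped.std(ddof=1).add_suffix("_stdev")
    return pd.concat([mean, std], axis=1).reset_index()


def compare_strategies(
    reports: pd.DataFrame,
    pairs: Sequence[tuple],
    metric: str = "auc",
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank comparisons between strategy settings.

    Each pair is ``((strategy_a, size_a), (strategy_b, size_b))``. Pairing
    is across targets when a ``target`` column is present (one averaged
    value per target), otherwise across repeats. Degenerate comparisons
    (all differences zero) are flagged instead of reporting a p-value.
    """
    unit = "target" if "target" in reports.columns else "repeat"
    rows = []
    for (sa, za), (sb, zb) in pairs:
        sel_a = reports[(reports["strategy"] == sa) & (reports["size"] == za)]
        sel_b = reports[(reports["strategy"] == sb) & (reports["size"] == zb)]
        a = sel_a.groupby(unit, sort=True)[metric].mean()
        b = sel_b.groupby(unit, sort=True)[metric].mean()
        common = a.index.intersection(b.index)
        if len(common) != len(a) or len(common) != len(b):
            raise ValueError(f"mismatched {unit} keys between {sa}/{za} and {sb}/{zb}")
        row = {
            "strategy_a": sa, "size_a": za, "strategy_b": sb, "size_b": zb,
            "metric": metric, "n_pairs": len(common),
            "mean_a": float(a[common].mean()), "mean_b": float(b[common].mean()),
        }
        try:
            stat, p = metrics.wilcoxon_signed_rank(a[common].values, b[common].values)
            row.update(statistic=stat, p_value=p, degenerate=False)
        except ValueError:
            row.update(statistic=np.nan, p_value=np.nan, degenerate=True)
        rows.append(row)
    return pd.DataFrame(rows)
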