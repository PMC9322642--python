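"""Evaluation metrics: AUC, EF, scaffold recovery/overlap, Wilcoxon test."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from synergyscreen.fusion import RankedList
from synergyscreen.metrics import (
    OverlapReport,
    auc,
    enrichment_factor,
    evaluate,
    scaffold_overlap,
    scaffold_recovery,
    topk_size,
    wilcoxon_signed_rank,
)


def _ranking(ids):
    return RankedList(tuple(ids), provenance="fp2d")


def _labels(ranking_ids, active_ids):
    active = set(active_ids)
    return {c: ("active" if c in active else "decoy") for c in ranking_ids}


def brute_force_auc(ranking_ids, labels):
    """All-pairs oracle: fraction of (active, decoy) pairs ranked concordantly."""
    pos = {c: i for i, c in enumerate(ranking_ids)}
    actives = [c for c in labels if labels[c] == "active"]
    decoys = [c for c in labels if labels[c] == "decoy"]
    concordant = sum(
        1 for a in actives for d in decoys if pos[a] < pos[d]
    )
    return concordant / (len(actives) * len(decoys))


class TestTopkSize:
    @pytest.mark.parametrize(
        "n,k,expected",
        [(1000, 1, 10), (95_000, 1, 950), (101, 1, 2), (10, 1, 1), (7, 100, 7)],
    )
    def test_examples(self, n, k, expected):
        assert topk_size(n, k) == expected

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            topk_size(100, 0)


class TestAuc:
    def test_perfect_separation(self):
        r = _ranking(["a1", "a2", "d1", "d2"])
        assert auc(r, _labels(r.ids, {"a1", "a2"})) == 1.0

    def test_inverted(self):
        r = _ranking(["d1", "d2", "a1", "a2"])
        assert auc(r, _labels(r.ids, {"a1", "a2"})) == 0.0

    def test_alternating(self):
        r = _ranking(["a1", "d1", "a2", "d2"])
        assert auc(r, _labels(r.ids, {"a1", "a2"})) == 0.75

    def test_unlabeled_entries_ignored(self):
        r = _ranking(["q", "a1", "d1"])
        labels = {"a1": "active", "d1": "decoy"}
        assert auc(r, labels) == 1.0

    def test_missing_labeled_compound_rejected(self):
        r = _ranking(["a1", "d1"])
        with pytest.raises(ValueError, match="cover"):
            auc(r, {"a1": "active", "d1": "decoy", "ghost": "decoy"})

    def test_degenerate_rejected(self):
        r = _ranking(["a1", "a2"])
        with pytest.raises(ValueError):
            auc(r, _labels(r.ids, {"a1", "a2"}))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 60))
        n_act = int(rng.integers(1, n))
        ids = [f"c{i}" for i in range(n)]
        order = list(np.array(ids)[rng.permutation(n)])
        labels = _labels(ids, set(ids[:n_act]))
        assert auc(_ranking(order), labels) == brute_force_auc(order, labels)


class TestEnrichmentFactor:
    def test_derived_ef50(self):
        # 1000 compounds, 10 actives, 5 of them in the top 10
        top = [f"a{i}" for i in range(5)] + [f"d{i}" for i in range(5)]
        rest = [f"a{i}" for i in range(5, 10)] + [f"d{i}" for i in range(5, 990)]
        r = _ranking(top + rest)
        labels = _labels(r.ids, {f"a{i}" for i in range(10)})
        assert enrichment_factor(r, labels, 1) == pytest.approx(50.0)

    def test_cap_attained(self):
        r = _ranking([f"a{i}" for i in range(10)] + [f"d{i}" for i in range(990)])
        labels = _labels(r.ids, {f"a{i}" for i in range(10)})
        assert enrichment_factor(r, labels, 1) == pytest.approx(100.0)

    def test_invariant_to_decoy_permutation_below_cutoff(self, rng):
        ids = [f"a{i}" for i in range(3)] + [f"d{i}" for i in range(97)]
        labels = _labels(ids, {f"a{i}" for i in range(3)})
        base = _ranking(ids)
        ef = enrichment_factor(base, labels, 3)
        tail = list(base.ids[3:])
        rng.shuffle(tail)
        assert enrichment_factor(_ranking(list(base.ids[:3]) + tail), labels, 3) == ef

    def test_monotone_under_active_promotion(self):
        ids = ["d0", "d1", "a0", "d2", "d3", "d4", "d5", "d6", "d7", "d8"]
        labels = _labels(ids, {"a0"})
        before = enrichment_factor(_ranking(ids), labels, 10)
        promoted = ["a0"] + [c for c in ids if c != "a0"]
        after = enrichment_factor(_ranking(promoted), labels, 10)
        assert after >= before


class TestScaffoldRecovery:
    SCAFFOLDS = {f"a{i}": f"s{i % 10}" for i in range(20)}

    def test_partial_recovery(self):
        # top 1% of 400 = 4 slots; actives a0..a3 cover scaffolds s0..s3 (4 of 10)
        actives = [f"a{i}" for i in range(20)]
        decoys = [f"d{i}" for i in range(380)]
        order = actives[:4] + decoys + actives[4:]
        labels = _labels(order, set(actives))
        srr = scaffold_recovery(_ranking(order), labels, self.SCAFFOLDS, 1)
        assert srr == pytest.approx(0.4)

    def test_all_and_none(self):
        actives = [f"a{i}" for i in range(20)]
        decoys = [f"d{i}" for i in range(20)]
        labels = _labels(actives + decoys, set(actives))
        assert scaffold_recovery(
            _ranking(actives + decoys), labels, self.SCAFFOLDS, 50
        ) == 1.0
        assert scaffold_recovery(
            _ranking(decoys + actives), labels, self.SCAFFOLDS, 50
        ) == 0.0

    def test_missing_scaffold_key_rejected(self):
        labels = _labels(["a0", "d0"], {"a0"})
        with pytest.raises(ValueError, match="scaffold"):
            scaffold_recovery(_ranking(["a0", "d0"]), labels, {}, 10)


class TestScaffoldOverlap:
    def test_set_arithmetic_example(self):
        # A = {s1, s2}, B = {s2, s3}, T = 10
        actives = [f"a{i}" for i in range(10)]
        scaffolds = {f"a{i}": f"s{i}" for i in range(10)}
        decoys = [f"d{i}" for i in range(90)]
        labels = _labels(actives + decoys, set(actives))
        rank_a = _ranking(["a1", "a2"] + decoys + [c for c in actives if c not in ("a1", "a2")])
        rank_b = _ranking(["a2", "a3"] + decoys + [c for c in actives if c not in ("a2", "a3")])
        rep = scaffold_overlap(rank_a, rank_b, labels, scaffolds, 2)
        assert rep == OverlapReport(0.1, 0.1, 0.1, 0.3)

    def test_identical_rankings(self):
        actives = [f"a{i}" for i in range(10)]
        scaffolds = {f"a{i}": f"s{i}" for i in range(10)}
        decoys = [f"d{i}" for i in range(90)]
        order = actives[:3] + decoys + actives[3:]
        labels = _labels(order, set(actives))
        r = _ranking(order)
        rep = scaffold_overlap(r, r, labels, scaffolds, 3)
        assert rep.exclusive_a == rep.exclusive_b == 0.0
        assert rep.both == scaffold_recovery(r, labels, scaffolds, 3)

    @given(st.integers(0, 2**31 - 1))
    def test_identity_holds(self, seed):
        rng = np.random.default_rng(seed)
        n_act, n_dec = 12, 48
        ids = [f"a{i}" for i in range(n_act)] + [f"d{i}" for i in range(n_dec)]
        scaffolds = {f"a{i}": f"s{rng.integers(5)}" for i in range(n_act)}
        labels = _labels(ids, {f"a{i}" for i in range(n_act)})
        ra = _ranking(list(np.array(ids)[rng.permutation(len(ids))]))
        rb = _ranking(list(np.array(ids)[rng.permutation(len(ids))]))
        rep = scaffold_overlap(ra, rb, labels, scaffolds, 10)
        assert abs(rep.exclusive_a + rep.exclusive_b + rep.both - rep.at_least_one) < 1e-12


def exact_wilcoxon_by_enumeration(d):
    """Oracle: full enumeration of the 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    order = np.argsort(np.abs(d), kind="stable")
    # midranks
    ranks = np.empty(n)
    sorted_abs = np.abs(d)[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w_plus = ranks[d > 0].sum()
    w_min_obs = min(w_plus, ranks.sum() - w_plus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_min_obs:
            count += 1
    return min(1.0, 2 * count / 2**n)


class TestWilcoxon:
    def test_constant_shift_n10(self):
        a = np.arange(10, dtype=float)
        stat, p = wilcoxon_signed_rank(a + 1.0, a)
        assert stat == 0.0
        assert p == pytest.approx(2 / 1024)

    def test_antisymmetric(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=12), rng.normal(size=12)
        stat_ab, p_ab = wilcoxon_signed_rank(a, b)
        stat_ba, p_ba = wilcoxon_signed_rank(b, a)
        assert p_ab == p_ba and stat_ab == stat_ba

    def test_degenerate(self):
        a = np.arange(8, dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank(a, a)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2, 3], [3, 2, 1])

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        d = np.round(rng.normal(size=n), 1)
        d[d == 0] = 0.5
        # compare d against zeros so the paired differences are exactly d
        # (ties in |d| included), matching the enumeration oracle
        _, p = wilcoxon_signed_rank(d, np.zeros(n))
        assert p == pytest.approx(exact_wilcoxon_by_enumeration(d), abs=1e-12)

    def test_large_n_matches_scipy_approximation(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(11)
        a = rng.normal(size=60)
        b = a + rng.normal(0.3, 1.0, size=60)
        stat, p = wilcoxon_signed_rank(a, b)
        ref = scipy_wilcoxon(a, b, zero_method="wilcox", correction=False,
                             method="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_evaluate_report_fields():
    ids = [f"a{i}" for i in range(5)] + [f"d{i}" for i in range(95)]
    labels = _labels(ids, {f"a{i}" for i in range(5)})
    scaffolds = {f"a{i}": f"s{i}" for i in range(5)}
    report = evaluate(_ranking(ids), labels, scaffolds, k_list=(1, 10),
                      provenance={"strategy": "2d"})
    assert report.n_actives == 5 and report.n_library == 100
    assert set(report.ef) == {1, 10} and set(report.srr) == {1, 10}
    assert report.auc == 1.0
    assert report.srr[10] == 1.0
    assert report.provenance["strategy"] == "2d"
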