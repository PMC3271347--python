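"""Consensus/majority arithmetic, pairwise tables, combinations, restriction."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathconsensus.stats import (
    combination_gene_ec,
    combination_reaction_gene_ec,
    consensus,
    majority,
    pairwise_table,
    restricted_compare,
    round_half_up_pct,
)
from pathconsensus.stats import build_all_partitions, compare_partition

from conftest import met, rxn, snapshot


# Printed-table worked examples: (intersection-or-count, union, percent).
# Database-level gene/EC/metabolite/reaction statistics plus the single-pathway
# case study and the unique-gene total, as printed by the source comparison.
WORKED_EXAMPLES = [
    (510, 3858, 13),   # gene consensus
    (1636, 3858, 42),  # gene majority (>=3 of 5)
    (259, 1410, 18),   # EC consensus
    (400, 4679, 9),    # metabolite consensus
    (101, 7758, 1),    # reaction consensus, strict
    (199, 6968, 3),    # reaction consensus, relaxed
    (5, 30, 17),       # TCA reaction consensus
    (16, 45, 36),      # TCA gene consensus
    (6, 20, 30),       # TCA EC consensus
    (18, 41, 44),      # TCA metabolite consensus
    (1004, 6968, 14),  # reaction majority, relaxed
    (1139, 3858, 30),  # unique genes total
]


@pytest.mark.parametrize("count,total,expected", WORKED_EXAMPLES)
def test_round_half_up_reproduces_printed_percentages(count, total, expected):
    assert round_half_up_pct(count, total) == expected


def test_round_half_up_is_half_up_not_bankers():
    assert round_half_up_pct(1, 8) == 13  # 12.5 rounds up
    assert round_half_up_pct(3, 8) == 38  # 37.5 rounds up


class TestConsensus:
    def test_brute_force_membership_enumeration(self):
        rng = np.random.default_rng(17)
        universe = list(range(40))
        for _ in range(20):
            sets = {
                f"db{i}": {x for x in universe if rng.random() < 0.5}
                for i in range(4)
            }
            if not any(sets.values()):
                continue
            res = consensus(sets, majority_threshold=3)
            # oracle: enumerate each element's membership count
            union = set().union(*sets.values())
            counts = {x: sum(x in s for s in sets.values()) for x in union}
            assert res.union_size == len(union)
            assert res.consensus_count == sum(1 for c in counts.values() if c == 4)
            assert res.majority_count == sum(1 for c in counts.values() if c >= 3)
            for k in range(1, 5):
                assert res.occurrence_histogram[k] == sum(
                    1 for c in counts.values() if c == k
                )
            assert sum(res.occurrence_histogram.values()) == res.union_size
            assert res.unique_total == res.occurrence_histogram[1]

    def test_identical_sets_full_consensus(self):
        sets = {n: {1, 2, 3} for n in ("A", "B", "C", "D", "E")}
        res = consensus(sets)
        assert res.consensus_pct == 100
        assert res.unique_total == 0

    def test_order_invariance(self):
        sets = {"A": {1, 2}, "B": {2, 3}, "C": {3, 4}}
        results = []
        for perm in itertools.permutations(sets):
            results.append(consensus({k: sets[k] for k in perm}))
        assert all(r == results[0] for r in results)

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError, match="empty union"):
            consensus({"A": set(), "B": set()}, majority_threshold=2)


class TestMajority:
    def test_threshold_one_is_whole_union(self):
        sets = {"A": {1}, "B": {2}, "C": {3}}
        count, pct = majority(sets, threshold=1)
        assert count == 3 and pct == 100

    def test_threshold_n_equals_consensus(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            sets = {f"db{i}": set(rng.integers(0, 20, size=8).tolist()) for i in range(5)}
            res = consensus(sets)
            count, pct = majority(sets, threshold=5)
            assert count == res.consensus_count and pct == res.consensus_pct

    def test_monotone_in_threshold(self):
        sets = {f"db{i}": set(range(i, i + 6)) for i in range(4)}
        counts = [majority(sets, threshold=t)[0] for t in range(1, 5)]
        assert counts == sorted(counts, reverse=True)


class TestPairwise:
    def test_disjoint_and_nested(self):
        table = pairwise_table({"A": {1, 2}, "B": {3, 4}})
        assert table.loc["A", "B"] == 0.0
        table = pairwise_table({"A": {1, 2}, "B": {1, 2, 3, 4}})
        assert table.loc["A", "B"] == pytest.approx(50.0)
        assert table.loc["A", "A"] == 100.0

    def test_symmetric_and_bounded_below_by_nway(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            sets = {f"db{i}": set(rng.integers(0, 15, size=10).tolist()) for i in range(4)}
            table = pairwise_table(sets)
            assert (table.values == table.values.T).all()
            nway = consensus(sets)
            for a in sets:
                for b in sets:
                    if a != b:
                        # the pair intersection contains the N-way intersection
                        assert len(sets[a] & sets[b]) >= nway.consensus_count


def _annotated_snapshots(n_snapshots=3):
    """Snapshots with identical reactions but planted gene/EC disagreement."""

    def build(name, extra_gene=False, other_ec=False):
        mets = [
            met("A", names=("cpd A",), kegg_compound="C10001"),
            met("B", names=("cpd B",), kegg_compound="C10002"),
            met("C", names=("cpd C",), kegg_compound="C10003"),
            met("D", names=("cpd D",), kegg_compound="C10004"),
        ]
        genes = ["11", "22", "33"] + (["44"] if extra_gene else [])
        rxns = [
            # full agreement everywhere
            rxn("r1", ["A"], ["B"], genes=["g11"], ecs=["1.1.1.1"]),
            # extra gene in one snapshot
            rxn("r2", ["B"], ["C"], genes=["g22"] + (["g44"] if extra_gene else []), ecs=["2.2.2.2"]),
            # EC disagreement in one snapshot
            rxn("r3", ["C"], ["D"], genes=["g33"], ecs=["4.4.4.4" if other_ec else "3.3.3.3"]),
        ]
        return snapshot(name, metabolites=mets, reactions=rxns, genes=genes)

    return [build("A"), build("B", extra_gene=True), build("C", other_ec=True)]


class TestCombinations:
    def test_reaction_gene_ec_buckets(self):
        snaps = _annotated_snapshots()
        parts = build_all_partitions(snaps)
        out = combination_reaction_gene_ec(
            snaps, parts["reaction"], parts["gene"], parts["ec"]
        )
        assert out["consensus_reactions"] == 3
        assert out["full_agreement"] == 1  # r1
        assert out["ec_only"] == 1         # r2: ECs agree, extra gene in B
        assert out["gene_only"] == 1       # r3: genes agree, EC differs in C
        assert out["no_common_ec"] == 1    # r3 has no shared EC class
        assert out["no_common_gene"] == 0
        assert out["additional_genes"] == 1

    def test_gene_ec_buckets(self):
        snaps = _annotated_snapshots()
        parts = build_all_partitions(snaps)
        out = combination_gene_ec(snaps, parts["gene"], parts["ec"])
        # genes 11 and 22 keep identical EC sets; gene 33's EC set differs in C
        assert out["consensus_genes"] == 3
        assert out["all_ec_agree"] == 2
        assert out["no_common_ec"] == 1

    def test_planted_rates_recovered_from_generator(self):
        from pathconsensus.synthetic import PerturbationProfile, derive_snapshot, generate_ground_truth
        from pathconsensus.synthetic import true_overlap

        truth = generate_ground_truth(80, 5, seed=13)
        prof = PerturbationProfile(seed=13)
        snaps, ledgers = [], []
        for n in ("A", "B", "C"):
            s, l = derive_snapshot(truth, prof, n)
            snaps.append(s)
            ledgers.append(l)
        parts = build_all_partitions(snaps)
        out = combination_reaction_gene_ec(snaps, parts["reaction"], parts["gene"], parts["ec"])
        # identity profiles: every consensus reaction fully agrees
        assert out["consensus_reactions"] == len(truth.reactions)
        assert out["full_agreement"] == out["consensus_reactions"]


class TestRestrictedCompare:
    def _snaps(self):
        from pathconsensus.synthetic import PerturbationProfile, derive_snapshot, generate_ground_truth

        truth = generate_ground_truth(40, 4, seed=8)
        prof = PerturbationProfile(p_cov=0.9, seed=8)
        return truth, [derive_snapshot(truth, prof, n)[0] for n in ("A", "B")]

    def test_pathway_scope_subsets_reactions(self):
        truth, snaps = self._snaps()
        pw = sorted(truth.pathways)[0]
        pw_name = truth.pathways[pw].name
        res = restricted_compare(snaps, pw_name, majority_threshold=2)
        expected_union = {
            r.truth_id for r in truth.reactions.values() if r.pathway == pw
        }
        assert res["reactions"].union_size <= len(expected_union)
        assert res["reactions"].union_size > 0

    def test_missing_scope_lists_snapshots(self):
        _, snaps = self._snaps()
        with pytest.raises(ValueError, match="A, B"):
            restricted_compare(snaps, "no such pathway")

    def test_category_scope_matches_hand_filter(self):
        truth, snaps = self._snaps()
        scope = {"energy metabolism"}
        res = restricted_compare(snaps, scope, majority_threshold=2)
        # independent filter-then-count: reactions whose truth pathway has the
        # category, present in both snapshots
        wanted = {
            rid
            for rid, r in truth.reactions.items()
            if r.pathway and truth.pathways[r.pathway].category in scope
        }
        per_snap = []
        for s in snaps:
            per_snap.append({rid for rid in s.reactions if rid in wanted})
        union = per_snap[0] | per_snap[1]
        inter = per_snap[0] & per_snap[1]
        assert res["reactions"].union_size == len(union)
        assert res["reactions"].consensus_count == len(inter)

    def test_whole_scope_equals_unrestricted(self):
        truth, snaps = self._snaps()
        all_cats = {p.category for p in truth.pathways.values()}
        res = restricted_compare(snaps, all_cats, majority_threshold=2)
        parts = build_all_partitions(snaps)
        full = compare_partition(parts["reaction"], 2)
        assert res["reactions"].union_size == full.union_size
        assert res["reactions"].consensus_count == full.consensus_count


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(
        st.sets(st.integers(0, 12), min_size=0, max_size=8), min_size=2, max_size=5
    ).filter(lambda sets: any(sets))
)
def test_consensus_majority_inequalities(raw_sets):
    sets = {f"db{i}": s for i, s in enumerate(raw_sets)}
    n = len(sets)
    res = consensus(sets, majority_threshold=min(3, n))
    assert res.consensus_pct <= res.majority_pct <= 100
    assert res.consensus_count <= min(len(s) for s in sets.values())
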