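"""Metabolite cascade, transitive closure, reaction/gene/EC partitions."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathconsensus.datamodel import GeneRecord, IdentifierBundle, MetaboliteRecord
from pathconsensus.matching import (
    EntityKey,
    MatchConfig,
    build_ec_partition,
    build_gene_partition,
    build_metabolite_partition,
    build_reaction_partition,
    formulas_equal,
    metabolites_match,
    normalize_name,
    reaction_signature,
    resolve_ignore_classes,
)

from conftest import met, rxn, snapshot


# ---------------------------------------------------------------------------
# Name normalisation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Acetyl-CoA", "acetylcoa"),
        ("acetyl CoA", "acetylcoa"),
        ("ACETYL_COA", "acetylcoa"),
        ("D-glucose 6-phosphate", "dglucose6phosphate"),
        ("H+", "h"),
        ("N‐acetyl", "nacetyl"),  # unicode hyphen treated like ASCII dash
    ],
)
def test_normalize_name_case_space_punctuation(raw, expected):
    assert normalize_name(raw) == expected


def test_normalize_name_no_transliteration():
    # Greek letters are preserved, never spelled out: these stay distinct
    assert normalize_name("α-D-Glucose") != normalize_name("alpha-D-glucose")
    assert normalize_name("α-D-Glucose") == normalize_name("α D Glucose")


# ---------------------------------------------------------------------------
# Metabolite cascade decision table
# ---------------------------------------------------------------------------


def _m(**kw) -> MetaboliteRecord:
    defaults = dict(local_id="m", names=("x",))
    defaults.update(kw)
    names = defaults.pop("names")
    ids = {
        k: defaults.pop(k)
        for k in ("kegg_compound", "kegg_glycan", "chebi", "pubchem_compound", "cas")
        if k in defaults
    }
    return MetaboliteRecord(names=tuple(names), ids=IdentifierBundle(**ids), **defaults)


class TestMetaboliteCascade:
    """Decision table over every route of the matching cascade."""

    def test_primary_id_equal_matches(self):
        a = _m(kegg_compound="C00031")
        b = _m(kegg_compound="C00031")
        assert metabolites_match(a, b) == (True, "kegg_compound")

    def test_primary_id_unequal_is_final_despite_secondary_agreement(self):
        # the stop rule: both carry the primary id, so nothing downstream runs
        a = _m(kegg_compound="C15972", cas="50-00-0", names=("lipoamide",), formula="C8H15NOS2")
        b = _m(kegg_compound="C00248", cas="50-00-0", names=("lipoamide",), formula="C8H15NOS2")
        assert metabolites_match(a, b) == (False, None)

    def test_override_pair_beats_primary_id_mismatch(self):
        # enzyme-bound vs unbound forms hand-annotated as the same compound
        a = _m(kegg_compound="C15972")
        b = _m(kegg_compound="C00248")
        cfg = MatchConfig(override_pairs=(("kegg_compound:C15972", "kegg_compound:C00248"),))
        assert metabolites_match(a, b, cfg) == (True, "override")
        assert metabolites_match(b, a, cfg) == (True, "override")

    def test_secondary_id_route_when_primary_absent(self):
        a = _m(cas="64-17-5")
        b = _m(kegg_compound="C00469", cas="64-17-5")
        assert metabolites_match(a, b) == (True, "secondary_id:cas")

    @pytest.mark.parametrize("ns", ["kegg_glycan", "chebi", "pubchem_compound"])
    def test_each_secondary_namespace_can_carry_the_match(self, ns):
        a = _m(**{ns: "G00001" if ns == "kegg_glycan" else "1234"})
        b = _m(**{ns: "G00001" if ns == "kegg_glycan" else "1234"})
        assert metabolites_match(a, b) == (True, f"secondary_id:{ns}")

    def test_disagreeing_secondary_does_not_block_name_route(self):
        a = _m(chebi="111", names=("pyruvate",), formula="C3H4O3")
        b = _m(chebi="222", names=("pyruvate",), formula="C3H4O3")
        assert metabolites_match(a, b) == (True, "name+formula")

    def test_name_route_requires_equal_formula(self):
        a = _m(names=("glucose",), formula="C6H12O6")
        b = _m(names=("glucose",), formula="C6H10O5")
        assert metabolites_match(a, b) == (False, None)

    def test_name_route_requires_formula_presence_on_both(self):
        a = _m(names=("glucose",), formula="C6H12O6")
        b = _m(names=("glucose",))
        assert metabolites_match(a, b) == (False, None)
        cfg = MatchConfig(name_requires_formula=False)
        assert metabolites_match(a, b, cfg) == (True, "name+formula")

    def test_name_route_matches_any_shared_synonym(self):
        a = _m(names=("alpha-D-glucose", "dextrose"), formula="C6H12O6")
        b = _m(names=("Dextrose",), formula="C6H12O6")
        assert metabolites_match(a, b) == (True, "name+formula")

    def test_h_tolerant_formula_mode(self):
        a = _m(names=("glucose",), formula="C6H12O6")
        b = _m(names=("glucose",), formula="C6H11O6")
        assert metabolites_match(a, b) == (False, None)
        assert metabolites_match(a, b, MatchConfig(h_tolerant_formula=True)) == (
            True,
            "name+formula",
        )
        # H tolerance never excuses a non-H difference
        c = _m(names=("glucose",), formula="C5H12O6")
        assert metabolites_match(a, c, MatchConfig(h_tolerant_formula=True)) == (False, None)

    def test_generic_never_matches_specific(self):
        generic = _m(names=("an alcohol",), is_generic=True, kegg_compound="C00069")
        specific = _m(names=("ethanol",), kegg_compound="C00069")
        assert metabolites_match(generic, specific) == (False, None)
        # guard off: the shared primary id carries the match
        cfg = MatchConfig(generic_specific_guard=False)
        assert metabolites_match(generic, specific, cfg) == (True, "kegg_compound")

    def test_quarantined_name_cannot_carry_match(self):
        a = _m(names=("isomerX",), formula="C4H8O4")
        b = _m(names=("isomerX",), formula="C4H8O4")
        assert metabolites_match(a, b)[0]
        assert metabolites_match(
            a, b, quarantined_names=frozenset({"isomerx"})
        ) == (False, None)

    def test_no_route_no_match(self):
        assert metabolites_match(_m(names=("a",)), _m(names=("b",))) == (False, None)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_cascade_symmetry(data):
    """metabolites_match(a, b) == metabolites_match(b, a) on fuzzed records."""
    ids = st.one_of(st.none(), st.sampled_from(["C00001", "C00002", "C00003"]))
    chebis = st.one_of(st.none(), st.sampled_from(["1", "2"]))

    def record():
        kwargs = {}
        kc = data.draw(ids)
        if kc:
            kwargs["kegg_compound"] = kc
        ch = data.draw(chebis)
        if ch:
            kwargs["chebi"] = ch
        return _m(
            names=(data.draw(st.sampled_from(["x", "y", "z"])),),
            formula=data.draw(st.one_of(st.none(), st.sampled_from(["CH4", "C2H6"]))),
            is_generic=data.draw(st.booleans()),
            **kwargs,
        )

    a, b = record(), record()
    cfg = MatchConfig(h_tolerant_formula=data.draw(st.booleans()))
    assert metabolites_match(a, b, cfg)[0] == metabolites_match(b, a, cfg)[0]


# ---------------------------------------------------------------------------
# Brute-force oracle for partitions
# ---------------------------------------------------------------------------


def brute_force_metabolite_partition(snapshots, cfg=None):
    """Independent oracle: connected components of the all-pairs match graph."""
    from pathconsensus.matching import _quarantined_names

    cfg = cfg or MatchConfig()
    quarantine = _quarantined_names(snapshots)
    keyed = [
        (EntityKey(s.name, m.local_id, "metabolite"), s.name, m)
        for s in snapshots
        for m in s.metabolites.values()
    ]
    g = nx.Graph()
    g.add_nodes_from(k for k, _, _ in keyed)
    for i in range(len(keyed)):
        for j in range(i + 1, len(keyed)):
            (ki, si, mi), (kj, sj, mj) = keyed[i], keyed[j]
            ok, _ = metabolites_match(
                mi, mj, cfg, snapshot_a=si, snapshot_b=sj, quarantined_names=quarantine
            )
            if ok:
                g.add_edge(ki, kj)
    return {frozenset(c) for c in nx.connected_components(g)}


def random_fixture(rng, n_per_snapshot=30, n_snapshots=3):
    """Random metabolite fixture exercising every cascade route."""
    snaps = []
    n_compounds = max(4, n_per_snapshot // 2)
    for s in range(n_snapshots):
        mets = []
        for i in range(n_per_snapshot):
            cid = int(rng.integers(0, n_compounds))
            kwargs = {}
            if rng.random() < 0.6:
                kwargs["kegg_compound"] = f"C{10000 + cid:05d}"
            if rng.random() < 0.4:
                kwargs["chebi"] = str(100 + cid)
            if rng.random() < 0.3:
                kwargs["cas"] = f"{50 + cid}-00-{cid % 10}"
            mets.append(
                met(
                    f"m{s}_{i}",
                    names=(f"compound {cid}",),
                    formula=f"C{cid + 1}H{2 * cid + 2}" if rng.random() < 0.8 else None,
                    is_generic=rng.random() < 0.1,
                    **kwargs,
                )
            )
        snaps.append(snapshot(f"db{s}", metabolites=mets))
    return snaps


class TestPartitionOracleEquivalence:
    def test_transitive_closure_bridges_namespaces(self):
        a = snapshot("A", metabolites=[met("m1", names=("u",), cas="50-00-0")])
        b = snapshot(
            "B", metabolites=[met("m1", names=("v",), cas="50-00-0", chebi="16842")]
        )
        c = snapshot("C", metabolites=[met("m1", names=("w",), chebi="16842")])
        part = build_metabolite_partition([a, b, c])
        assert len(part.classes) == 1
        assert len(part.classes[0]) == 3

    def test_no_matches_all_singletons(self):
        a = snapshot("A", metabolites=[met("m1", names=("one",)), met("m2", names=("two",))])
        b = snapshot("B", metabolites=[met("m1", names=("three",))])
        part = build_metabolite_partition([a, b])
        assert all(len(c) == 1 for c in part.classes)
        assert len(part.classes) == 3

    def test_partition_equals_brute_force_components(self):
        rng = np.random.default_rng(42)
        for trial in range(8):
            snaps = random_fixture(rng, n_per_snapshot=40)
            part = build_metabolite_partition(snaps)
            assert set(part.classes) == brute_force_metabolite_partition(snaps)

    def test_partition_covers_all_and_is_disjoint(self):
        rng = np.random.default_rng(7)
        snaps = random_fixture(rng)
        part = build_metabolite_partition(snaps)
        members = [m for c in part.classes for m in c]
        assert len(members) == len(set(members))
        total = sum(len(s.metabolites) for s in snaps)
        assert len(members) == total

    def test_generic_guard_soundness(self):
        rng = np.random.default_rng(3)
        snaps = random_fixture(rng)
        part = build_metabolite_partition(snaps)
        by_key = {
            EntityKey(s.name, m.local_id, "metabolite"): m
            for s in snaps
            for m in s.metabolites.values()
        }
        for cls in part.classes:
            flags = {by_key[k].is_generic for k in cls}
            assert len(flags) == 1


# ---------------------------------------------------------------------------
# Reaction signatures and partition
# ---------------------------------------------------------------------------


def _reaction_snapshots():
    def build(name, reactions):
        mets = [
            met("A", names=("cpd A",), kegg_compound="C10001"),
            met("B", names=("cpd B",), kegg_compound="C10002"),
            met("C", names=("cpd C",), kegg_compound="C10003"),
            met("h2o", names=("H2O",), kegg_compound="C00001"),
            met("h", names=("H+",), kegg_compound="C00080"),
        ]
        return snapshot(name, metabolites=mets, reactions=reactions)

    return build


class TestReactionSignature:
    def test_direction_and_ignored_water_collapse(self):
        build = _reaction_snapshots()
        a = build("A", [rxn("r1", ["A", "h2o"], ["B"])])
        b = build("B", [rxn("r1", ["B"], ["A"])])
        part_m = build_metabolite_partition([a, b])
        part_r = build_reaction_partition([a, b], part_m)
        assert len(part_r.classes) == 1

    def test_proton_blocks_strict_but_not_relaxed(self):
        build = _reaction_snapshots()
        a = build("A", [rxn("r1", ["A"], ["B"])])
        b = build("B", [rxn("r1", ["A"], ["B", "h"])])
        part_m = build_metabolite_partition([a, b])
        strict = build_reaction_partition([a, b], part_m, MatchConfig(ignore_metabolites=frozenset()))
        relaxed = build_reaction_partition([a, b], part_m)
        assert len(strict.classes) == 2
        assert len(relaxed.classes) == 1

    def test_pure_water_transport_degenerate_and_excluded(self):
        mets = [
            met("h2o_c", names=("H2O",), compartment="c", kegg_compound="C00001"),
            met("h2o_m", names=("H2O",), compartment="m", kegg_compound="C00001"),
        ]
        a = snapshot("A", metabolites=mets, reactions=[rxn("r1", ["h2o_c"], ["h2o_m"])])
        b = snapshot("B", metabolites=[met("x", names=("cpd",))], reactions=[])
        part_m = build_metabolite_partition([a, b])
        part_r = build_reaction_partition([a, b], part_m)
        assert part_r.classes == []
        assert [k.local_id for k in part_r.excluded["degenerate_signature"]] == ["r1"]

    def test_same_reaction_both_directions_counted_once(self):
        build = _reaction_snapshots()
        a = build("A", [rxn("r1", ["A"], ["B"]), rxn("r2", ["B"], ["A"])])
        b = build("B", [rxn("r1", ["A"], ["B"])])
        part_m = build_metabolite_partition([a, b])
        part_r = build_reaction_partition([a, b], part_m)
        assert len(part_r.classes) == 1
        sets = part_r.entity_sets()
        assert len(sets["A"]) == 1 and len(sets["B"]) == 1

    def test_strict_classes_contained_in_relaxed_classes(self):
        from pathconsensus.synthetic import PerturbationProfile, derive_snapshot, generate_ground_truth

        truth = generate_ground_truth(60, 4, seed=21)
        prof = PerturbationProfile(p_cov=0.9, p_balance_h2o_hplus=0.5, p_flip_direction=0.3, seed=21)
        snaps = [derive_snapshot(truth, prof, n)[0] for n in ("A", "B", "C")]
        part_m = build_metabolite_partition(snaps)
        strict = build_reaction_partition(snaps, part_m, MatchConfig(ignore_metabolites=frozenset()))
        relaxed = build_reaction_partition(snaps, part_m)
        relaxed_classes = list(relaxed.classes)
        relaxed_excluded = set(relaxed.excluded.get("degenerate_signature", []))
        for s_cls in strict.classes:
            comparable = s_cls - relaxed_excluded
            if not comparable:
                continue
            assert any(comparable <= r_cls for r_cls in relaxed_classes)

    def test_ignore_set_monotonicity(self):
        """Enlarging the ignore set never decreases cross-snapshot matches and
        never increases the countable union."""
        from pathconsensus.synthetic import PerturbationProfile, derive_snapshot, generate_ground_truth

        truth = generate_ground_truth(50, 4, seed=31)
        prof = PerturbationProfile(p_cov=0.8, p_balance_h2o_hplus=0.6, seed=31)
        snaps = [derive_snapshot(truth, prof, n)[0] for n in ("A", "B")]
        part_m = build_metabolite_partition(snaps)

        def cross_matches_and_union(ignore):
            part = build_reaction_partition(snaps, part_m, MatchConfig(ignore_metabolites=ignore))
            cross = sum(
                1 for c in part.classes if len({k.snapshot_name for k in c}) > 1
            )
            return cross, len(part.classes)

        ignores = [frozenset(), frozenset({"H+"}), frozenset({"H+", "H2O"}), frozenset({"e-", "H+", "H2O"})]
        results = [cross_matches_and_union(ig) for ig in ignores]
        for (c1, u1), (c2, u2) in zip(results, results[1:]):
            assert c2 >= c1
            assert u2 <= u1


# ---------------------------------------------------------------------------
# Gene and EC partitions
# ---------------------------------------------------------------------------


class TestGenePartition:
    def test_identical_gene_id_groups_across_snapshots(self):
        snaps = [
            snapshot(n, genes=[GeneRecord("g1", "1737")]) for n in ("A", "B", "C")
        ]
        part = build_gene_partition(snaps)
        assert len(part.classes) == 1
        assert len(part.classes[0]) == 3

    def test_missing_gene_id_excluded_and_reported(self):
        snaps = [
            snapshot("A", genes=[GeneRecord("g1", "10"), GeneRecord("g2", None)]),
            snapshot("B", genes=[GeneRecord("g1", "10")]),
        ]
        part = build_gene_partition(snaps)
        assert len(part.classes) == 1
        assert [k.local_id for k in part.excluded["no_shared_identifier"]] == ["g2"]


class TestECPartition:
    def _snaps(self, ec_lists):
        out = []
        for i, ecs in enumerate(ec_lists):
            mets = [met("m1"), met("m2")]
            out.append(
                snapshot(
                    f"db{i}",
                    metabolites=mets,
                    reactions=[rxn("r1", ["m1"], ["m2"], ecs=ecs)],
                )
            )
        return out

    def test_partial_ec_excluded_at_level_4(self):
        part = build_ec_partition(self._snaps([["1.1.1.-", "1.1.1.1"], ["1.1.1.1"]]), level=4)
        assert len(part.classes) == 1
        assert [k.local_id for k in part.excluded["partial_ec"]] == ["1.1.1.-"]

    def test_level_3_groups_by_prefix(self):
        part = build_ec_partition(self._snaps([["1.1.1.1"], ["1.1.1.2"]]), level=3)
        assert len(part.classes) == 1
        part4 = build_ec_partition(self._snaps([["1.1.1.1"], ["1.1.1.2"]]), level=4)
        assert len(part4.classes) == 2

    def test_level3_class_count_never_exceeds_level4(self):
        rng = np.random.default_rng(5)
        ec_lists = [
            [f"{rng.integers(1, 4)}.{rng.integers(1, 4)}.{rng.integers(1, 4)}.{rng.integers(1, 6)}" for _ in range(10)]
            for _ in range(3)
        ]
        l3 = build_ec_partition(self._snaps(ec_lists), level=3)
        l4 = build_ec_partition(self._snaps(ec_lists), level=4)
        assert len(l3.classes) <= len(l4.classes)


def test_ignore_set_resolution_by_id_and_name():
    a = snapshot("A", metabolites=[met("w", names=("aqua",), kegg_compound="C00001")])
    b = snapshot("B", metabolites=[met("p", names=("H+",))])
    part = build_metabolite_partition([a, b])
    reps = resolve_ignore_classes(part, [a, b], MatchConfig())
    locals_ = {r.local_id for r in reps}
    assert locals_ == {"w", "p"}  # water via accession, proton via name


def test_formulas_equal_handles_multidigit_and_tolerance():
    assert formulas_equal("C10H16N5O13P3", "C10H16N5O13P3")
    assert not formulas_equal("C10H16N5O13P3", "C10H15N5O13P3")
    assert formulas_equal("C10H16N5O13P3", "C10H15N5O13P3", h_tolerant=True)
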