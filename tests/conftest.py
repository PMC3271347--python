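"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import pytest

from pathconsensus.datamodel import (
    DatabaseSnapshot,
    ECNumber,
    GeneRecord,
    IdentifierBundle,
    MetaboliteRecord,
    PathwayRecord,
    ReactionRecord,
)


def met(
    local_id: str,
    names=("x",),
    formula=None,
    compartment=None,
    is_generic=False,
    instance_ids=(),
    is_protein=False,
    **ids,
) -> MetaboliteRecord:
    return MetaboliteRecord(
        local_id=local_id,
        names=tuple(names),
        formula=formula,
        compartment=compartment,
        ids=IdentifierBundle(**ids),
        is_generic=is_generic,
        instance_ids=tuple(instance_ids),
        is_protein=is_protein,
    )


def rxn(local_id: str, side_a, side_b, genes=(), ecs=(), pathways=()) -> ReactionRecord:
    def as_side(entries):
        if isinstance(entries, dict):
            return entries
        return {m: 1.0 for m in entries}

    return ReactionRecord(
        local_id=local_id,
        side_a=as_side(side_a),
        side_b=as_side(side_b),
        genes=frozenset(genes),
        ecs=frozenset(ECNumber.parse(e) for e in ecs),
        pathways=frozenset(pathways),
    )


def snapshot(name: str, metabolites=(), reactions=(), genes=(), pathways=()) -> DatabaseSnapshot:
    snap = DatabaseSnapshot(name=name)
    for m in metabolites:
        snap.metabolites[m.local_id] = m
    for r in reactions:
        snap.reactions[r.local_id] = r
    for g in genes:
        if isinstance(g, str):
            g = GeneRecord(local_id=f"g{g}", gene_id=g)
        snap.genes[g.local_id] = g
    for p in pathways:
        if isinstance(p, tuple):
            p = PathwayRecord(local_id=p[0], name=p[1], category=p[2] if len(p) > 2 else None)
        snap.pathways[p.local_id] = p
    return snap


@pytest.fixture
def two_identical_snapshots():
    def build(name):
        mets = [
            met("m1", names=("alpha",), formula="C6H12O6", kegg_compound="C00031"),
            met("m2", names=("beta",), formula="C3H6O3", kegg_compound="C00186"),
            met("m3", names=("water",), formula="H2O", kegg_compound="C00001"),
        ]
        rxns = [
            rxn("r1", ["m1", "m3"], ["m2"], genes=["g10"], ecs=["1.1.1.1"], pathways=["p1"]),
        ]
        return snapshot(
            name,
            metabolites=mets,
            reactions=rxns,
            genes=[GeneRecord("g10", "10")],
            pathways=[("p1", "glycolysis")],
        )

    return build("A"), build("B")
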