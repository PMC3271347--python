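"""Pathway categorization and the core-metabolism subset.

Pathways are manually assigned to one of nine metabolism categories (guided by
the KEGG pathway hierarchy) plus ``miscellaneous`` for pathways that fit none,
and ``transport`` for transport pathways. Reactions, genes and EC numbers
inherit the categories of every pathway they belong to, so an entity may carry
several categories; reactions outside any pathway carry none and cannot enter
a category-restricted comparison.

The core subset keeps the six categories generally regarded as metabolism
proper (amino acid, carbohydrate, energy, lipid, cofactors-and-vitamins,
nucleotide) and drops transport reactions (participants spanning more than one
compartment) and, for databases that annotate them, macromolecular reactions
(any participant flagged as a protein).
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from pathlib import Path
from typing import Mapping

from .datamodel import DatabaseSnapshot, ReactionRecord

__all__ = [
    "CATEGORY_LABELS",
    "CORE_CATEGORIES",
    "assign_categories",
    "load_category_mapping",
    "reaction_categories",
    "is_transport",
    "is_macromolecular",
    "core_subset",
]

#: Closed vocabulary: nine KEGG-guided labels plus miscellaneous and transport.
CATEGORY_LABELS = frozenset(
    {
        "amino acid metabolism",
        "carbohydrate metabolism",
        "energy metabolism",
        "glycan biosynthesis and metabolism",
        "lipid metabolism",
        "metabolism of cofactors and vitamins",
        "metabolism of secondary metabolites",
        "nucleotide metabolism",
        "xenobiotics biodegradation and metabolism",
        "miscellaneous",
        "transport",
    }
)

CORE_CATEGORIES = frozenset(
    {
        "amino acid metabolism",
        "carbohydrate metabolism",
        "energy metabolism",
        "lipid metabolism",
        "metabolism of cofactors and vitamins",
        "nucleotide metabolism",
    }
)


def load_category_mapping(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``pathway_id<TAB>category`` → mapping."""
    mapping: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        header_skipped = False
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pid, _, cat = line.partition("\t")
            if not header_skipped and cat.strip().lower() == "category":
                header_skipped = True
                continue
            mapping[pid.strip()] = cat.strip()
    return mapping


def assign_categories(
    snapshot: DatabaseSnapshot, mapping: Mapping[str, str]
) -> DatabaseSnapshot:
    """Set pathway categories from a pathway→category table.

    Unmapped pathways fall back to ``miscellaneous`` with a warning; unknown
    labels are rejected.
    """
    out = DatabaseSnapshot(
        name=snapshot.name,
        genes=dict(snapshot.genes),
        metabolites=dict(snapshot.metabolites),
        reactions=dict(snapshot.reactions),
        uninstantiable=snapshot.uninstantiable,
    )
    for pid, pw in snapshot.pathways.items():
        cat = mapping.get(pid)
        if cat is None:
            warnings.warn(
                f"{snapshot.name}: pathway {pid!r} not in category mapping; "
                f"assigned 'miscellaneous'",
                stacklevel=2,
            )
            cat = "miscellaneous"
        if cat not in CATEGORY_LABELS:
            raise ValueError(f"pathway {pid!r}: unknown category {cat!r}")
        out.pathways[pid] = replace(pw, category=cat)
    return out


def reaction_categories(r: ReactionRecord, snapshot: DatabaseSnapshot) -> set[str]:
    """Categories a reaction inherits from its pathways (empty when the
    reaction belongs to no pathway or its pathways are uncategorized)."""
    cats = set()
    for pid in r.pathways:
        pw = snapshot.pathways.get(pid)
        if pw is not None and pw.category is not None:
            cats.add(pw.category)
    return cats


def is_transport(r: ReactionRecord, snapshot: DatabaseSnapshot) -> bool:
    """True iff the participants span more than one compartment. Absent
    compartments collapse into one shared "unspecified" pseudo-compartment so
    sparsely annotated databases are not spuriously full of transport."""
    compartments = set()
    for mid in r.participants():
        m = snapshot.metabolites[mid]
        compartments.add(m.compartment if m.compartment is not None else "__unspecified__")
    return len(compartments) > 1


def is_macromolecular(r: ReactionRecord, snapshot: DatabaseSnapshot) -> bool:
    """True iff at least one participant is flagged as a protein."""
    return any(snapshot.metabolites[mid].is_protein for mid in r.participants())


def core_subset(
    snapshot: DatabaseSnapshot,
    *,
    drop_macromolecular: bool = False,
    drop_transport: bool = True,
) -> DatabaseSnapshot:
    """Restrict a snapshot to core metabolic processes.

    Keeps reactions carrying at least one of the six core categories; drops
    pathway-less (hence uncategorizable) reactions, transport reactions (when
    ``drop_transport``) and macromolecular reactions (when
    ``drop_macromolecular`` — which databases get this filter is a per-run
    configuration choice, since only some annotate proteins as participants).
    Metabolites, genes and pathways are restricted to what the kept reactions
    reference. Idempotent; the output passes snapshot validation.
    """
    kept: set[str] = set()
    for r in snapshot.reactions.values():
        if not (reaction_categories(r, snapshot) & CORE_CATEGORIES):
            continue
        if drop_transport and is_transport(r, snapshot):
            continue
        if drop_macromolecular and is_macromolecular(r, snapshot):
            continue
        kept.add(r.local_id)

    from .stats import _subset_snapshot

    return _subset_snapshot(snapshot, kept)
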