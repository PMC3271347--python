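"""Agreement statistics over entity-class partitions.

The central quantity is the *consensus*: the size of the N-way intersection of
the per-database entity sets as a percentage of their union,

    consensus = |C_1 ∩ ... ∩ C_N| / |C_1 ∪ ... ∪ C_N| × 100%

where ``C_i`` is the set of entity equivalence classes present in database
``i``. Because the consensus is constrained by the smallest database, the
*majority score* — the fraction of the union present in at least k (default 3)
of the N databases — is reported alongside, together with the full occurrence
histogram (how many classes appear in exactly k databases) and per-database
unique counts.

Printed percentages are rounded half-up to whole percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Mapping, Sequence

import pandas as pd

from .datamodel import DatabaseSnapshot
from .matching import (
    EntityKey,
    MatchConfig,
    MatchPartition,
    build_ec_partition,
    build_gene_partition,
    build_metabolite_partition,
    build_reaction_partition,
)

__all__ = [
    "EntitySets",
    "ComparisonResult",
    "round_half_up_pct",
    "consensus",
    "majority",
    "pairwise_table",
    "pairwise_compare",
    "combination_gene_ec",
    "combination_reaction_gene_ec",
    "restricted_compare",
    "build_all_partitions",
    "compare_partition",
]

#: Per-snapshot sets of entity-class identifiers (class representatives, or
#: ground-truth ids when produced by the synthetic oracle).
EntitySets = Mapping[str, set]


def round_half_up_pct(count: int, total: int) -> int:
    """Percentage rounded half-up to a whole percent (the convention that
    reproduces printed database-comparison tables: 8.55→9, 16.67→17...)."""
    if total <= 0:
        raise ValueError("percentage of an empty union is undefined")
    return int(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class ComparisonResult:
    """Union size, occurrence histogram and derived agreement statistics for
    one entity class."""

    n_snapshots: int
    union_size: int
    #: k -> number of classes present in exactly k snapshots (k = 1..N).
    occurrence_histogram: dict[int, int]
    consensus_count: int
    consensus_pct: int
    majority_threshold: int
    majority_count: int
    majority_pct: int
    unique_per_snapshot: dict[str, int]
    #: reason -> number of entities excluded from the comparison.
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def unique_total(self) -> int:
        return self.occurrence_histogram.get(1, 0)

    def unique_pct(self, snapshot: str) -> int:
        return round_half_up_pct(self.unique_per_snapshot[snapshot], self.union_size)

    def to_row(self) -> dict:
        row = {
            "union": self.union_size,
            "consensus": self.consensus_count,
            "consensus_pct": self.consensus_pct,
            "majority": self.majority_count,
            "majority_pct": self.majority_pct,
            "unique_total": self.unique_total,
            "unique_total_pct": round_half_up_pct(self.unique_total, self.union_size),
        }
        for snap in sorted(self.unique_per_snapshot):
            row[f"unique_{snap}"] = self.unique_per_snapshot[snap]
        return row


def _compare(sets: EntitySets, majority_threshold: int) -> ComparisonResult:
    names = sorted(sets)
    n = len(names)
    if n < 2:
        raise ValueError("need at least two snapshots")
    if not (1 <= majority_threshold <= n):
        raise ValueError(f"majority threshold must be in 1..{n}")
    union: set = set()
    for name in names:
        union |= sets[name]
    if not union:
        raise ValueError("empty union: consensus percentage is undefined")

    occurrence: dict[Hashable, int] = {}
    owner: dict[Hashable, str] = {}
    for name in names:
        for entity in sets[name]:
            occurrence[entity] = occurrence.get(entity, 0) + 1
            owner[entity] = name

    histogram = {k: 0 for k in range(1, n + 1)}
    for count in occurrence.values():
        histogram[count] += 1
    unique_per_snapshot = {name: 0 for name in names}
    for entity, count in occurrence.items():
        if count == 1:
            unique_per_snapshot[owner[entity]] += 1

    consensus_count = histogram[n]
    majority_count = sum(histogram[k] for k in range(majority_threshold, n + 1))
    return ComparisonResult(
        n_snapshots=n,
        union_size=len(union),
        occurrence_histogram=histogram,
        consensus_count=consensus_count,
        consensus_pct=round_half_up_pct(consensus_count, len(union)),
        majority_threshold=majority_threshold,
        majority_count=majority_count,
        majority_pct=round_half_up_pct(majority_count, len(union)),
        unique_per_snapshot=unique_per_snapshot,
    )


def consensus(sets: EntitySets, majority_threshold: int = 3) -> ComparisonResult:
    """Full comparison result for one entity class. Order-independent in the
    snapshots: the sets are keyed by name and all outputs are sorted."""
    return _compare(sets, majority_threshold)


def majority(sets: EntitySets, threshold: int = 3) -> tuple[int, int]:
    """(count, pct) of classes present in at least ``threshold`` snapshots.
    ``threshold == N`` reproduces the consensus; ``threshold == 1`` covers the
    whole union (100%)."""
    result = _compare(sets, threshold)
    return result.majority_count, result.majority_pct


def compare_partition(
    partition: MatchPartition, majority_threshold: int = 3
) -> ComparisonResult:
    """ComparisonResult straight from a MatchPartition, carrying the
    partition's exclusion counts along."""
    result = _compare(partition.entity_sets(), majority_threshold)
    result.excluded = {reason: len(keys) for reason, keys in partition.excluded.items()}
    return result


# ---------------------------------------------------------------------------
# Pairwise comparisons
# ---------------------------------------------------------------------------


def pairwise_table(sets: EntitySets) -> pd.DataFrame:
    """Symmetric matrix of pairwise consensus percentages
    ``100·|C_i∩C_j|/|C_i∪C_j|`` (exact floats; diagonal 100).

    Only valid when the entity sets themselves are pair-independent (gene ids,
    EC numbers, ground-truth ids). For matcher-derived metabolite/reaction
    classes use :func:`pairwise_compare`, which rebuilds the partitions per
    pair so transitive closure through a third database cannot bridge a pair.
    """
    names = sorted(sets)
    data = []
    for a in names:
        row = []
        for b in names:
            if a == b:
                row.append(100.0)
            else:
                un = len(sets[a] | sets[b])
                row.append(100.0 * len(sets[a] & sets[b]) / un if un else 0.0)
        data.append(row)
    return pd.DataFrame(data, index=names, columns=names)


def pairwise_compare(
    snapshots: Sequence[DatabaseSnapshot],
    entity_class: str,
    cfg: MatchConfig | None = None,
) -> pd.DataFrame:
    """Pairwise consensus matrix with partitions rebuilt from each pair alone
    (no third-party transitive bridging)."""
    cfg = cfg or MatchConfig()
    names = sorted(s.name for s in snapshots)
    by_name = {s.name: s for s in snapshots}
    out = pd.DataFrame(100.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pair = [by_name[a], by_name[b]]
            if entity_class == "gene":
                part = build_gene_partition(pair)
            elif entity_class == "ec":
                part = build_ec_partition(pair)
            elif entity_class == "metabolite":
                part = build_metabolite_partition(pair, cfg)
            elif entity_class == "reaction":
                met = build_metabolite_partition(pair, cfg)
                part = build_reaction_partition(pair, met, cfg)
            else:
                raise ValueError(f"unknown entity class {entity_class!r}")
            sets = part.entity_sets()
            ca, cb = sets.get(a, set()), sets.get(b, set())
            un = len(ca | cb)
            value = 100.0 * len(ca & cb) / un if un else 0.0
            out.loc[a, b] = out.loc[b, a] = value
    return out


# ---------------------------------------------------------------------------
# Multi-level combination comparisons
# ---------------------------------------------------------------------------


def _gene_classes_of_reactions(
    snap: DatabaseSnapshot, reaction_ids: set[str], gene_class_of: Mapping[EntityKey, EntityKey]
) -> set[EntityKey]:
    out: set[EntityKey] = set()
    for rid in reaction_ids:
        for g in snap.reactions[rid].genes:
            key = EntityKey(snap.name, g, "gene")
            if key in gene_class_of:  # genes without shared id are excluded
                out.add(gene_class_of[key])
    return out


def _ec_classes_of_reactions(
    snap: DatabaseSnapshot, reaction_ids: set[str], ec_class_of: Mapping[EntityKey, EntityKey]
) -> set[EntityKey]:
    out: set[EntityKey] = set()
    for rid in reaction_ids:
        for ec in snap.reactions[rid].ecs:
            key = EntityKey(snap.name, str(ec), "ec")
            if key in ec_class_of:  # partial ECs are excluded
                out.add(ec_class_of[key])
    return out


def combination_gene_ec(
    snapshots: Sequence[DatabaseSnapshot],
    gene_partition: MatchPartition,
    ec_partition: MatchPartition,
) -> dict:
    """Two-level agreement over the consensus genes: for each gene present in
    every snapshot, do the snapshots also agree on the EC number(s) the gene
    is connected to (via its reactions)? Buckets: all EC sets identical
    (``all_ec_agree``), a common EC exists (``at_least_one_ec``), none."""
    by_name = {s.name: s for s in snapshots}
    names = sorted(by_name)
    gene_sets = gene_partition.entity_sets()
    consensus_genes = set.intersection(*(gene_sets.get(n, set()) for n in names))
    ec_class_of = ec_partition.class_of()

    # gene class rep -> per snapshot set of member gene local_ids
    members: dict[EntityKey, dict[str, set[str]]] = {}
    gene_class_of = gene_partition.class_of()
    for key, rep in gene_class_of.items():
        if rep in consensus_genes:
            members.setdefault(rep, {}).setdefault(key.snapshot_name, set()).add(key.local_id)

    # reaction index: gene local_id -> reaction ids, per snapshot
    gene_to_reactions: dict[str, dict[str, set[str]]] = {n: {} for n in names}
    for name in names:
        for r in by_name[name].reactions.values():
            for g in r.genes:
                gene_to_reactions[name].setdefault(g, set()).add(r.local_id)

    all_agree = at_least_one = none_agree = 0
    for rep in sorted(consensus_genes):
        ec_sets = []
        for name in names:
            rids: set[str] = set()
            for g in members[rep].get(name, set()):
                rids |= gene_to_reactions[name].get(g, set())
            ec_sets.append(_ec_classes_of_reactions(by_name[name], rids, ec_class_of))
        first = ec_sets[0]
        if all(s == first for s in ec_sets) and first:
            all_agree += 1
        elif set.intersection(*ec_sets):
            at_least_one += 1
        else:
            none_agree += 1

    n_cons = len(consensus_genes)
    return {
        "consensus_genes": n_cons,
        "all_ec_agree": all_agree,
        "at_least_one_ec": all_agree + at_least_one,
        "no_common_ec": none_agree,
        "all_ec_agree_pct": round_half_up_pct(all_agree, n_cons) if n_cons else 0,
        "at_least_one_ec_pct": (
            round_half_up_pct(all_agree + at_least_one, n_cons) if n_cons else 0
        ),
    }


def combination_reaction_gene_ec(
    snapshots: Sequence[DatabaseSnapshot],
    reaction_partition: MatchPartition,
    gene_partition: MatchPartition,
    ec_partition: MatchPartition,
) -> dict:
    """Three-level agreement over the consensus reactions.

    For each reaction class present in every snapshot, a snapshot's gene/EC
    set is the union over that snapshot's member reactions of the class.
    Buckets (mutually exclusive on the gene/EC axes they describe):
    ``full_agreement`` — identical non-empty gene sets and identical non-empty
    EC sets everywhere; ``ec_only`` / ``gene_only`` — one level fully agrees,
    the other does not; ``no_common_ec`` / ``no_common_gene`` — empty
    intersection on that level. ``additional_genes`` tags classes where a
    common gene core exists but some snapshot links extra genes.
    """
    by_name = {s.name: s for s in snapshots}
    names = sorted(by_name)
    gene_class_of = gene_partition.class_of()
    ec_class_of = ec_partition.class_of()

    rxn_sets = reaction_partition.entity_sets()
    consensus_rxn = set.intersection(*(rxn_sets.get(n, set()) for n in names))

    # class rep -> per-snapshot member reaction local_ids
    members: dict[EntityKey, dict[str, set[str]]] = {}
    for cls in reaction_partition.classes:
        rep = min(cls)
        if rep in consensus_rxn:
            for m in cls:
                members.setdefault(rep, {}).setdefault(m.snapshot_name, set()).add(m.local_id)

    counts = {
        "consensus_reactions": len(consensus_rxn),
        "full_agreement": 0,
        "ec_only": 0,
        "gene_only": 0,
        "no_common_ec": 0,
        "no_common_gene": 0,
        "additional_genes": 0,
    }
    for rep in sorted(consensus_rxn):
        gene_sets, ec_sets = [], []
        for name in names:
            rids = members[rep].get(name, set())
            gene_sets.append(_gene_classes_of_reactions(by_name[name], rids, gene_class_of))
            ec_sets.append(_ec_classes_of_reactions(by_name[name], rids, ec_class_of))
        g0, e0 = gene_sets[0], ec_sets[0]
        gene_all = bool(g0) and all(s == g0 for s in gene_sets)
        ec_all = bool(e0) and all(s == e0 for s in ec_sets)
        gene_any = bool(set.intersection(*gene_sets))
        ec_any = bool(set.intersection(*ec_sets))
        if gene_all and ec_all:
            counts["full_agreement"] += 1
        elif ec_all:
            counts["ec_only"] += 1
        elif gene_all:
            counts["gene_only"] += 1
        if not ec_any:
            counts["no_common_ec"] += 1
        if not gene_any:
            counts["no_common_gene"] += 1
        if gene_any and not gene_all:
            counts["additional_genes"] += 1
    return counts


# ---------------------------------------------------------------------------
# Restricted (pathway- or category-scoped) comparisons
# ---------------------------------------------------------------------------


def _subset_snapshot(snap: DatabaseSnapshot, reaction_ids: set[str]) -> DatabaseSnapshot:
    """Sub-snapshot induced by a reaction subset: participating metabolites
    (plus instances of participating generics), linked genes, and the
    pathways those reactions belong to."""
    out = DatabaseSnapshot(name=snap.name)
    for rid in sorted(reaction_ids):
        out.reactions[rid] = snap.reactions[rid]
    met_ids: set[str] = set()
    for r in out.reactions.values():
        met_ids |= r.participants()
    for mid in sorted(met_ids):
        m = snap.metabolites[mid]
        met_ids_extra = [i for i in m.instance_ids if i in snap.metabolites]
        out.metabolites[mid] = m
        for inst in met_ids_extra:
            out.metabolites.setdefault(inst, snap.metabolites[inst])
    gene_ids = {g for r in out.reactions.values() for g in r.genes}
    for gid in sorted(gene_ids):
        out.genes[gid] = snap.genes[gid]
    pw_ids = {p for r in out.reactions.values() for p in r.pathways}
    for pid in sorted(pw_ids):
        out.pathways[pid] = snap.pathways[pid]
    return out


def restricted_compare(
    snapshots: Sequence[DatabaseSnapshot],
    scope: str | set[str],
    cfg: MatchConfig | None = None,
    *,
    pathway_aliases: Mapping[str, str] | None = None,
    majority_threshold: int = 3,
) -> dict:
    """Recompute all four entity-class comparisons on a subset.

    ``scope`` is either a pathway name (string; resolved against each
    snapshot's pathway names, with ``pathway_aliases`` mapping snapshot name →
    that snapshot's local pathway name when they differ) or a set of category
    labels (reactions carrying at least one of them are retained; categories
    must be assigned first).

    For a pathway scope, genes and EC numbers are additionally matched within
    matching reactions (per-reaction-class agreement via the three-level
    combination breakdown) next to the across-subset comparison.
    """
    cfg = cfg or MatchConfig()
    by_name = {s.name: s for s in snapshots}
    subsets: dict[str, DatabaseSnapshot] = {}

    if isinstance(scope, str):
        lacking = []
        for name, snap in sorted(by_name.items()):
            wanted = pathway_aliases.get(name, scope) if pathway_aliases else scope
            pw_ids = {p.local_id for p in snap.pathways.values() if p.name == wanted}
            rids = {
                r.local_id for r in snap.reactions.values() if r.pathways & pw_ids
            }
            if not rids:
                lacking.append(name)
            subsets[name] = _subset_snapshot(snap, rids)
        if lacking:
            raise ValueError(
                f"pathway scope {scope!r} empty in snapshots: {', '.join(lacking)}"
            )
    else:
        from .categories import reaction_categories

        for name, snap in sorted(by_name.items()):
            rids = {
                r.local_id
                for r in snap.reactions.values()
                if reaction_categories(r, snap) & scope
            }
            subsets[name] = _subset_snapshot(snap, rids)

    subs = [subsets[n] for n in sorted(subsets)]
    met_part = build_metabolite_partition(subs, cfg)
    rxn_part = build_reaction_partition(subs, met_part, cfg)
    gene_part = build_gene_partition(subs)
    ec_part = build_ec_partition(subs, level=4)

    results = {
        "genes": compare_partition(gene_part, majority_threshold),
        "ecs": compare_partition(ec_part, majority_threshold),
        "metabolites": compare_partition(met_part, majority_threshold),
        "reactions": compare_partition(rxn_part, majority_threshold),
        "within_reaction_agreement": combination_reaction_gene_ec(
            subs, rxn_part, gene_part, ec_part
        ),
        "partitions": {
            "metabolite": met_part,
            "reaction": rxn_part,
            "gene": gene_part,
            "ec": ec_part,
        },
        "subsets": subsets,
    }
    return results


def build_all_partitions(
    snapshots: Sequence[DatabaseSnapshot],
    cfg: MatchConfig | None = None,
    ec_level: int = 4,
) -> dict[str, MatchPartition]:
    """Metabolite, reaction, gene and EC partitions for one configuration."""
    cfg = cfg or MatchConfig()
    met = build_metabolite_partition(snapshots, cfg)
    return {
        "metabolite": met,
        "reaction": build_reaction_partition(snapshots, met, cfg),
        "gene": build_gene_partition(snapshots),
        "ec": build_ec_partition(snapshots, level=ec_level),
    }
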