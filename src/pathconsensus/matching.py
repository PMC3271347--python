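"""Entity resolution across database snapshots.

Identity is established per entity class:

* **metabolites** — a decision cascade: shared primary compound identifier
  (KEGG-Compound-style) first and *final* when both records carry one, then
  any agreeing secondary identifier (glycan/ChEBI/PubChem/CAS namespaces),
  then a shared normalized name backed by an equal chemical formula. Manual
  override pairs (the enzyme-bound/unbound lipoamide situation) force a match;
  a generic class placeholder never matches a specific compound. Pairwise
  matches are closed transitively: if A~B and B~C then A~C, even when the two
  matches used different routes.
* **reactions** — identical participant sets on both sides after mapping each
  participant to its metabolite equivalence class; direction, compartments and
  stoichiometric coefficients are ignored; a configurable ignore set (by
  default electrons, protons and water) removes ubiquitous species whose
  bookkeeping differs between databases.
* **genes** — identical shared-namespace gene identifiers.
* **EC numbers** — identical complete EC numbers (level 4) or identical
  three-component prefixes (level 3); partial EC numbers are excluded.

All outputs are :class:`MatchPartition` objects (disjoint equivalence classes
over :class:`EntityKey`), deterministic for a given input: class
representatives are the lexicographically smallest member and every
serialization is sorted.
"""

from __future__ import annotations

import re
import string
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from .datamodel import (
    ID_NAMESPACES,
    DatabaseSnapshot,
    MetaboliteRecord,
    ReactionRecord,
)

__all__ = [
    "EntityKey",
    "MatchConfig",
    "MatchPartition",
    "normalize_name",
    "parse_formula",
    "formulas_equal",
    "metabolites_match",
    "build_metabolite_partition",
    "reaction_signature",
    "ReactionSignature",
    "build_reaction_partition",
    "build_gene_partition",
    "build_ec_partition",
    "DEFAULT_IGNORE_KEGG_IDS",
]

SECONDARY_NAMESPACES = tuple(ns for ns in ID_NAMESPACES if ns != "kegg_compound")

#: Primary-namespace accessions for the default ignore set, so the canonical
#: labels resolve without relying on names.
DEFAULT_IGNORE_KEGG_IDS: dict[str, str] = {
    "e-": "C05359",
    "H+": "C00080",
    "H2O": "C00001",
}


class EntityKey(NamedTuple):
    """Globally unique handle of one entity within a comparison run."""

    snapshot_name: str
    local_id: str
    entity_class: str  # gene | ec | metabolite | reaction


@dataclass
class MatchConfig:
    """Tunable matching behaviour.

    ignore_metabolites
        Canonical labels of small ubiquitous species removed from both reaction
        sides before comparison. Default {e-, H+, H2O}; single-pathway case
        studies typically use {H+} only. Labels resolve to concrete
        metabolites via the primary compound identifier
        (:data:`DEFAULT_IGNORE_KEGG_IDS`) or via normalized name.
    h_tolerant_formula
        When true, the formula backing a name-based match disregards the H
        count, accommodating databases that store different protonation
        states.
    override_pairs
        Descriptor pairs forced to match regardless of the cascade. A
        descriptor is ``snapshot:local_id`` or ``namespace:identifier``
        (e.g. ``kegg_compound:C15972``).
    generic_specific_guard
        Never merge a generic class placeholder with a specific compound.
    name_requires_formula
        Name-based matches additionally require both formulas present and
        equal; missing data cannot satisfy the requirement.
    """

    ignore_metabolites: frozenset[str] = frozenset({"e-", "H+", "H2O"})
    h_tolerant_formula: bool = False
    override_pairs: tuple[tuple[str, str], ...] = ()
    generic_specific_guard: bool = True
    name_requires_formula: bool = True


# ---------------------------------------------------------------------------
# Name and formula normalisation
# ---------------------------------------------------------------------------

_PUNCT = set(string.punctuation)


def normalize_name(raw: str) -> str:
    """Canonicalize a metabolite name for comparison.

    Unicode compatibility normalization (so typographic dash/letter variants
    collide predictably), casefolded, with all whitespace and punctuation
    removed. No transliteration: a Greek alpha and the word "alpha" stay
    distinct.
    """
    s = unicodedata.normalize("NFKC", raw).casefold()
    out = []
    for ch in s:
        if ch in _PUNCT or ch.isspace():
            continue
        cat = unicodedata.category(ch)
        if cat[0] in ("P", "Z"):
            continue
        out.append(ch)
    return "".join(out)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int] | None:
    """Hill-style formula → element counts; None when unparseable."""
    counts: dict[str, int] = {}
    pos = 0
    text = formula.strip()
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or not m.group(1):
            return None
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    return counts or None


def formulas_equal(fa: str, fb: str, h_tolerant: bool = False) -> bool:
    ca, cb = parse_formula(fa), parse_formula(fb)
    if ca is None or cb is None:
        # unparseable formulas compare as raw strings
        return fa.strip() == fb.strip()
    if h_tolerant:
        ca = {k: v for k, v in ca.items() if k != "H"}
        cb = {k: v for k, v in cb.items() if k != "H"}
    return ca == cb


# ---------------------------------------------------------------------------
# Metabolite cascade
# ---------------------------------------------------------------------------


def _descriptor_matches(desc: str, snapshot_name: str, m: MetaboliteRecord) -> bool:
    ns, _, value = desc.partition(":")
    if not value:
        return False
    if ns in ID_NAMESPACES:
        return m.ids.get(ns) == value
    # otherwise a snapshot-scoped descriptor: snapshot:local_id
    return ns == snapshot_name and m.local_id == value


def _override_hit(
    cfg: MatchConfig,
    snap_a: str,
    a: MetaboliteRecord,
    snap_b: str,
    b: MetaboliteRecord,
) -> bool:
    for d1, d2 in cfg.override_pairs:
        if (_descriptor_matches(d1, snap_a, a) and _descriptor_matches(d2, snap_b, b)) or (
            _descriptor_matches(d2, snap_a, a) and _descriptor_matches(d1, snap_b, b)
        ):
            return True
    return False


def metabolites_match(
    a: MetaboliteRecord,
    b: MetaboliteRecord,
    cfg: MatchConfig | None = None,
    *,
    snapshot_a: str = "",
    snapshot_b: str = "",
    quarantined_names: frozenset[str] = frozenset(),
) -> tuple[bool, str | None]:
    """Decide whether two metabolite records denote the same compound.

    Returns ``(matched, route)`` where route is one of ``override``,
    ``kegg_compound``, ``secondary_id:<ns>``, ``name+formula`` or None.

    The cascade: override pairs first (hand-curated identity assertions beat
    everything, including the generic/specific guard); then the guard; then
    the primary compound identifier — when both records carry one, that
    comparison is final either way: a differing primary identifier blocks the
    match even if secondary identifiers agree. Otherwise any agreeing
    secondary identifier matches, and finally a shared normalized name backed
    by an equal formula (H count disregarded under ``h_tolerant_formula``).
    ``quarantined_names`` holds normalized names found ambiguous (mapped to
    more than one formula inside one snapshot); they never support a match.
    """
    cfg = cfg or MatchConfig()

    if cfg.override_pairs and _override_hit(cfg, snapshot_a, a, snapshot_b, b):
        return True, "override"

    if cfg.generic_specific_guard and a.is_generic != b.is_generic:
        return False, None

    ka, kb = a.ids.kegg_compound, b.ids.kegg_compound
    if ka is not None and kb is not None:
        # stop rule: the primary-namespace comparison is final
        return (ka == kb), ("kegg_compound" if ka == kb else None)

    for ns in SECONDARY_NAMESPACES:
        va, vb = a.ids.get(ns), b.ids.get(ns)
        if va is not None and vb is not None and va == vb:
            return True, f"secondary_id:{ns}"

    shared = (
        {normalize_name(n) for n in a.names} & {normalize_name(n) for n in b.names}
    ) - quarantined_names
    if shared:
        if cfg.name_requires_formula:
            if (
                a.formula is not None
                and b.formula is not None
                and formulas_equal(a.formula, b.formula, cfg.h_tolerant_formula)
            ):
                return True, "name+formula"
        else:
            return True, "name+formula"
    return False, None


# ---------------------------------------------------------------------------
# Union-find and partitions
# ---------------------------------------------------------------------------


class _DisjointSet:
    """Deterministic union-find over EntityKeys (union by smaller key)."""

    def __init__(self, members: Iterable[EntityKey]):
        self.parent: dict[EntityKey, EntityKey] = {m: m for m in members}

    def find(self, x: EntityKey) -> EntityKey:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: EntityKey, b: EntityKey) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if rb < ra:
            ra, rb = rb, ra
        self.parent[rb] = ra

    def classes(self) -> list[frozenset[EntityKey]]:
        groups: dict[EntityKey, set[EntityKey]] = {}
        for m in self.parent:
            groups.setdefault(self.find(m), set()).add(m)
        return [frozenset(groups[r]) for r in sorted(groups)]


@dataclass
class MatchPartition:
    """Equivalence classes over entities of all compared snapshots."""

    entity_class: str
    classes: list[frozenset[EntityKey]]
    #: (smaller key, larger key) -> route label for each direct pairwise match.
    evidence: dict[tuple[EntityKey, EntityKey], str] = field(default_factory=dict)
    #: reason -> entities excluded from comparison (reported, not compared).
    excluded: dict[str, list[EntityKey]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[EntityKey] = set()
        for cls in self.classes:
            if cls & seen:
                raise ValueError("partition classes are not disjoint")
            seen |= cls
        for (a, b), _route in self.evidence.items():
            if a.entity_class != b.entity_class:
                raise ValueError("evidence links different entity classes")

    def representative(self, cls: frozenset[EntityKey]) -> EntityKey:
        return min(cls)

    def class_of(self) -> dict[EntityKey, EntityKey]:
        """Member -> class representative."""
        return {m: min(cls) for cls in self.classes for m in cls}

    def entity_sets(self) -> dict[str, set[EntityKey]]:
        """Per-snapshot sets of class representatives (the ``C_i`` sets).

        Within-snapshot duplicates collapse automatically: a snapshot
        contributes one representative per class it participates in.
        """
        sets: dict[str, set[EntityKey]] = {}
        for cls in self.classes:
            rep = min(cls)
            for member in cls:
                sets.setdefault(member.snapshot_name, set()).add(rep)
        return sets


def _quarantined_names(snapshots: Sequence[DatabaseSnapshot]) -> frozenset[str]:
    """Normalized names that map to >1 distinct formula within one snapshot
    are ambiguous synonyms; they may not support name-based matches."""
    bad: set[str] = set()
    for snap in snapshots:
        seen: dict[str, set[str]] = {}
        for m in snap.metabolites.values():
            if m.formula is None:
                continue
            for n in m.names:
                seen.setdefault(normalize_name(n), set()).add(m.formula.strip())
        bad |= {name for name, formulas in seen.items() if len(formulas) > 1}
    return frozenset(bad)


def _candidate_pairs(
    keyed: list[tuple[EntityKey, str, MetaboliteRecord]],
) -> set[tuple[int, int]]:
    """Candidate index pairs via blocking on shared identifier values and
    normalized names. Sound for the cascade: any matching pair (other than
    overrides, handled separately) shares an identifier value or a name."""
    blocks: dict[tuple[str, str], list[int]] = {}
    for i, (_key, _snap, m) in enumerate(keyed):
        for ns, value in m.ids.present().items():
            blocks.setdefault((ns, value), []).append(i)
        for n in m.names:
            blocks.setdefault(("name", normalize_name(n)), []).append(i)
    pairs: set[tuple[int, int]] = set()
    for members in blocks.values():
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                pairs.add((members[x], members[y]))
    return pairs


def build_metabolite_partition(
    snapshots: Sequence[DatabaseSnapshot], cfg: MatchConfig | None = None
) -> MatchPartition:
    """All-pairs metabolite matching (across and within snapshots) closed
    transitively with a union-find; equivalent to connected components of the
    pairwise match graph."""
    cfg = cfg or MatchConfig()
    if len(snapshots) < 2:
        raise ValueError("need at least two snapshots to compare")
    quarantine = _quarantined_names(snapshots)

    keyed: list[tuple[EntityKey, str, MetaboliteRecord]] = []
    for snap in snapshots:
        for m in (snap.metabolites[k] for k in sorted(snap.metabolites)):
            keyed.append((EntityKey(snap.name, m.local_id, "metabolite"), snap.name, m))

    dsu = _DisjointSet(k for k, _, _ in keyed)
    evidence: dict[tuple[EntityKey, EntityKey], str] = {}

    def record(i: int, j: int) -> None:
        (ki, si, mi), (kj, sj, mj) = keyed[i], keyed[j]
        ok, route = metabolites_match(
            mi, mj, cfg, snapshot_a=si, snapshot_b=sj, quarantined_names=quarantine
        )
        if ok:
            dsu.union(ki, kj)
            pair = (ki, kj) if ki < kj else (kj, ki)
            evidence[pair] = route or "unknown"

    for i, j in sorted(_candidate_pairs(keyed)):
        record(i, j)

    if cfg.override_pairs:
        # overrides may link records sharing no identifier or name; check the
        # (rare) descriptor hits exhaustively against every other record
        hit = [
            i
            for i, (_k, s, m) in enumerate(keyed)
            if any(
                _descriptor_matches(d, s, m)
                for pair in cfg.override_pairs
                for d in pair
            )
        ]
        for i in hit:
            for j in range(len(keyed)):
                if i < j:
                    record(i, j)
                elif j < i:
                    record(j, i)

    return MatchPartition(entity_class="metabolite", classes=dsu.classes(), evidence=evidence)


# ---------------------------------------------------------------------------
# Reaction signatures and partition
# ---------------------------------------------------------------------------


class ReactionSignature(NamedTuple):
    sides: tuple[tuple[EntityKey, ...], tuple[EntityKey, ...]]
    degenerate: bool


def resolve_ignore_classes(
    partition: MatchPartition,
    snapshots: Sequence[DatabaseSnapshot],
    cfg: MatchConfig,
) -> frozenset[EntityKey]:
    """Class representatives of the configured ignore species.

    A label resolves to any metabolite whose primary compound identifier is
    the label's registered accession, or whose normalized name equals the
    normalized label; every class containing such a metabolite is ignored.
    """
    class_of = partition.class_of()
    wanted_ids = {
        DEFAULT_IGNORE_KEGG_IDS[lbl] for lbl in cfg.ignore_metabolites if lbl in DEFAULT_IGNORE_KEGG_IDS
    }
    wanted_names = {normalize_name(lbl) for lbl in cfg.ignore_metabolites}
    reps: set[EntityKey] = set()
    for snap in snapshots:
        for m in snap.metabolites.values():
            key = EntityKey(snap.name, m.local_id, "metabolite")
            if key not in class_of:
                continue
            if (m.ids.kegg_compound in wanted_ids) or (
                {normalize_name(n) for n in m.names} & wanted_names
            ):
                reps.add(class_of[key])
    return frozenset(reps)


def reaction_signature(
    r: ReactionRecord,
    snapshot_name: str,
    partition: MatchPartition,
    ignore_classes: frozenset[EntityKey] = frozenset(),
    class_of: Mapping[EntityKey, EntityKey] | None = None,
) -> ReactionSignature:
    """Canonical identity of a reaction: the unordered pair of its two sides,
    each side the set of metabolite-class representatives after removing
    ignored classes. Direction, compartments and coefficients do not
    participate. A signature whose sides coincide, or whose sides are both
    empty, after removal is degenerate (non-comparable: typically pure
    transport of an ignored species)."""
    if class_of is None:
        class_of = partition.class_of()

    def side_reps(side: Mapping[str, float]) -> tuple[EntityKey, ...]:
        reps = {
            class_of[EntityKey(snapshot_name, mid, "metabolite")] for mid in side
        }
        return tuple(sorted(reps - ignore_classes))

    sa, sb = side_reps(r.side_a), side_reps(r.side_b)
    if sb < sa:
        sa, sb = sb, sa
    degenerate = (sa == sb) or (not sa and not sb)
    return ReactionSignature(sides=(sa, sb), degenerate=degenerate)


def build_reaction_partition(
    snapshots: Sequence[DatabaseSnapshot],
    metabolite_partition: MatchPartition,
    cfg: MatchConfig | None = None,
) -> MatchPartition:
    """Group reactions by equal signatures (transitive closure is implied by
    signature equality). The same reaction written in two directions within
    one snapshot lands in one class and is counted once. Degenerate-signature
    reactions are excluded from statistics but listed under
    ``excluded['degenerate_signature']``."""
    cfg = cfg or MatchConfig()
    ignore = resolve_ignore_classes(metabolite_partition, snapshots, cfg)
    class_of = metabolite_partition.class_of()

    groups: dict[ReactionSignature, set[EntityKey]] = {}
    degenerate: list[EntityKey] = []
    evidence: dict[tuple[EntityKey, EntityKey], str] = {}
    for snap in snapshots:
        for r in (snap.reactions[k] for k in sorted(snap.reactions)):
            key = EntityKey(snap.name, r.local_id, "reaction")
            sig = reaction_signature(r, snap.name, metabolite_partition, ignore, class_of)
            if sig.degenerate:
                degenerate.append(key)
                continue
            groups.setdefault(sig, set()).add(key)

    classes = []
    for sig in sorted(groups, key=lambda s: s.sides):
        members = groups[sig]
        classes.append(frozenset(members))
        ordered = sorted(members)
        for a, b in zip(ordered, ordered[1:]):
            evidence[(a, b)] = "reaction_sides"

    return MatchPartition(
        entity_class="reaction",
        classes=classes,
        evidence=evidence,
        excluded={"degenerate_signature": sorted(degenerate)} if degenerate else {},
    )


# ---------------------------------------------------------------------------
# Gene and EC partitions
# ---------------------------------------------------------------------------


def build_gene_partition(snapshots: Sequence[DatabaseSnapshot]) -> MatchPartition:
    """Classes are groups sharing an identical gene identifier; records with
    no shared-namespace identifier are excluded and reported."""
    groups: dict[str, set[EntityKey]] = {}
    missing: list[EntityKey] = []
    evidence: dict[tuple[EntityKey, EntityKey], str] = {}
    for snap in snapshots:
        for g in (snap.genes[k] for k in sorted(snap.genes)):
            key = EntityKey(snap.name, g.local_id, "gene")
            if g.gene_id is None:
                missing.append(key)
            else:
                groups.setdefault(g.gene_id, set()).add(key)
    classes = []
    for gid in sorted(groups):
        members = sorted(groups[gid])
        classes.append(frozenset(members))
        for a, b in zip(members, members[1:]):
            evidence[(a, b)] = "identical_gene"
    return MatchPartition(
        entity_class="gene",
        classes=classes,
        evidence=evidence,
        excluded={"no_shared_identifier": sorted(missing)} if missing else {},
    )


def build_ec_partition(
    snapshots: Sequence[DatabaseSnapshot], level: int = 4
) -> MatchPartition:
    """Group identical complete EC numbers (level 4) or identical first-three
    prefixes (level 3). Partial EC numbers (1.1.1.-) are semantically
    ambiguous and excluded at either level.

    EC numbers have no records of their own in a snapshot; the compared
    entities are the distinct EC numbers referenced by the snapshot's
    reactions, keyed by their string form.
    """
    if level not in (3, 4):
        raise ValueError("EC comparison level must be 3 or 4")
    groups: dict[tuple, set[EntityKey]] = {}
    partial: list[EntityKey] = []
    evidence: dict[tuple[EntityKey, EntityKey], str] = {}
    for snap in snapshots:
        ecs = {ec for r in snap.reactions.values() for ec in r.ecs}
        for ec in sorted(ecs):
            key = EntityKey(snap.name, str(ec), "ec")
            if ec.is_partial:
                partial.append(key)
                continue
            group_key = ec.prefix3() if level == 3 else (ec.c1, ec.c2, ec.c3, ec.c4)
            groups.setdefault(group_key, set()).add(key)
    classes = []
    for gk in sorted(groups):
        members = sorted(groups[gk])
        classes.append(frozenset(members))
        for a, b in zip(members, members[1:]):
            evidence[(a, b)] = "identical_ec"
    return MatchPartition(
        entity_class="ec",
        classes=classes,
        evidence=evidence,
        excluded={"partial_ec": sorted(partial)} if partial else {},
    )
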