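"""Synthetic pathway-database generator with ground-truth bookkeeping.

Real pathway databases disagree for cataloged reasons: partial coverage,
missing or out-of-date identifiers, name spelling variants, protonation-state
differences, multi-step conversions lumped into net reactions, alternative
cosubstrates, generic class metabolites standing in for specific compounds,
direction conventions, and proton/water bookkeeping. This module builds a
random ground-truth metabolic network and derives K database snapshots from it
by applying each of those perturbations independently with configurable
probabilities, recording every transformation in a :class:`TruthLedger` so
recovery tests can compare what the matcher found against what is actually
true.

Everything is deterministic under the profile seed: the same
(truth, profile, name) triple yields a byte-identical snapshot.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datamodel import (
    DatabaseSnapshot,
    ECNumber,
    GeneRecord,
    IdentifierBundle,
    MetaboliteRecord,
    PathwayRecord,
    ReactionRecord,
    UpdateTables,
)
from .matching import EntityKey

__all__ = [
    "TruthMetabolite",
    "TruthReaction",
    "TruthPathway",
    "TruthRoute",
    "GroundTruth",
    "PerturbationProfile",
    "TruthLedger",
    "generate_ground_truth",
    "derive_snapshot",
    "true_overlap",
    "CURRENCY",
]


# ---------------------------------------------------------------------------
# Ground truth types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthMetabolite:
    truth_id: str
    names: tuple[str, ...]  # base name first, then synonyms
    formula: str | None
    charge: int
    compartment: str
    ids: IdentifierBundle
    is_generic: bool = False
    instance_ids: tuple[str, ...] = ()  # truth ids of class instances
    is_protein: bool = False
    is_currency: bool = False


@dataclass(frozen=True)
class TruthReaction:
    truth_id: str
    side_a: tuple[tuple[str, float], ...]  # (metabolite truth id, coefficient)
    side_b: tuple[tuple[str, float], ...]
    genes: tuple[str, ...]  # shared-namespace gene ids
    ecs: tuple[str, ...]
    pathway: str | None
    route_id: str | None = None  # member of a lumpable chain


@dataclass(frozen=True)
class TruthPathway:
    truth_id: str
    name: str
    category: str


@dataclass(frozen=True)
class TruthRoute:
    """A linear chain of reactions eligible for lumping into a net reaction."""

    route_id: str
    reaction_ids: tuple[str, ...]
    net_a: tuple[tuple[str, float], ...]
    net_b: tuple[tuple[str, float], ...]


@dataclass
class GroundTruth:
    uid: str
    metabolites: dict[str, TruthMetabolite]
    reactions: dict[str, TruthReaction]
    pathways: dict[str, TruthPathway]
    routes: list[TruthRoute]

    def category_mapping(self) -> dict[str, str]:
        """Pathway local_id -> category, for use with assign_categories."""
        return {pid: pw.category for pid, pw in self.pathways.items()}


# Currency metabolites use their real primary-namespace accessions so the
# default ignore-set resolution works unchanged on synthetic snapshots; all
# other synthetic accessions live in a C8xxxx/C9xxxx block.
CURRENCY: tuple[TruthMetabolite, ...] = (
    TruthMetabolite("cur_h2o", ("H2O", "water"), "H2O", 0, "c",
                    IdentifierBundle(kegg_compound="C00001"), is_currency=True),
    TruthMetabolite("cur_h", ("H+",), "H", 1, "c",
                    IdentifierBundle(kegg_compound="C00080"), is_currency=True),
    TruthMetabolite("cur_atp", ("ATP",), "C10H16N5O13P3", 0, "c",
                    IdentifierBundle(kegg_compound="C00002", chebi="15422"), is_currency=True),
    TruthMetabolite("cur_adp", ("ADP",), "C10H15N5O10P2", 0, "c",
                    IdentifierBundle(kegg_compound="C00008", chebi="16761"), is_currency=True),
    TruthMetabolite("cur_pi", ("phosphate", "Pi"), "H3PO4", 0, "c",
                    IdentifierBundle(kegg_compound="C00009"), is_currency=True),
    TruthMetabolite("cur_nad", ("NAD+",), "C21H28N7O14P2", 1, "c",
                    IdentifierBundle(kegg_compound="C00003"), is_currency=True),
    TruthMetabolite("cur_nadh", ("NADH",), "C21H29N7O14P2", 0, "c",
                    IdentifierBundle(kegg_compound="C00004"), is_currency=True),
    TruthMetabolite("cur_gtp", ("GTP",), "C10H16N5O14P3", 0, "c",
                    IdentifierBundle(kegg_compound="C00044"), is_currency=True),
    TruthMetabolite("cur_gdp", ("GDP",), "C10H15N5O11P2", 0, "c",
                    IdentifierBundle(kegg_compound="C00035"), is_currency=True),
)

#: Fixed alternative-cosubstrate mapping (ADP -> GDP style): which participants
#: get swapped when a database lists the same conversion with an alternative
#: nucleotide cosubstrate. Fixed, not sampled, so the alternative reaction has
#: one identity across snapshots.
ALT_COSUBSTRATE = {"cur_atp": "cur_gtp", "cur_adp": "cur_gdp"}

#: Bookkeeping species never perturbed at the metabolite level (a database
#: that cannot recognise water is not a database worth emulating).
_EXEMPT = {"cur_h2o", "cur_h"}

_CATEGORY_CYCLE = (
    "carbohydrate metabolism",
    "amino acid metabolism",
    "energy metabolism",
    "lipid metabolism",
    "nucleotide metabolism",
    "metabolism of cofactors and vitamins",
    "glycan biosynthesis and metabolism",
    "miscellaneous",
)


def _rng_for(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(label.encode()) % (2**31)])


# ---------------------------------------------------------------------------
# Ground truth generation
# ---------------------------------------------------------------------------


def generate_ground_truth(
    n_reactions: int,
    n_pathways: int = 5,
    seed: int = 0,
    *,
    frac_transport: float = 0.0,
    frac_macromolecular: float = 0.0,
    n_generic_classes: int | None = None,
) -> GroundTruth:
    """Random bipartite metabolite–reaction network with shared currency
    metabolites, pathway assignments, and ≥1 lumpable three-step chain per 20
    reactions.

    Core metabolites carry a full identifier bundle, a unique name (plus a
    recoverable synonym and an unrecoverable "hard" synonym pool entry), and a
    formula; relaxed reaction signatures are unique by construction so the
    perturbation machinery, not the generator, is the only source of
    ambiguity. ``frac_transport``/``frac_macromolecular`` optionally add
    cross-compartment and protein-participant reactions for the
    categorization filters (off by default).
    """
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    rng = _rng_for(seed, "ground-truth")

    metabolites: dict[str, TruthMetabolite] = {m.truth_id: m for m in CURRENCY}
    n_core = max(8, int(n_reactions * 1.6))
    core_ids: list[str] = []
    for i in range(n_core):
        tid = f"met{i:04d}"
        core_ids.append(tid)
        formula = "C{}H{}N{}O{}".format(
            int(rng.integers(2, 30)),
            int(rng.integers(4, 50)),
            int(rng.integers(0, 5)),
            int(rng.integers(1, 10)),
        )
        metabolites[tid] = TruthMetabolite(
            truth_id=tid,
            names=(f"compound {i:04d}", f"cpd {i:04d} alt"),
            formula=formula,
            charge=0,
            compartment="c",
            ids=IdentifierBundle(
                kegg_compound=f"C9{i:04d}"[:6],
                chebi=str(90000 + i),
                pubchem_compound=str(80000 + i),
                cas=f"{1000 + i}-{10 + i % 80:02d}-{i % 10}",
            ),
        )

    n_classes = (
        n_generic_classes if n_generic_classes is not None else max(1, n_core // 15)
    )
    class_ids: list[str] = []
    pool = core_ids.copy()
    for j in range(min(n_classes, len(pool) // 3)):
        members = tuple(pool[j * 3 : j * 3 + 3])
        cid = f"cls{j:03d}"
        class_ids.append(cid)
        metabolites[cid] = TruthMetabolite(
            truth_id=cid,
            names=(f"a class-{j:03d} compound",),
            formula=None,
            charge=0,
            compartment="c",
            ids=IdentifierBundle(kegg_compound=f"C8{9000 + j:04d}"),
            is_generic=True,
            instance_ids=members,
        )

    pathways = {
        f"pw{j:03d}": TruthPathway(
            f"pw{j:03d}", f"pathway {j:03d}", _CATEGORY_CYCLE[j % len(_CATEGORY_CYCLE)]
        )
        for j in range(max(1, n_pathways))
    }
    pathway_ids = sorted(pathways)
    transport_pw = None
    if frac_transport > 0:
        transport_pw = "pw_transport"
        pathways[transport_pw] = TruthPathway(transport_pw, "transport", "transport")

    n_genes = max(5, (n_reactions * 2) // 3)
    gene_pool = [str(1000 + i) for i in range(n_genes)]

    reactions: dict[str, TruthReaction] = {}
    routes: list[TruthRoute] = []
    seen_signatures: set[frozenset] = set()

    def relaxed_signature(
        side_a: Iterable[tuple[str, float]], side_b: Iterable[tuple[str, float]]
    ) -> frozenset:
        strip = {"cur_h2o", "cur_h"}
        sa = frozenset(m for m, _ in side_a if m not in strip)
        sb = frozenset(m for m, _ in side_b if m not in strip)
        return frozenset((sa, sb))

    def draw_ec() -> str:
        return "{}.{}.{}.{}".format(
            int(rng.integers(1, 7)),
            int(rng.integers(1, 15)),
            int(rng.integers(1, 15)),
            int(rng.integers(1, 200)),
        )

    def draw_genes() -> tuple[str, ...]:
        k = int(rng.integers(1, 4))
        return tuple(sorted(rng.choice(gene_pool, size=min(k, len(gene_pool)), replace=False)))

    rxn_index = 0
    n_routes = max(1, n_reactions // 20)
    inter_index = 0

    # Lumpable chains first: S -> I1 -> I2 -> P with dedicated intermediates.
    for ridx in range(n_routes):
        if rxn_index + 3 > n_reactions:
            break
        s, p = rng.choice(core_ids, size=2, replace=False)
        inters = []
        for _ in range(2):
            tid = f"int{inter_index:04d}"
            inter_index += 1
            metabolites[tid] = TruthMetabolite(
                truth_id=tid,
                names=(f"intermediate {tid}",),
                formula=f"C{5 + inter_index}H{8 + inter_index}O{2 + inter_index % 5}",
                charge=0,
                compartment="c",
                ids=IdentifierBundle(kegg_compound=f"C7{inter_index:04d}"[:6]),
            )
            inters.append(tid)
        chain = [s, inters[0], inters[1], p]
        route_id = f"route{ridx:03d}"
        member_ids = []
        for k in range(3):
            rid = f"rxn{rxn_index:04d}"
            rxn_index += 1
            member_ids.append(rid)
            sa = ((chain[k], 1.0),)
            sb = ((chain[k + 1], 1.0),)
            seen_signatures.add(relaxed_signature(sa, sb))
            reactions[rid] = TruthReaction(
                truth_id=rid,
                side_a=sa,
                side_b=sb,
                genes=draw_genes(),
                ecs=(draw_ec(),),
                pathway=pathway_ids[rxn_index % len(pathway_ids)],
                route_id=route_id,
            )
        net_sig = relaxed_signature(((s, 1.0),), ((p, 1.0),))
        seen_signatures.add(net_sig)
        routes.append(
            TruthRoute(route_id, tuple(member_ids), ((s, 1.0),), ((p, 1.0),))
        )

    n_transport = int(round(frac_transport * n_reactions))
    n_macro = int(round(frac_macromolecular * n_reactions))

    # Remaining ordinary reactions.
    while rxn_index < n_reactions - n_transport - n_macro:
        for _attempt in range(200):
            n_sub = int(rng.integers(1, 3))
            n_prod = int(rng.integers(1, 3))
            chosen = rng.choice(core_ids, size=n_sub + n_prod, replace=False)
            subs = [(str(m), 1.0) for m in chosen[:n_sub]]
            prods = [(str(m), 1.0) for m in chosen[n_sub:]]
            u = rng.random()
            if u < 0.35:
                subs += [("cur_atp", 1.0), ("cur_h2o", 1.0)]
                prods += [("cur_adp", 1.0), ("cur_pi", 1.0), ("cur_h", 1.0)]
            elif u < 0.65:
                subs += [("cur_nad", 1.0)]
                prods += [("cur_nadh", 1.0), ("cur_h", 1.0)]
            sig = relaxed_signature(subs, prods)
            if sig in seen_signatures:
                continue
            seen_signatures.add(sig)
            rid = f"rxn{rxn_index:04d}"
            reactions[rid] = TruthReaction(
                truth_id=rid,
                side_a=tuple(sorted(subs)),
                side_b=tuple(sorted(prods)),
                genes=draw_genes(),
                ecs=(draw_ec(),),
                pathway=pathway_ids[rxn_index % len(pathway_ids)],
            )
            rxn_index += 1
            break
        else:
            raise RuntimeError("could not draw a unique reaction; pool too small")

    # Transport reactions: same compound in two compartments.
    for t in range(n_transport):
        src = str(rng.choice(core_ids))
        mito_id = f"{src}_m"
        if mito_id not in metabolites:
            base = metabolites[src]
            metabolites[mito_id] = replace(
                base, truth_id=mito_id, compartment="m"
            )
        rid = f"rxn{rxn_index:04d}"
        rxn_index += 1
        reactions[rid] = TruthReaction(
            truth_id=rid,
            side_a=((src, 1.0),),
            side_b=((mito_id, 1.0),),
            genes=draw_genes(),
            ecs=(),
            pathway=transport_pw,
        )

    # Macromolecular reactions: one protein participant.
    for t in range(n_macro):
        prot_id = f"prot{t:03d}"
        metabolites[prot_id] = TruthMetabolite(
            truth_id=prot_id,
            names=(f"protein {t:03d}",),
            formula=None,
            charge=0,
            compartment="c",
            ids=IdentifierBundle(),
            is_protein=True,
        )
        other = str(rng.choice(core_ids))
        rid = f"rxn{rxn_index:04d}"
        rxn_index += 1
        reactions[rid] = TruthReaction(
            truth_id=rid,
            side_a=((prot_id, 1.0), ("cur_atp", 1.0)),
            side_b=((other, 1.0), ("cur_adp", 1.0)),
            genes=draw_genes(),
            ecs=(draw_ec(),),
            pathway=pathway_ids[rxn_index % len(pathway_ids)],
        )

    return GroundTruth(
        uid=f"gt-{seed}-{n_reactions}-{n_pathways}",
        metabolites=metabolites,
        reactions=reactions,
        pathways=pathways,
        routes=routes,
    )


# ---------------------------------------------------------------------------
# Perturbation profiles
# ---------------------------------------------------------------------------


@dataclass
class PerturbationProfile:
    """Per-entity perturbation probabilities for deriving one snapshot.

    ``p_id_drop`` is either one probability applied to every identifier
    namespace (including the gene namespace) or a per-namespace mapping.
    All probabilities in [0, 1]; the same seed yields a byte-identical
    snapshot.
    """

    p_cov: float = 1.0
    p_id_drop: float | Mapping[str, float] = 0.0
    p_name_variant: float = 0.0
    p_proton_shift: float = 0.0
    p_lump: float = 0.0
    p_alt_substrate: float = 0.0
    p_generic: float = 0.0
    p_obsolete_inject: float = 0.0
    p_flip_direction: float = 0.0
    p_balance_h2o_hplus: float = 0.0
    drop_pathway_assignment: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.p_cov, self.p_name_variant, self.p_proton_shift, self.p_lump,
            self.p_alt_substrate, self.p_generic, self.p_obsolete_inject,
            self.p_flip_direction, self.p_balance_h2o_hplus,
            self.drop_pathway_assignment,
        ]
        if isinstance(self.p_id_drop, Mapping):
            probs.extend(self.p_id_drop.values())
        else:
            probs.append(self.p_id_drop)
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0,1]: {p}")

    def id_drop(self, namespace: str) -> float:
        if isinstance(self.p_id_drop, Mapping):
            return float(self.p_id_drop.get(namespace, 0.0))
        return float(self.p_id_drop)

    def to_dict(self) -> dict:
        d = {
            "p_cov": self.p_cov,
            "p_id_drop": (
                dict(self.p_id_drop) if isinstance(self.p_id_drop, Mapping) else self.p_id_drop
            ),
            "p_name_variant": self.p_name_variant,
            "p_proton_shift": self.p_proton_shift,
            "p_lump": self.p_lump,
            "p_alt_substrate": self.p_alt_substrate,
            "p_generic": self.p_generic,
            "p_obsolete_inject": self.p_obsolete_inject,
            "p_flip_direction": self.p_flip_direction,
            "p_balance_h2o_hplus": self.p_balance_h2o_hplus,
            "drop_pathway_assignment": self.drop_pathway_assignment,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PerturbationProfile":
        return cls(**dict(d))


@dataclass
class TruthLedger:
    """What each emitted entity really is, and what happened to it."""

    ground_truth_uid: str
    snapshot_name: str
    #: EntityKey -> truth id (route id for lumped reactions).
    entity_map: dict[EntityKey, str] = field(default_factory=dict)
    #: EntityKey -> perturbation tags applied to that entity.
    tags: dict[EntityKey, tuple[str, ...]] = field(default_factory=dict)
    #: transfer/obsolete tables produced by obsolete-identifier injection;
    #: applying them with apply_identifier_updates reverses the injection.
    update_tables: UpdateTables = field(default_factory=UpdateTables)


# ---------------------------------------------------------------------------
# Snapshot derivation
# ---------------------------------------------------------------------------


def derive_snapshot(
    truth: GroundTruth, profile: PerturbationProfile, name: str
) -> tuple[DatabaseSnapshot, TruthLedger]:
    """Derive one database snapshot from the ground truth under a profile.

    Each perturbation applies independently per eligible entity with its
    stated probability; the ledger records the truth id and tags of every
    emitted entity. The output passes snapshot validation.
    """
    rng = _rng_for(profile.seed, f"snapshot:{name}")
    ledger = TruthLedger(ground_truth_uid=truth.uid, snapshot_name=name)
    transferred: dict[str, dict[str, str]] = {}
    obsolete: dict[str, set[str]] = {}
    obsolete_counter = 0

    # ---- reaction selection -------------------------------------------------
    selected: list[tuple[str, TruthReaction, list[str]]] = []  # (emit id, rxn, tags)
    route_by_member = {rid: rt for rt in truth.routes for rid in rt.reaction_ids}
    lumped_routes: set[str] = set()
    for rt in sorted(truth.routes, key=lambda r: r.route_id):
        if rng.random() < profile.p_lump:
            lumped_routes.add(rt.route_id)
            net = TruthReaction(
                truth_id=rt.route_id,
                side_a=rt.net_a,
                side_b=rt.net_b,
                genes=tuple(
                    sorted({g for rid in rt.reaction_ids for g in truth.reactions[rid].genes})
                ),
                ecs=tuple(
                    sorted({e for rid in rt.reaction_ids for e in truth.reactions[rid].ecs})
                ),
                pathway=truth.reactions[rt.reaction_ids[0]].pathway,
            )
            selected.append((rt.route_id, net, ["lumped"]))

    for rid in sorted(truth.reactions):
        rxn = truth.reactions[rid]
        if rxn.route_id in lumped_routes:
            continue
        if rng.random() < profile.p_cov:
            selected.append((rid, rxn, []))

    # ---- per-reaction transforms -------------------------------------------
    instance_to_class: dict[str, str] = {}
    for m in truth.metabolites.values():
        if m.is_generic:
            for inst in m.instance_ids:
                instance_to_class.setdefault(inst, m.truth_id)

    emitted_reactions: list[tuple[str, TruthReaction, list[str]]] = []
    for emit_id, rxn, tags in selected:
        side_a = dict(rxn.side_a)
        side_b = dict(rxn.side_b)

        if profile.p_generic and rng.random() < profile.p_generic:
            eligible = sorted(
                m for m in (*side_a, *side_b) if m in instance_to_class
            )
            if eligible:
                target = eligible[0]
                cls = instance_to_class[target]
                for side in (side_a, side_b):
                    if target in side:
                        side[cls] = side.pop(target)
                tags = tags + ["generic_substitution"]

        if profile.p_flip_direction and rng.random() < profile.p_flip_direction:
            side_a, side_b = side_b, side_a
            tags = tags + ["direction_flip"]

        if profile.p_balance_h2o_hplus and rng.random() < profile.p_balance_h2o_hplus:
            species = "cur_h" if rng.random() < 0.5 else "cur_h2o"
            side = side_a if rng.random() < 0.5 else side_b
            if species in side:
                del side[species]
                tags = tags + [f"balance_removed:{species}"]
            else:
                side[species] = 1.0
                tags = tags + [f"balance_added:{species}"]

        pathway = rxn.pathway
        if profile.drop_pathway_assignment and rng.random() < profile.drop_pathway_assignment:
            pathway = None
            tags = tags + ["pathway_dropped"]

        emitted = TruthReaction(
            truth_id=rxn.truth_id,
            side_a=tuple(sorted(side_a.items())),
            side_b=tuple(sorted(side_b.items())),
            genes=rxn.genes,
            ecs=rxn.ecs,
            pathway=pathway,
            route_id=rxn.route_id,
        )
        emitted_reactions.append((emit_id, emitted, tags))

        if profile.p_alt_substrate and rng.random() < profile.p_alt_substrate:
            if any(m in ALT_COSUBSTRATE for m in (*side_a, *side_b)):
                alt_a = {ALT_COSUBSTRATE.get(m, m): c for m, c in side_a.items()}
                alt_b = {ALT_COSUBSTRATE.get(m, m): c for m, c in side_b.items()}
                emitted_reactions.append(
                    (
                        f"{emit_id}_alt",
                        TruthReaction(
                            truth_id=f"{rxn.truth_id}::alt",
                            side_a=tuple(sorted(alt_a.items())),
                            side_b=tuple(sorted(alt_b.items())),
                            genes=rxn.genes,
                            ecs=rxn.ecs,
                            pathway=pathway,
                        ),
                        tags + ["alt_cosubstrate"],
                    )
                )

    # ---- metabolite emission ------------------------------------------------
    needed: set[str] = set()
    for _eid, rxn, _tags in emitted_reactions:
        needed.update(m for m, _ in rxn.side_a)
        needed.update(m for m, _ in rxn.side_b)
    for tid in sorted(needed):
        m = truth.metabolites[tid]
        if m.is_generic:
            needed = needed | set(m.instance_ids)

    snapshot = DatabaseSnapshot(name=name)

    for tid in sorted(needed):
        m = truth.metabolites[tid]
        tags: list[str] = []
        names = list(m.names)
        formula = m.formula
        bundle = m.ids.present()
        exempt = m.truth_id in _EXEMPT

        if not exempt:
            if profile.p_name_variant and rng.random() < profile.p_name_variant:
                base = m.names[0]
                u = rng.random()
                if u < 0.4:
                    names = [base.upper().replace(" ", "-")]
                    tags.append("name_variant:recoverable")
                elif u < 0.7 and len(m.names) > 1:
                    names = [m.names[1].title()]
                    tags.append("name_variant:synonym")
                else:
                    names = [f"trivial name {zlib.crc32((name + tid).encode()) % 10**6}"]
                    tags.append("name_variant:hard")

            if profile.p_proton_shift and formula and rng.random() < profile.p_proton_shift:
                from .matching import parse_formula

                counts = parse_formula(formula)
                if counts is not None:
                    delta = 1 if rng.random() < 0.5 else -1
                    h = max(0, counts.get("H", 0) + delta)
                    counts["H"] = h
                    formula = "".join(
                        f"{el}{n if n != 1 else ''}"
                        for el, n in sorted(counts.items())
                        if n > 0
                    )
                    names = names + [f"{names[0]} ({'1-' if delta < 0 else '1+'})"]
                    tags.append("proton_shift")

            for ns in ("kegg_compound", "kegg_glycan", "chebi", "pubchem_compound", "cas"):
                if ns in bundle and rng.random() < profile.id_drop(ns):
                    del bundle[ns]
                    tags.append(f"id_dropped:{ns}")

            if (
                profile.p_obsolete_inject
                and "kegg_compound" in bundle
                and rng.random() < profile.p_obsolete_inject
            ):
                old = f"C6{obsolete_counter:04d}"
                obsolete_counter += 1
                if rng.random() < 0.5:
                    transferred.setdefault("kegg_compound", {})[old] = bundle["kegg_compound"]
                    tags.append("obsolete_injected:transferred")
                else:
                    obsolete.setdefault("kegg_compound", set()).add(old)
                    tags.append("obsolete_injected:obsolete")
                bundle["kegg_compound"] = old

        rec = MetaboliteRecord(
            local_id=tid,
            names=tuple(names),
            formula=formula,
            charge=m.charge,
            compartment=m.compartment,
            ids=IdentifierBundle(**bundle),
            is_generic=m.is_generic,
            instance_ids=tuple(i for i in m.instance_ids if i in needed),
            is_protein=m.is_protein,
        )
        snapshot.metabolites[tid] = rec
        key = EntityKey(name, tid, "metabolite")
        ledger.entity_map[key] = m.truth_id
        if tags:
            ledger.tags[key] = tuple(tags)

    # ---- genes ---------------------------------------------------------------
    needed_genes = sorted({g for _eid, rxn, _t in emitted_reactions for g in rxn.genes})
    gene_drop = profile.id_drop("gene")
    for gid in needed_genes:
        local = f"g{gid}"
        tags = []
        value: str | None = gid
        if gene_drop and rng.random() < gene_drop:
            value = None
            tags.append("id_dropped:gene")
        elif profile.p_obsolete_inject and rng.random() < profile.p_obsolete_inject:
            old = str(900000 + obsolete_counter)
            obsolete_counter += 1
            if rng.random() < 0.5:
                transferred.setdefault("gene", {})[old] = gid
                tags.append("obsolete_injected:transferred")
            else:
                obsolete.setdefault("gene", set()).add(old)
                tags.append("obsolete_injected:obsolete")
            value = old
        snapshot.genes[local] = GeneRecord(local_id=local, gene_id=value)
        key = EntityKey(name, local, "gene")
        ledger.entity_map[key] = gid
        if tags:
            ledger.tags[key] = tuple(tags)

    # ---- pathways and reactions ---------------------------------------------
    needed_pw = sorted(
        {rxn.pathway for _e, rxn, _t in emitted_reactions if rxn.pathway is not None}
    )
    for pid in needed_pw:
        pw = truth.pathways[pid]
        snapshot.pathways[pid] = PathwayRecord(
            local_id=pid, name=pw.name, category=pw.category
        )

    for emit_id, rxn, tags in emitted_reactions:
        rec = ReactionRecord(
            local_id=emit_id,
            side_a=dict(rxn.side_a),
            side_b=dict(rxn.side_b),
            reversible_hint=None,
            genes=frozenset(f"g{g}" for g in rxn.genes),
            ecs=frozenset(ECNumber.parse(e) for e in rxn.ecs),
            pathways=frozenset() if rxn.pathway is None else frozenset({rxn.pathway}),
            is_set_reaction=any(
                truth.metabolites[m].is_generic
                for m, _ in (*rxn.side_a, *rxn.side_b)
            ),
        )
        snapshot.reactions[emit_id] = rec
        key = EntityKey(name, emit_id, "reaction")
        ledger.entity_map[key] = rxn.truth_id
        if tags:
            ledger.tags[key] = tuple(tags)

    ledger.update_tables = UpdateTables(transferred=transferred, obsolete=obsolete)
    return snapshot, ledger


# ---------------------------------------------------------------------------
# Truth oracle
# ---------------------------------------------------------------------------


def true_overlap(
    ledgers: Sequence[TruthLedger], entity_class: str
) -> dict[str, set[str]]:
    """Ground-truth membership sets (snapshot name -> truth ids), enabling
    expected-consensus computation independent of the matcher."""
    uids = {lg.ground_truth_uid for lg in ledgers}
    if len(uids) > 1:
        raise ValueError(f"ledgers come from different ground truths: {sorted(uids)}")
    out: dict[str, set[str]] = {}
    for lg in ledgers:
        s = out.setdefault(lg.snapshot_name, set())
        for key, tid in lg.entity_map.items():
            if key.entity_class == entity_class:
                s.add(tid)
    return out
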