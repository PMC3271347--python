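"""Domain types and interchange I/O for metabolic pathway database snapshots.

A *snapshot* is one pathway database's content at a point in time: genes,
metabolites (with their identifier bundles), reactions, and pathways. All
snapshots live in a small JSON interchange format defined here (a TSV bundle
dialect is accepted for hand-authored fixtures); importing vendor formats such
as SBML or BioPAX is explicitly out of scope and refused with a pointer to the
interchange format.

The module also implements the two content-normalisation steps that precede
any comparison: replacing out-of-date identifiers using transfer/obsolete
tables, and instantiating reactions that operate on *sets* of metabolites
(generic class participants) by positional first-member pairing.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "SCHEMA_VERSION",
    "ID_NAMESPACES",
    "DEFAULT_ID_PATTERNS",
    "InterchangeError",
    "SnapshotValidationError",
    "IdentifierBundle",
    "MetaboliteRecord",
    "GeneRecord",
    "ECNumber",
    "ReactionRecord",
    "PathwayRecord",
    "DatabaseSnapshot",
    "UpdateTables",
    "UpdateSummary",
    "load_snapshot",
    "write_snapshot",
    "validate_snapshot",
    "load_update_tables",
    "apply_identifier_updates",
    "expand_generic_reactions",
]

SCHEMA_VERSION = "1.0"

#: Metabolite identifier namespaces, in cascade priority order. The first is
#: the primary namespace (its comparison is a stop rule in matching); the rest
#: are secondary.
ID_NAMESPACES = ("kegg_compound", "kegg_glycan", "chebi", "pubchem_compound", "cas")

#: Syntax patterns per namespace. Configurable: pass an ``id_patterns`` mapping
#: to :func:`validate_snapshot` / :func:`load_snapshot` to override.
DEFAULT_ID_PATTERNS: dict[str, str] = {
    "kegg_compound": r"C\d{5}",
    "kegg_glycan": r"G\d{5}",
    "chebi": r"(CHEBI:)?\d+",
    "pubchem_compound": r"\d+",
    "cas": r"\d{2,7}-\d{2}-\d",
    "gene": r"\d+",
}

_VENDOR_EXTENSIONS = {".xml", ".sbml", ".owl", ".biopax"}


class InterchangeError(ValueError):
    """Malformed interchange file (parse failure, wrong schema, bad field)."""


class SnapshotValidationError(ValueError):
    """A structurally parseable snapshot violates an integrity invariant."""

    def __init__(self, messages: list[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IdentifierBundle:
    """Cross-reference identifiers of one metabolite.

    Any subset of the five namespaces may be present; a fully empty bundle is
    legal (the metabolite can still be compared by name + formula).
    """

    kegg_compound: str | None = None
    kegg_glycan: str | None = None
    chebi: str | None = None
    pubchem_compound: str | None = None
    cas: str | None = None

    def get(self, namespace: str) -> str | None:
        return getattr(self, namespace)

    def present(self) -> dict[str, str]:
        """Namespace -> identifier for the identifiers that are present."""
        return {ns: v for ns in ID_NAMESPACES if (v := getattr(self, ns)) is not None}

    def is_empty(self) -> bool:
        return not self.present()


@dataclass(frozen=True)
class GeneRecord:
    local_id: str
    #: Shared-namespace (Entrez-style) gene identifier; absent genes are
    #: excluded from comparison and reported separately.
    gene_id: str | None = None


@dataclass(frozen=True)
class ECNumber:
    """Enzyme Commission number; ``c4 is None`` marks a partial EC (1.1.1.-).

    Partial EC numbers are semantically ambiguous and excluded from
    comparisons, but they are representable so snapshots can carry them.
    """

    c1: int
    c2: int
    c3: int
    c4: int | None = None

    def __post_init__(self) -> None:
        for c in (self.c1, self.c2, self.c3):
            if c < 1:
                raise ValueError(f"EC components must be positive: {self}")
        if self.c4 is not None and self.c4 < 1:
            raise ValueError(f"EC serial must be positive: {self}")

    def __lt__(self, other: "ECNumber") -> bool:
        # partial ECs (no serial) sort before complete ones in their subclass
        key = (self.c1, self.c2, self.c3, self.c4 is not None, self.c4 or 0)
        other_key = (other.c1, other.c2, other.c3, other.c4 is not None, other.c4 or 0)
        return key < other_key

    @property
    def is_partial(self) -> bool:
        return self.c4 is None

    def prefix3(self) -> tuple[int, int, int]:
        return (self.c1, self.c2, self.c3)

    def __str__(self) -> str:
        tail = "-" if self.c4 is None else str(self.c4)
        return f"{self.c1}.{self.c2}.{self.c3}.{tail}"

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        parts = text.strip().split(".")
        if len(parts) != 4:
            raise InterchangeError(f"not an EC number: {text!r}")
        try:
            c1, c2, c3 = (int(p) for p in parts[:3])
            c4 = None if parts[3] in ("-", "") else int(parts[3])
        except ValueError as exc:
            raise InterchangeError(f"not an EC number: {text!r}") from exc
        return cls(c1, c2, c3, c4)


@dataclass(frozen=True)
class MetaboliteRecord:
    local_id: str
    names: tuple[str, ...]
    formula: str | None = None
    charge: int | None = None
    compartment: str | None = None
    ids: IdentifierBundle = field(default_factory=IdentifierBundle)
    #: Class placeholder such as "an alcohol"; never matched to a specific
    #: compound (see the generic/specific guard in matching).
    is_generic: bool = False
    #: Specific instances of a generic class (local_ids within the snapshot).
    instance_ids: tuple[str, ...] = ()
    #: Macromolecule flag used by the core-subset filter.
    is_protein: bool = False


@dataclass(frozen=True)
class ReactionRecord:
    local_id: str
    #: Unordered reaction sides: metabolite local_id -> stoichiometric
    #: coefficient. Coefficients are stored but ignored in matching.
    side_a: Mapping[str, float]
    side_b: Mapping[str, float]
    reversible_hint: bool | None = None
    genes: frozenset[str] = frozenset()
    ecs: frozenset[ECNumber] = frozenset()
    pathways: frozenset[str] = frozenset()
    #: True when a side contains generic/set participants.
    is_set_reaction: bool = False

    def participants(self) -> frozenset[str]:
        return frozenset(self.side_a) | frozenset(self.side_b)


@dataclass(frozen=True)
class PathwayRecord:
    local_id: str
    name: str
    category: str | None = None


@dataclass
class DatabaseSnapshot:
    """One pathway database's content, keyed by local identifier."""

    name: str
    genes: dict[str, GeneRecord] = field(default_factory=dict)
    metabolites: dict[str, MetaboliteRecord] = field(default_factory=dict)
    reactions: dict[str, ReactionRecord] = field(default_factory=dict)
    pathways: dict[str, PathwayRecord] = field(default_factory=dict)
    #: Reactions whose set instantiation failed (positional pairing
    #: ill-defined); populated by expand_generic_reactions.
    uninstantiable: tuple[str, ...] = ()

    def counts(self) -> tuple[int, int, int, int]:
        return (
            len(self.genes),
            len(self.metabolites),
            len(self.reactions),
            len(self.pathways),
        )


@dataclass
class UpdateTables:
    """Identifier transfer maps and obsolete sets, per namespace.

    ``transferred`` maps must be pre-flattened (values never appear as keys),
    which makes :func:`apply_identifier_updates` idempotent.
    """

    transferred: dict[str, dict[str, str]] = field(default_factory=dict)
    obsolete: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ns, table in self.transferred.items():
            clash = set(table) & self.obsolete.get(ns, set())
            if clash:
                raise ValueError(
                    f"namespace {ns!r}: identifiers both transferred and "
                    f"obsolete: {sorted(clash)}"
                )
            chained = set(table) & set(table.values())
            if chained:
                raise ValueError(
                    f"namespace {ns!r}: transfer map not flattened, these "
                    f"targets are also keys: {sorted(chained)}"
                )


@dataclass
class UpdateSummary:
    """Counts of identifier replacements and removals, per namespace."""

    replaced: dict[str, int] = field(default_factory=dict)
    removed: dict[str, int] = field(default_factory=dict)

    def _bump(self, bucket: dict[str, int], ns: str) -> None:
        bucket[ns] = bucket.get(ns, 0) + 1


# ---------------------------------------------------------------------------
# Interchange I/O
# ---------------------------------------------------------------------------


def _as_tuple(value, what: str) -> tuple[str, ...]:
    if value is None:
        return ()
    if not isinstance(value, (list, tuple)):
        raise InterchangeError(f"{what}: expected a list, got {type(value).__name__}")
    return tuple(str(v) for v in value)


def _side_from_json(entries, rxn_id: str, which: str) -> dict[str, float]:
    side: dict[str, float] = {}
    for entry in entries:
        if not (isinstance(entry, (list, tuple)) and len(entry) == 2):
            raise InterchangeError(
                f"reaction {rxn_id!r} {which}: entries must be "
                f"[metabolite_id, coefficient] pairs"
            )
        mid, coeff = str(entry[0]), float(entry[1])
        if coeff <= 0:
            raise InterchangeError(
                f"reaction {rxn_id!r} {which}: coefficient for {mid!r} must be positive"
            )
        if mid in side:
            raise InterchangeError(
                f"reaction {rxn_id!r} {which}: metabolite {mid!r} listed twice"
            )
        side[mid] = coeff
    return side


def _metabolite_from_json(obj: dict) -> MetaboliteRecord:
    local_id = str(obj["local_id"])
    names = _as_tuple(obj.get("names"), f"metabolite {local_id!r} names")
    if not names:
        raise InterchangeError(f"metabolite {local_id!r}: at least one name required")
    ids_obj = obj.get("ids") or {}
    unknown = set(ids_obj) - set(ID_NAMESPACES)
    if unknown:
        raise InterchangeError(
            f"metabolite {local_id!r}: unknown identifier namespaces {sorted(unknown)}"
        )
    charge = obj.get("charge")
    return MetaboliteRecord(
        local_id=local_id,
        names=names,
        formula=obj.get("formula"),
        charge=None if charge is None else int(charge),
        compartment=obj.get("compartment"),
        ids=IdentifierBundle(**{k: str(v) for k, v in ids_obj.items() if v is not None}),
        is_generic=bool(obj.get("is_generic", False)),
        instance_ids=_as_tuple(obj.get("instance_ids"), f"metabolite {local_id!r} instances"),
        is_protein=bool(obj.get("is_protein", False)),
    )


def _reaction_from_json(obj: dict) -> ReactionRecord:
    local_id = str(obj["local_id"])
    rev = obj.get("reversible")
    return ReactionRecord(
        local_id=local_id,
        side_a=_side_from_json(obj.get("side_a", []), local_id, "side_a"),
        side_b=_side_from_json(obj.get("side_b", []), local_id, "side_b"),
        reversible_hint=None if rev is None else bool(rev),
        genes=frozenset(_as_tuple(obj.get("genes"), f"reaction {local_id!r} genes")),
        ecs=frozenset(
            ECNumber.parse(e) for e in _as_tuple(obj.get("ecs"), f"reaction {local_id!r} ecs")
        ),
        pathways=frozenset(_as_tuple(obj.get("pathways"), f"reaction {local_id!r} pathways")),
        is_set_reaction=bool(obj.get("is_set_reaction", False)),
    )


def snapshot_from_dict(doc: dict) -> DatabaseSnapshot:
    """Build a snapshot from a parsed interchange document (no validation)."""
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise InterchangeError(
            f"unsupported schema_version {doc.get('schema_version')!r} "
            f"(expected {SCHEMA_VERSION!r})"
        )
    snap = DatabaseSnapshot(name=str(doc.get("name", "")))
    if not snap.name:
        raise InterchangeError("snapshot 'name' is required and non-empty")
    for i, obj in enumerate(doc.get("genes", [])):
        try:
            rec = GeneRecord(
                local_id=str(obj["local_id"]),
                gene_id=None if obj.get("gene_id") is None else str(obj["gene_id"]),
            )
        except KeyError as exc:
            raise InterchangeError(f"genes[{i}]: missing field {exc}") from exc
        snap.genes[rec.local_id] = rec
    for i, obj in enumerate(doc.get("metabolites", [])):
        try:
            rec = _metabolite_from_json(obj)
        except KeyError as exc:
            raise InterchangeError(f"metabolites[{i}]: missing field {exc}") from exc
        snap.metabolites[rec.local_id] = rec
    for i, obj in enumerate(doc.get("reactions", [])):
        try:
            rxn = _reaction_from_json(obj)
        except KeyError as exc:
            raise InterchangeError(f"reactions[{i}]: missing field {exc}") from exc
        snap.reactions[rxn.local_id] = rxn
    for i, obj in enumerate(doc.get("pathways", [])):
        try:
            pw = PathwayRecord(
                local_id=str(obj["local_id"]),
                name=str(obj["name"]),
                category=obj.get("category"),
            )
        except KeyError as exc:
            raise InterchangeError(f"pathways[{i}]: missing field {exc}") from exc
        snap.pathways[pw.local_id] = pw
    return snap


def snapshot_to_dict(snapshot: DatabaseSnapshot) -> dict:
    """Serialize to the interchange document with canonical ordering."""

    def side(mapping: Mapping[str, float]) -> list[list]:
        return [[mid, mapping[mid]] for mid in sorted(mapping)]

    return {
        "schema_version": SCHEMA_VERSION,
        "name": snapshot.name,
        "genes": [
            {"local_id": g.local_id, "gene_id": g.gene_id}
            for g in (snapshot.genes[k] for k in sorted(snapshot.genes))
        ],
        "metabolites": [
            {
                "local_id": m.local_id,
                "names": list(m.names),
                "formula": m.formula,
                "charge": m.charge,
                "compartment": m.compartment,
                "ids": m.ids.present(),
                "is_generic": m.is_generic,
                "instance_ids": sorted(m.instance_ids),
                "is_protein": m.is_protein,
            }
            for m in (snapshot.metabolites[k] for k in sorted(snapshot.metabolites))
        ],
        "reactions": [
            {
                "local_id": r.local_id,
                "side_a": side(r.side_a),
                "side_b": side(r.side_b),
                "reversible": r.reversible_hint,
                "genes": sorted(r.genes),
                "ecs": sorted(str(e) for e in r.ecs),
                "pathways": sorted(r.pathways),
                "is_set_reaction": r.is_set_reaction,
            }
            for r in (snapshot.reactions[k] for k in sorted(snapshot.reactions))
        ],
        "pathways": [
            {"local_id": p.local_id, "name": p.name, "category": p.category}
            for p in (snapshot.pathways[k] for k in sorted(snapshot.pathways))
        ],
    }


def _split_cell(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    return tuple(v for v in cell.split("|") if v) if cell else ()


def _load_tsv_bundle(path: Path) -> dict:
    """Read the TSV bundle dialect: one file per record array in a directory.

    UTF-8, tab-separated, header row; list-valued cells are pipe-delimited;
    reaction sides use ``id:coeff`` items (bare ids default to coefficient 1).
    """
    import csv

    doc: dict = {"schema_version": SCHEMA_VERSION, "name": path.name}
    meta = path / "snapshot.tsv"
    if meta.exists():
        with meta.open(encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        if rows and rows[0].get("name"):
            doc["name"] = rows[0]["name"]

    def read(fname: str) -> list[dict]:
        fpath = path / fname
        if not fpath.exists():
            return []
        with fpath.open(encoding="utf-8") as fh:
            return list(csv.DictReader(fh, delimiter="\t"))

    doc["genes"] = [
        {"local_id": r["local_id"], "gene_id": r.get("gene_id") or None}
        for r in read("genes.tsv")
    ]
    doc["metabolites"] = []
    for r in read("metabolites.tsv"):
        ids = {
            ns: r[ns]
            for ns in ID_NAMESPACES
            if r.get(ns)  # empty cell = absent
        }
        doc["metabolites"].append(
            {
                "local_id": r["local_id"],
                "names": list(_split_cell(r.get("names", ""))),
                "formula": r.get("formula") or None,
                "charge": int(r["charge"]) if r.get("charge") else None,
                "compartment": r.get("compartment") or None,
                "ids": ids,
                "is_generic": r.get("is_generic", "").lower() in ("1", "true", "yes"),
                "instance_ids": list(_split_cell(r.get("instance_ids", ""))),
                "is_protein": r.get("is_protein", "").lower() in ("1", "true", "yes"),
            }
        )

    def parse_side(cell: str, rid: str, which: str) -> list[list]:
        out = []
        for item in _split_cell(cell):
            mid, _, coeff = item.partition(":")
            try:
                out.append([mid, float(coeff) if coeff else 1.0])
            except ValueError as exc:
                raise InterchangeError(
                    f"reaction {rid!r} {which}: bad side item {item!r}"
                ) from exc
        return out

    doc["reactions"] = []
    for r in read("reactions.tsv"):
        rid = r["local_id"]
        doc["reactions"].append(
            {
                "local_id": rid,
                "side_a": parse_side(r.get("side_a", ""), rid, "side_a"),
                "side_b": parse_side(r.get("side_b", ""), rid, "side_b"),
                "reversible": (
                    None
                    if not r.get("reversible")
                    else r["reversible"].lower() in ("1", "true", "yes")
                ),
                "genes": list(_split_cell(r.get("genes", ""))),
                "ecs": list(_split_cell(r.get("ecs", ""))),
                "pathways": list(_split_cell(r.get("pathways", ""))),
                "is_set_reaction": r.get("is_set_reaction", "").lower()
                in ("1", "true", "yes"),
            }
        )
    doc["pathways"] = [
        {
            "local_id": r["local_id"],
            "name": r.get("name", r["local_id"]),
            "category": r.get("category") or None,
        }
        for r in read("pathways.tsv")
    ]
    return doc


def validate_snapshot(
    snapshot: DatabaseSnapshot,
    id_patterns: Mapping[str, str] | None = None,
) -> None:
    """Check every snapshot invariant; raise SnapshotValidationError listing
    all violations (dangling references named individually)."""
    from .categories import CATEGORY_LABELS

    patterns = {ns: re.compile(rf"^(?:{p})$") for ns, p in (id_patterns or DEFAULT_ID_PATTERNS).items()}
    problems: list[str] = []

    for g in snapshot.genes.values():
        if g.gene_id is not None:
            pat = patterns.get("gene")
            if not g.gene_id:
                problems.append(f"gene {g.local_id!r}: empty gene_id")
            elif pat and not pat.match(g.gene_id):
                problems.append(f"gene {g.local_id!r}: malformed gene_id {g.gene_id!r}")

    from .matching import normalize_name  # late import: avoid cycle at module load

    for m in snapshot.metabolites.values():
        if not m.names:
            problems.append(f"metabolite {m.local_id!r}: no names")
        normed = [normalize_name(n) for n in m.names]
        if len(set(normed)) != len(normed):
            problems.append(f"metabolite {m.local_id!r}: duplicate names after normalization")
        for ns, value in m.ids.present().items():
            pat = patterns.get(ns)
            if not value:
                problems.append(f"metabolite {m.local_id!r}: empty {ns} identifier")
            elif pat and not pat.match(value):
                problems.append(
                    f"metabolite {m.local_id!r}: malformed {ns} identifier {value!r}"
                )
        if m.instance_ids and not m.is_generic:
            problems.append(
                f"metabolite {m.local_id!r}: has instances but is_generic is false"
            )
        if m.local_id in m.instance_ids:
            problems.append(f"metabolite {m.local_id!r}: lists itself as an instance")
        for inst in m.instance_ids:
            if inst not in snapshot.metabolites:
                problems.append(
                    f"metabolite {m.local_id!r}: dangling instance {inst!r}"
                )

    for r in snapshot.reactions.values():
        if not r.side_a or not r.side_b:
            problems.append(f"reaction {r.local_id!r}: empty side")
        for mid in sorted(r.participants()):
            if mid not in snapshot.metabolites:
                problems.append(f"reaction {r.local_id!r}: dangling metabolite {mid!r}")
        for gid in sorted(r.genes):
            if gid not in snapshot.genes:
                problems.append(f"reaction {r.local_id!r}: dangling gene {gid!r}")
        for pid in sorted(r.pathways):
            if pid not in snapshot.pathways:
                problems.append(f"reaction {r.local_id!r}: dangling pathway {pid!r}")

    for p in snapshot.pathways.values():
        if p.category is not None and p.category not in CATEGORY_LABELS:
            problems.append(
                f"pathway {p.local_id!r}: unknown category {p.category!r}"
            )

    if problems:
        raise SnapshotValidationError(problems)


def load_snapshot(path: str | Path, schema_check: bool = True) -> DatabaseSnapshot:
    """Load a snapshot from interchange JSON or a TSV bundle directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _VENDOR_EXTENSIONS:
        raise InterchangeError(
            f"{path.name}: SBML/BioPAX import is not supported; convert the "
            f"database to the interchange JSON format (schema_version "
            f"{SCHEMA_VERSION}, top-level arrays genes/metabolites/reactions/"
            f"pathways) or a TSV bundle directory"
        )
    if path.is_dir():
        doc = _load_tsv_bundle(path)
    else:
        try:
            with path.open(encoding="utf-8") as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise InterchangeError(f"{path.name}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
        if not isinstance(doc, dict):
            raise InterchangeError(f"{path.name}: top level must be an object")
    snapshot = snapshot_from_dict(doc)
    if schema_check:
        validate_snapshot(snapshot)
    return snapshot


def write_snapshot(snapshot: DatabaseSnapshot, path: str | Path) -> None:
    """Write interchange JSON with canonical record ordering (sorted by
    local_id), so write→load→write round-trips byte-identically."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(snapshot_to_dict(snapshot), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Identifier updating
# ---------------------------------------------------------------------------


def load_update_tables(paths: Mapping[str, str | Path]) -> UpdateTables:
    """Read per-namespace two-column TSV tables (``old<TAB>new``; an empty
    second column marks the identifier obsolete)."""
    transferred: dict[str, dict[str, str]] = {}
    obsolete: dict[str, set[str]] = {}
    for ns, p in paths.items():
        with Path(p).open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                old = parts[0].strip()
                new = parts[1].strip() if len(parts) > 1 else ""
                if not old:
                    raise InterchangeError(f"{p}:{lineno}: empty old identifier")
                if new:
                    transferred.setdefault(ns, {})[old] = new
                else:
                    obsolete.setdefault(ns, set()).add(old)
    return UpdateTables(transferred=transferred, obsolete=obsolete)


def _update_one(
    value: str | None, ns: str, tables: UpdateTables, summary: UpdateSummary
) -> str | None:
    if value is None:
        return None
    moved = tables.transferred.get(ns, {}).get(value)
    if moved is not None:
        summary._bump(summary.replaced, ns)
        return moved
    if value in tables.obsolete.get(ns, set()):
        summary._bump(summary.removed, ns)
        return None
    return value


def apply_identifier_updates(
    snapshot: DatabaseSnapshot, tables: UpdateTables
) -> tuple[DatabaseSnapshot, UpdateSummary]:
    """Replace transferred identifiers with their targets and drop obsolete
    ones (the identifier, never the record: the entity can still match via
    other routes). Idempotent, because transfer maps are pre-flattened.
    """
    summary = UpdateSummary()
    out = DatabaseSnapshot(name=snapshot.name, uninstantiable=snapshot.uninstantiable)

    for g in snapshot.genes.values():
        out.genes[g.local_id] = replace(
            g, gene_id=_update_one(g.gene_id, "gene", tables, summary)
        )
    for m in snapshot.metabolites.values():
        new_ids = {
            ns: _update_one(m.ids.get(ns), ns, tables, summary) for ns in ID_NAMESPACES
        }
        out.metabolites[m.local_id] = replace(
            m, ids=IdentifierBundle(**{k: v for k, v in new_ids.items() if v is not None})
        )
    ec_map = tables.transferred.get("ec", {})
    ec_obsolete = tables.obsolete.get("ec", set())
    for r in snapshot.reactions.values():
        new_ecs = set()
        for ec in r.ecs:
            text = str(ec)
            if text in ec_map:
                new_ecs.add(ECNumber.parse(ec_map[text]))
                summary._bump(summary.replaced, "ec")
            elif text in ec_obsolete:
                summary._bump(summary.removed, "ec")
            else:
                new_ecs.add(ec)
        out.reactions[r.local_id] = replace(r, ecs=frozenset(new_ecs))
    out.pathways = dict(snapshot.pathways)
    return out, summary


# ---------------------------------------------------------------------------
# Set/class instantiation
# ---------------------------------------------------------------------------


def _generic_participants(r: ReactionRecord, snap: DatabaseSnapshot) -> tuple[list[str], list[str]]:
    """Generic participants with known instances on each side, in sorted order."""

    def pick(side: Mapping[str, float]) -> list[str]:
        return [
            mid
            for mid in sorted(side)
            if (m := snap.metabolites.get(mid)) is not None
            and m.is_generic
            and m.instance_ids
        ]

    return pick(r.side_a), pick(r.side_b)


def expand_generic_reactions(
    snapshot: DatabaseSnapshot, mode: str = "first_member"
) -> DatabaseSnapshot:
    """Instantiate reactions whose participants are metabolite sets/classes.

    ``first_member`` replaces each set participant by that set's first listed
    member, pairing positionally across sides (first set on the left with the
    first set on the right, and so on). ``all_members`` emits one instantiated
    reaction per positional index, bounded by the shortest set. ``none``
    returns the snapshot unchanged. Reactions where both sides carry sets but
    in unequal numbers cannot be positionally paired; they are left in place
    and flagged in ``snapshot.uninstantiable``. Generic metabolites without
    instances are also left in place (they simply cannot be instantiated).

    Metabolite-level comparisons always see class instances as candidate match
    targets regardless of mode, because instances are ordinary records of the
    snapshot's metabolites collection.
    """
    if mode not in ("first_member", "all_members", "none"):
        raise ValueError(f"unknown expansion mode {mode!r}")
    if mode == "none":
        return snapshot

    out = DatabaseSnapshot(
        name=snapshot.name,
        genes=dict(snapshot.genes),
        metabolites=dict(snapshot.metabolites),
        pathways=dict(snapshot.pathways),
    )
    flagged = list(snapshot.uninstantiable)

    for r in (snapshot.reactions[k] for k in sorted(snapshot.reactions)):
        gen_a, gen_b = _generic_participants(r, snapshot)
        if not gen_a and not gen_b:
            out.reactions[r.local_id] = r
            continue
        if gen_a and gen_b and len(gen_a) != len(gen_b):
            out.reactions[r.local_id] = r
            flagged.append(r.local_id)
            continue

        sets = gen_a + gen_b
        if mode == "first_member":
            indices = [0]
        else:
            shortest = min(len(snapshot.metabolites[g].instance_ids) for g in sets)
            indices = list(range(shortest))

        for k in indices:
            sub: dict[str, str] = {}
            ok = True
            for g in sets:
                members = snapshot.metabolites[g].instance_ids
                if k >= len(members):
                    ok = False
                    break
                sub[g] = members[k]
            if not ok:
                continue

            def instantiate(side: Mapping[str, float]) -> dict[str, float]:
                new: dict[str, float] = {}
                for mid, coeff in side.items():
                    new_mid = sub.get(mid, mid)
                    new[new_mid] = new.get(new_mid, 0.0) + coeff
                return new

            suffix = "" if mode == "first_member" else f"__inst{k}"
            out.reactions[r.local_id + suffix] = replace(
                r,
                local_id=r.local_id + suffix,
                side_a=instantiate(r.side_a),
                side_b=instantiate(r.side_b),
                is_set_reaction=False,
            )

    out.uninstantiable = tuple(flagged)
    return out
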