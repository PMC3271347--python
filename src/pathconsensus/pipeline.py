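"""End-to-end comparison pipeline and report exports.

One YAML config drives a whole comparison run: snapshot paths, identifier
update tables, matching configuration, the comparison modes to execute
(global, strict-vs-relaxed, pairwise, core-restricted, single-pathway scope)
and the output directory. Every table written is a view of the exported
partition dumps — counts in summaries are recomputable from the partition TSV,
never computed along an independent code path. Identical config and seed
produce byte-identical artifact directories.
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .categories import CORE_CATEGORIES, assign_categories, core_subset, load_category_mapping
from .datamodel import (
    DatabaseSnapshot,
    apply_identifier_updates,
    expand_generic_reactions,
    load_snapshot,
    load_update_tables,
)
from .matching import EntityKey, MatchConfig, MatchPartition
from .stats import (
    ComparisonResult,
    build_all_partitions,
    combination_gene_ec,
    combination_reaction_gene_ec,
    compare_partition,
    pairwise_compare,
    restricted_compare,
)

__all__ = [
    "ConfigError",
    "load_config",
    "run_pipeline",
    "export_alignment",
    "export_partition",
    "render_reaction",
]


class ConfigError(ValueError):
    """Pipeline config missing or malformed; message names the field path."""


_KNOWN_KEYS = {
    "snapshots",
    "update_tables",
    "match",
    "modes",
    "majority_threshold",
    "expand_generic",
    "pathway_scope",
    "pathway_aliases",
    "category_mapping",
    "core",
    "out_dir",
    "seed",
}


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with path.open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config: top level must be a mapping")
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"config: unknown keys {sorted(unknown)}")
    if "snapshots" not in cfg or not isinstance(cfg["snapshots"], list) or len(cfg["snapshots"]) < 2:
        raise ConfigError("config.snapshots: need a list of at least two snapshot paths")
    if "out_dir" not in cfg:
        raise ConfigError("config.out_dir: required")
    return cfg


def match_config_from(cfg_block: Mapping | None) -> MatchConfig:
    block = dict(cfg_block or {})
    overrides: list = []
    pairs_file = block.pop("override_pairs_file", None)
    if pairs_file:
        with Path(pairs_file).open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, _, b = line.partition("\t")
                overrides.append((a.strip(), b.strip()))
    overrides.extend(tuple(p) for p in block.pop("override_pairs", []))
    ignore = block.pop("ignore_metabolites", None)
    kwargs = {}
    if ignore is not None:
        kwargs["ignore_metabolites"] = frozenset(ignore)
    for key in ("h_tolerant_formula", "generic_specific_guard", "name_requires_formula"):
        if key in block:
            kwargs[key] = bool(block.pop(key))
    if block:
        raise ConfigError(f"config.match: unknown keys {sorted(block)}")
    return MatchConfig(override_pairs=tuple(overrides), **kwargs)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def render_reaction(snapshot: DatabaseSnapshot, local_id: str) -> str:
    """Human-readable rendering, sorted by first metabolite name per side."""
    r = snapshot.reactions[local_id]

    def side(mapping) -> str:
        parts = []
        for mid in sorted(mapping):
            m = snapshot.metabolites[mid]
            coeff = mapping[mid]
            prefix = "" if coeff == 1 else f"{coeff:g} "
            parts.append(prefix + m.names[0])
        return " + ".join(parts)

    return f"{side(r.side_a)} <=> {side(r.side_b)}"


def export_partition(partition: MatchPartition) -> pd.DataFrame:
    """Flat dump: class_id, entity_class, snapshot, local_id, route evidence."""
    routes: dict[EntityKey, str] = {}
    for (a, b), route in partition.evidence.items():
        routes.setdefault(a, route)
        routes.setdefault(b, route)
    rows = []
    for cls in partition.classes:
        rep = min(cls)
        class_id = f"{rep.snapshot_name}:{rep.local_id}"
        for member in sorted(cls):
            rows.append(
                {
                    "class_id": class_id,
                    "entity_class": partition.entity_class,
                    "snapshot": member.snapshot_name,
                    "local_id": member.local_id,
                    "route": routes.get(member, ""),
                }
            )
    for reason, keys in sorted(partition.excluded.items()):
        for key in keys:
            rows.append(
                {
                    "class_id": "",
                    "entity_class": partition.entity_class,
                    "snapshot": key.snapshot_name,
                    "local_id": key.local_id,
                    "route": f"excluded:{reason}",
                }
            )
    return pd.DataFrame(rows, columns=["class_id", "entity_class", "snapshot", "local_id", "route"])


def export_alignment(
    reaction_partition: MatchPartition,
    snapshots: Sequence[DatabaseSnapshot],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Alignment overview: one row per reaction class with a rendered reaction
    cell per snapshot (empty when the database lacks the reaction), its EC,
    gene and pathway lists, and the agreement count. Ordered by descending
    agreement, then class id. Degenerate/excluded reactions go in a second
    frame with reason codes."""
    by_name = {s.name: s for s in snapshots}
    names = sorted(by_name)
    rows = []
    for cls in reaction_partition.classes:
        rep = min(cls)
        row: dict = {"class_id": f"{rep.snapshot_name}:{rep.local_id}"}
        present = 0
        for snap_name in names:
            members = sorted(m.local_id for m in cls if m.snapshot_name == snap_name)
            if members:
                present += 1
                snap = by_name[snap_name]
                rendered = "; ".join(render_reaction(snap, mid) for mid in members)
                ecs = sorted({str(e) for mid in members for e in snap.reactions[mid].ecs})
                genes = sorted(
                    {
                        snap.genes[g].gene_id or g
                        for mid in members
                        for g in snap.reactions[mid].genes
                    }
                )
                pws = sorted(
                    {
                        by_name[snap_name].pathways[p].name
                        for mid in members
                        for p in snap.reactions[mid].pathways
                    }
                )
                row[f"{snap_name}__reaction"] = rendered
                row[f"{snap_name}__ecs"] = "|".join(ecs)
                row[f"{snap_name}__genes"] = "|".join(genes)
                row[f"{snap_name}__pathways"] = "|".join(pws)
            else:
                row[f"{snap_name}__reaction"] = ""
                row[f"{snap_name}__ecs"] = ""
                row[f"{snap_name}__genes"] = ""
                row[f"{snap_name}__pathways"] = ""
        row["agreement_count"] = present
        rows.append(row)
    columns = ["class_id"] + [
        f"{n}__{f}" for n in names for f in ("reaction", "ecs", "genes", "pathways")
    ] + ["agreement_count"]
    frame = pd.DataFrame(rows, columns=columns)
    frame = frame.sort_values(
        ["agreement_count", "class_id"], ascending=[False, True]
    ).reset_index(drop=True)

    excluded_rows = [
        {"snapshot": key.snapshot_name, "local_id": key.local_id, "reason": reason}
        for reason, keys in sorted(reaction_partition.excluded.items())
        for key in keys
    ]
    excluded = pd.DataFrame(excluded_rows, columns=["snapshot", "local_id", "reason"])
    return frame, excluded


def _result_json(result: ComparisonResult) -> dict:
    d = asdict(result)
    d["occurrence_histogram"] = {str(k): v for k, v in result.occurrence_histogram.items()}
    return d


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config_path: str | Path) -> Path:
    """Execute a full comparison run; returns the artifact directory."""
    cfg = load_config(config_path)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    mcfg = match_config_from(cfg.get("match"))
    majority_threshold = int(cfg.get("majority_threshold", 3))
    modes = list(cfg.get("modes", ["global"]))

    snapshots: list[DatabaseSnapshot] = []
    for p in cfg["snapshots"]:
        if not Path(p).exists():
            raise ConfigError(f"config.snapshots: file not found: {p}")
        snapshots.append(load_snapshot(p))

    if cfg.get("update_tables"):
        tables = load_update_tables(cfg["update_tables"])
        snapshots = [apply_identifier_updates(s, tables)[0] for s in snapshots]

    expand_mode = cfg.get("expand_generic", "none")
    if expand_mode != "none":
        snapshots = [expand_generic_reactions(s, expand_mode) for s in snapshots]

    if cfg.get("category_mapping"):
        mapping = load_category_mapping(cfg["category_mapping"])
        snapshots = [assign_categories(s, mapping) for s in snapshots]

    summaries: dict = {}

    if "global" in modes:
        for label, run_cfg in (
            ("strict", replace(mcfg, ignore_metabolites=frozenset())),
            ("relaxed", mcfg),
        ):
            parts = build_all_partitions(snapshots, run_cfg)
            results = {
                "genes": compare_partition(parts["gene"], majority_threshold),
                "ecs": compare_partition(parts["ec"], majority_threshold),
                "metabolites": compare_partition(parts["metabolite"], majority_threshold),
                "reactions": compare_partition(parts["reaction"], majority_threshold),
            }
            summaries[label] = {k: _result_json(v) for k, v in results.items()}
            summary_rows = pd.DataFrame(
                {k: v.to_row() for k, v in results.items()}
            ).T.reset_index(names="entity")
            _write_tsv(summary_rows, out_dir / f"summary_{label}.tsv")
            for entity, part in parts.items():
                _write_tsv(export_partition(part), out_dir / f"partition_{label}_{entity}.tsv")
            if label == "relaxed":
                alignment, excluded = export_alignment(parts["reaction"], snapshots)
                _write_tsv(alignment, out_dir / "alignment_overview.tsv")
                _write_tsv(excluded, out_dir / "alignment_excluded.tsv")
                summaries["combinations"] = {
                    "gene_ec": combination_gene_ec(snapshots, parts["gene"], parts["ec"]),
                    "reaction_gene_ec": combination_reaction_gene_ec(
                        snapshots, parts["reaction"], parts["gene"], parts["ec"]
                    ),
                }

    if "pairwise" in modes:
        for entity in ("gene", "ec", "metabolite", "reaction"):
            matrix = pairwise_compare(snapshots, entity, mcfg)
            matrix.round(1).to_csv(out_dir / f"pairwise_{entity}.tsv", sep="\t")

    if "core" in modes:
        core_cfg = dict(cfg.get("core", {}))
        drop_macro_for = set(core_cfg.get("drop_macromolecular_for", []))
        cores = [
            core_subset(
                s,
                drop_macromolecular=s.name in drop_macro_for,
                drop_transport=bool(core_cfg.get("drop_transport", True)),
            )
            for s in snapshots
        ]
        parts = build_all_partitions(cores, mcfg)
        results = {
            "genes": compare_partition(parts["gene"], majority_threshold),
            "ecs": compare_partition(parts["ec"], majority_threshold),
            "metabolites": compare_partition(parts["metabolite"], majority_threshold),
            "reactions": compare_partition(parts["reaction"], majority_threshold),
        }
        summaries["core"] = {k: _result_json(v) for k, v in results.items()}
        summary_rows = pd.DataFrame({k: v.to_row() for k, v in results.items()}).T.reset_index(
            names="entity"
        )
        _write_tsv(summary_rows, out_dir / "summary_core.tsv")

    if "pathway" in modes:
        scope = cfg.get("pathway_scope")
        if not scope:
            raise ConfigError("config.pathway_scope: required when modes includes 'pathway'")
        res = restricted_compare(
            snapshots,
            scope,
            mcfg,
            pathway_aliases=cfg.get("pathway_aliases"),
            majority_threshold=majority_threshold,
        )
        summaries["pathway"] = {
            "scope": scope,
            "genes": _result_json(res["genes"]),
            "ecs": _result_json(res["ecs"]),
            "metabolites": _result_json(res["metabolites"]),
            "reactions": _result_json(res["reactions"]),
            "within_reaction_agreement": res["within_reaction_agreement"],
        }

    with (out_dir / "summary.json").open("w", encoding="utf-8") as fh:
        json.dump(summaries, fh, indent=1, sort_keys=True)
        fh.write("\n")

    run_log = {
        "package_version": __version__,
        "config": {k: cfg[k] for k in sorted(cfg)},
        "snapshots": sorted(s.name for s in snapshots),
        "seed": cfg.get("seed"),
    }
    with (out_dir / "run_log.json").open("w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return out_dir
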