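"""End-to-end orchestration: align/lift -> scan -> profiles -> motifs -> structure.

One :class:`PipelineConfig` (loadable from YAML/JSON) drives all stages
against one ortholog family; every stage writes plain TSV/JSON into the
report directory and a ``summary.json`` records per-stage counts. Output
is deterministic: rerunning with identical config and inputs reproduces
the report tree byte for byte (sorted keys, no timestamps, no hidden
randomness).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import conservation, motif_map, nes_scan, seq_io, structure
from .align_anchor import RegionAnnotation, global_align, lift_region

log = logging.getLogger("motifshift")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    fasta: str
    metadata: str
    outdir: str
    tree: str | None = None
    reference_id: str | None = None
    regions: list[dict] = field(default_factory=list)  # {name, ref_id, start, end}
    nes_region: str = "NES"
    signature_region: str = "signature"
    signature_classes: tuple[str, ...] = motif_map.DEFAULT_CLASSES
    clade_labels: list[str] = field(default_factory=list)
    # optional structure stage: list of {a, b} PDB path pairs
    structure_pairs: list[dict] = field(default_factory=list)
    plddt_threshold: float = structure.PLDDT_DEFAULT
    rmsd_threshold: float = structure.RMSD_SIMILAR_DEFAULT
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _region_annotations(config: PipelineConfig) -> list[RegionAnnotation]:
    out = []
    for r in config.regions:
        out.append(
            RegionAnnotation(
                name=r["name"], ref_id=r["ref_id"],
                start=int(r["start"]), end=int(r["end"]),
            )
        )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the summary dict (also written).

    A stage that fails stops the run: later stages are skipped and the
    summary records the failure point. A missing tree only downgrades the
    parsimony step to a warning, since tallies are still meaningful.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}, "failed_stage": None}

    def finish(stage: str | None = None) -> dict:
        summary["failed_stage"] = stage
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n"
        )
        return summary

    # ---- load ----
    try:
        records = seq_io.read_fasta(config.fasta)
        meta = seq_io.read_metadata(config.metadata)
        records = seq_io.join_metadata(records, meta)
    except Exception as exc:
        log.error("input stage failed: %s", exc)
        summary["stages"]["load"] = {"error": str(exc)}
        finish("load")
        raise
    summary["stages"]["load"] = {"n_sequences": len(records)}

    tree = None
    if config.tree:
        tree = seq_io.read_tree(config.tree)

    # ---- align + lift ----
    regions = _region_annotations(config)
    lifted_rows = []
    lifted_by_region: dict[str, dict[str, object]] = {r.name: {} for r in regions}
    if config.reference_id and regions:
        by_id = {r.id: r for r in records}
        if config.reference_id not in by_id:
            err = f"reference id {config.reference_id!r} not in FASTA"
            summary["stages"]["lift"] = {"error": err}
            finish("lift")
            raise ConfigError(err)
        ref = by_id[config.reference_id]
        for rec in records:
            aln = global_align(ref, rec)
            for region in regions:
                lifted = lift_region(aln, region)
                lifted_by_region[region.name][rec.id] = (lifted, rec)
                lifted_rows.append(
                    {
                        "query_id": rec.id, "name": region.name,
                        "q_start": lifted.q_start, "q_end": lifted.q_end,
                        "status": lifted.status, "subsequence": lifted.subsequence,
                    }
                )
        pd.DataFrame(lifted_rows).to_csv(
            outdir / "lifted_regions.tsv", sep="\t", index=False
        )
        summary["stages"]["lift"] = {
            "n_lifted": len(lifted_rows),
            "n_complete": sum(1 for r in lifted_rows if r["status"] == "complete"),
        }

    # ---- NES scan ----
    hit_rows = []
    n_conforming = 0
    nes_lifts = lifted_by_region.get(config.nes_region, {})
    for rec in records:
        matches = nes_scan.scan_nes(rec.sequence)
        in_window_spans: set[tuple[int, int]] = set()
        if rec.id in nes_lifts:
            lifted, _ = nes_lifts[rec.id]
            if lifted.status != "missing":
                report = nes_scan.window_check(matches, lifted)
                if report.conforms:
                    n_conforming += 1
                in_window_spans = {(m.start, m.end) for m in report.contained}
        for m in matches:
            hit_rows.append(
                {
                    "seq_id": rec.id, "start": m.start, "end": m.end,
                    "spacer1": m.spacer1, "spacer2": m.spacer2,
                    "matched": m.matched,
                    "in_window": (m.start, m.end) in in_window_spans,
                }
            )
    pd.DataFrame(
        hit_rows,
        columns=["seq_id", "start", "end", "spacer1", "spacer2", "matched", "in_window"],
    ).to_csv(outdir / "nes_hits.tsv", sep="\t", index=False)
    summary["stages"]["nes_scan"] = {
        "n_matches": len(hit_rows),
        "n_sequences_conforming": n_conforming,
    }

    # ---- conservation profiles per region x taxon group ----
    distinct_rows = []
    n_profiles = 0
    for region in regions:
        entries = lifted_by_region[region.name]
        groups: dict[str, list[str]] = {}
        for lifted, rec in entries.values():
            if lifted.status == "complete":
                groups.setdefault(rec.taxon_group or "all", []).append(
                    lifted.subsequence
                )
        for group, seqs in sorted(groups.items()):
            # indels inside a lifted window give unequal lengths; profile
            # the modal length and report how many were set aside
            lengths = pd.Series([len(s) for s in seqs])
            modal = int(lengths.mode().iloc[0])
            usable = [s for s in seqs if len(s) == modal]
            profile = conservation.column_profile(usable, group=group)
            conservation.export_logo_data(
                profile, outdir / f"logo_{region.name}_{group}.tsv"
            )
            n_profiles += 1
            distinct_rows.append(
                {
                    "region": region.name, "taxon_group": group,
                    "n_sequences": len(seqs),
                    "n_profiled": len(usable),
                    "n_distinct": conservation.count_distinct(seqs),
                }
            )
    pd.DataFrame(
        distinct_rows,
        columns=["region", "taxon_group", "n_sequences", "n_profiled", "n_distinct"],
    ).to_csv(outdir / "region_distinct_counts.tsv", sep="\t", index=False)
    summary["stages"]["conservation"] = {"n_profiles": n_profiles}

    # ---- signature motif tally + parsimony ----
    sig_entries = lifted_by_region.get(config.signature_region, {})
    if sig_entries:
        assignments = []
        for lifted, rec in sig_entries.values():
            a = motif_map.extract_signature(lifted, classes=config.signature_classes)
            a.species = rec.species
            assignments.append(a)
        pd.DataFrame(
            [
                {
                    "seq_id": a.seq_id, "species": a.species, "motif": a.motif,
                    "class": a.class_label, "position": a.position,
                }
                for a in assignments
            ]
        ).to_csv(outdir / "signature_assignments.tsv", sep="\t", index=False)
        motif_summary: dict = {"n_assigned": len(assignments)}
        if tree is not None:
            if config.clade_labels:
                tally = motif_map.tally_by_clade(assignments, tree, config.clade_labels)
                tally.to_csv(outdir / "motif_tally.tsv", sep="\t")
            leaf_states = {a.species: a.class_label for a in assignments}
            pars = motif_map.parsimony_states(tree, leaf_states)
            pd.DataFrame(
                [
                    {
                        "parent": t.parent, "child": t.child,
                        "from": t.from_state, "to": t.to_state,
                    }
                    for t in pars.transitions
                ],
                columns=["parent", "child", "from", "to"],
            ).to_csv(outdir / "motif_transitions.tsv", sep="\t", index=False)
            motif_summary.update(
                {
                    "min_changes": pars.min_changes,
                    "is_unique": pars.is_unique,
                    "n_transitions": len(pars.transitions),
                }
            )
        else:
            log.warning("no tree supplied; parsimony step skipped")
            motif_summary["parsimony"] = "skipped (no tree)"
        summary["stages"]["motifs"] = motif_summary

    # ---- structure (optional) ----
    if config.structure_pairs:
        sup_rows = []
        for pair in config.structure_pairs:
            ma = seq_io.read_structure(pair["a"])
            mb = seq_io.read_structure(pair["b"])
            result = structure.superpose_models(
                ma, mb,
                plddt_threshold=config.plddt_threshold,
                similar_threshold=config.rmsd_threshold,
            )
            sup_rows.append(
                {
                    "a": pair["a"], "b": pair["b"],
                    "rmsd": round(result.rmsd, 6),
                    "n_atoms": result.n_atoms,
                    "similar": result.similar,
                }
            )
        (outdir / "superpositions.json").write_text(
            json.dumps(sup_rows, indent=1, sort_keys=True) + "\n"
        )
        summary["stages"]["structure"] = {"n_pairs": len(sup_rows)}

    return finish(None)
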