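"""End-to-end pipeline: prep -> blocks -> classify -> table -> report.

The driver ties the stages together on either real inputs (annotation files
plus a BLAST tabular hit file) or a simulated genome set, writes every
intermediate artifact as TSV, and records a JSON manifest (tool version,
parameters, input checksums) sufficient to reproduce the run.  A rerun into
the same output directory skips stages whose manifest fingerprint is
unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .aligntable import allocate_columns, fill_table, summarize_homology
from .anchors import (
    AnchorSet, FilterParams, build_anchor_sets, filter_hits, read_anchor_sets,
    write_anchor_sets,
)
from .classify import (
    classify_blocks, karyotype_map, recovery_metrics, write_labeled_blocks,
)
from .collinearity import (
    ChainParams, filter_blocks, read_blocks, score_blocks, write_block_anchors,
    write_blocks,
)
from .io import read_annotation, read_hits, write_alignment_table
from .model import GenomeAnnotation
from .simulate import (
    EventTree, SimulationConfig, build_event_tree, emit_hits, evolve_genomes,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    reference: str
    outdir: Path
    # either a simulator preset ...
    preset: str | None = None
    sim_config: SimulationConfig = field(default_factory=SimulationConfig)
    # ... or real inputs
    annotation_paths: dict[str, Path] = field(default_factory=dict)
    annotation_format: str = "gff3"
    hits_path: Path | None = None
    tree_spec: dict | str | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    chain_params: ChainParams = field(default_factory=ChainParams)
    thresholds: tuple[int, ...] = (4, 10, 20, 50)
    seed: int = 0


@dataclass
class PipelineResult:
    outdir: Path
    annotations: dict[str, GenomeAnnotation]
    anchor_sets: list[AnchorSet]
    blocks: list
    labeled: list
    table: object
    summary: object
    metrics: pd.DataFrame | None
    manifest: dict


def _fingerprint(config: PipelineConfig) -> str:
    h = hashlib.sha256()
    h.update(__version__.encode())

    def feed(obj) -> None:
        h.update(repr(obj).encode())

    feed(dataclasses.asdict(config.sim_config))
    feed(dataclasses.asdict(config.filter_params))
    feed(dataclasses.asdict(config.chain_params))
    feed((config.reference, config.preset, config.thresholds, config.seed,
          config.tree_spec, config.annotation_format))
    for name in sorted(config.annotation_paths):
        feed(name)
        h.update(Path(config.annotation_paths[name]).read_bytes())
    if config.hits_path is not None:
        h.update(Path(config.hits_path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fingerprint = _fingerprint(config)
    manifest_path = out / "manifest.json"
    cached = None
    if manifest_path.exists():
        try:
            cached = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            cached = None
    reuse = bool(cached) and cached.get("fingerprint") == fingerprint

    # ---- inputs -----------------------------------------------------------
    truth = None
    subgenomes: dict[str, dict[str, str]] = {}
    if config.preset is not None:
        tree = build_event_tree(config.preset)
        sim_cfg = dataclasses.replace(config.sim_config, seed=config.seed)
        sim = evolve_genomes(tree, sim_cfg)
        annotations = sim.annotations
        hits = emit_hits(sim)
        truth = sim.truth
        subgenomes = sim.subgenomes
    else:
        if config.tree_spec is None:
            raise ValueError("tree_spec is required when not simulating")
        tree = build_event_tree(config.tree_spec)
        annotations = {}
        for name, path in config.annotation_paths.items():
            path = Path(path)
            if not path.exists():
                raise FileNotFoundError(f"annotation file not found: {path}")
            annotations[name] = read_annotation(
                path, format=config.annotation_format, genome_id=name
            )
        if config.hits_path is None or not Path(config.hits_path).exists():
            raise FileNotFoundError(f"hits file not found: {config.hits_path}")
        hits = read_hits(config.hits_path)
        for m in tree.merges:
            subgenomes[m.genome_id] = {lab: lab for lab, _ in m.donors}
    if config.reference not in annotations:
        raise ValueError(f"reference {config.reference!r} not among genomes")

    # ---- prep: filter, collapse tandems, anchor sets ----------------------
    genome_of = {
        g.gene_id: ann.genome_id
        for ann in annotations.values()
        for g in ann
    }
    hits = filter_hits(hits, config.filter_params, genome_of)
    collapsed: dict[str, GenomeAnnotation] = {}
    for name, ann in annotations.items():
        within = hits[
            hits["query"].map(genome_of).eq(name)
            & hits["subject"].map(genome_of).eq(name)
        ]
        new_ann, hits = _collapse_into(ann, within, hits, config.filter_params)
        collapsed[name] = new_ann
    genome_of = {
        g.gene_id: ann.genome_id for ann in collapsed.values() for g in ann
    }
    hits = hits[
        hits["query"].isin(genome_of) & hits["subject"].isin(genome_of)
    ].reset_index(drop=True)

    anchors_path = out / "anchors.tsv"
    if reuse and anchors_path.exists():
        anchor_sets = read_anchor_sets(anchors_path)
        log.info("prep: reused cached anchor sets (%d)", len(anchor_sets))
    else:
        names = list(collapsed)
        anchor_sets = []
        qg = hits["query"].map(genome_of)
        sg = hits["subject"].map(genome_of)
        for i, a in enumerate(names):
            for b in names[i:]:
                sub = hits[((qg == a) & (sg == b)) | ((qg == b) & (sg == a))]
                if sub.empty:
                    continue
                anchor_sets.extend(
                    build_anchor_sets(collapsed[a], collapsed[b], sub)
                )
        write_anchor_sets(anchor_sets, anchors_path)

    # ---- blocks -----------------------------------------------------------
    blocks_path = out / "blocks.tsv"
    blk_anchors_path = out / "block_anchors.tsv"
    if reuse and blocks_path.exists() and blk_anchors_path.exists():
        blocks = read_blocks(blocks_path, blk_anchors_path)
        log.info("blocks: reused cached blocks (%d)", len(blocks))
    else:
        blocks = []
        for aset in anchor_sets:
            blocks.extend(
                filter_blocks(score_blocks(aset, config.chain_params),
                              config.chain_params)
            )
        write_blocks(blocks, blocks_path)
        write_block_anchors(blocks, blk_anchors_path)

    # ---- classify ----------------------------------------------------------
    labeled = classify_blocks(blocks, tree, config.reference)
    write_labeled_blocks(labeled, out / "labeled_blocks.tsv")
    karyo = karyotype_map(labeled, collapsed[config.reference], subgenomes)
    karyo.to_csv(out / "karyotype.tsv", sep="\t", index=False)
    metrics = None
    if truth is not None:
        metrics = recovery_metrics(labeled, truth, genome_of)
        metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)

    # ---- table -------------------------------------------------------------
    schema = allocate_columns(tree, config.reference)
    table = fill_table(schema, labeled, collapsed)
    write_alignment_table(table, out / "alignment_table.tsv")

    # ---- report ------------------------------------------------------------
    summary = summarize_homology(
        blocks, collapsed, config.thresholds, subgenomes
    )
    summary.to_files(out / "summary")

    manifest = {
        "tool": "polysyn",
        "version": __version__,
        "fingerprint": fingerprint,
        "seed": config.seed,
        "reference": config.reference,
        "preset": config.preset,
        "cached": reuse,
        "parameters": {
            "filter": dataclasses.asdict(config.filter_params),
            "chain": dataclasses.asdict(config.chain_params),
            "simulation": dataclasses.asdict(config.sim_config)
            if config.preset
            else None,
            "thresholds": list(config.thresholds),
        },
        "genomes": {name: ann.n_genes for name, ann in annotations.items()},
        "n_anchor_sets": len(anchor_sets),
        "n_blocks": len(blocks),
        "n_table_columns": len(schema),
        "n_table_rows": len(table.rows),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        outdir=out, annotations=collapsed, anchor_sets=anchor_sets,
        blocks=blocks, labeled=labeled, table=table, summary=summary,
        metrics=metrics, manifest=manifest,
    )


def _collapse_into(ann, within_hits, all_hits, params):
    """Collapse one genome's tandems and rewrite the global hit table."""
    rep_map = _tandem_rep_map(ann, within_hits, params)
    chroms = {
        chrom: [g for g in genes if g.gene_id not in rep_map]
        for chrom, genes in ann.chromosomes.items()
    }
    new_ann = GenomeAnnotation(
        genome_id=ann.genome_id, chromosomes=chroms, rank_gaps_ok=True
    )
    if not rep_map:
        return new_ann, all_hits
    hits = all_hits.copy()
    hits["query"] = hits["query"].map(lambda g: rep_map.get(g, g))
    hits["subject"] = hits["subject"].map(lambda g: rep_map.get(g, g))
    hits = hits[hits["query"] != hits["subject"]]
    hits = (
        hits.sort_values(
            ["query", "subject", "bitscore", "identity"],
            ascending=[True, True, False, False],
            kind="mergesort",
        )
        .drop_duplicates(["query", "subject"], keep="first")
        .reset_index(drop=True)
    )
    return new_ann, hits


def _tandem_rep_map(ann, within_hits, params) -> dict[str, str]:
    from .anchors import tandem_arrays

    rep_of: dict[str, str] = {}
    for arr in tandem_arrays(ann, within_hits, params):
        rep = arr[0].gene_id
        for g in arr[1:]:
            rep_of[g.gene_id] = rep
    return rep_of
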