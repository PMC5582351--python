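"""Layered classification of collinear blocks into orthologs and
event-specific (out)paralogs.

After recursive polyploidizations a reference segment is homologous to
several segments of every other genome: one orthologous segment per
subgenome copy, plus outparalogous segments tracing back to the shared
ancient WGD.  Because post-WGD fractionation is largely shared between
descendants, orthologous blocks retain more collinear genes and higher
sequence identity than outparalogous ones — the two signals used here.
Competing blocks covering the same reference segment are ranked by
(collinear gene number, mean identity) and the top slots, one per expected
subgenome copy, are taken as orthologs; the rest are assigned to the oldest
WGD consistent with the lineage pair.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .collinearity import CollinearBlock
from .model import GenomeAnnotation
from .simulate import EventTree

log = logging.getLogger(__name__)

RELATIONS = (
    "ortholog", "gct_paralog", "mst_paralog", "homoeolog_merge", "unassigned",
)


@dataclass(frozen=True)
class EventLabel:
    relation: str
    event_id: str | None
    confidence: float

    def __post_init__(self) -> None:
        if self.relation != "unassigned" and self.event_id is None:
            raise ValueError("labeled relation requires an event id")


@dataclass
class LabeledBlock:
    block: CollinearBlock
    label: EventLabel
    #: 1-based homology-column slot within the target genome's expected
    #: multiplicity; 0 when the block exceeded the column quota.
    subgenome_track: int
    #: which side of the block is the reference genome ("a" or "b"; "a" for
    #: within-genome blocks)
    ref_side: str = "a"

    @property
    def target_genome(self) -> str:
        return self.block.genome_b if self.ref_side == "a" else self.block.genome_a

    def ref_span(self) -> tuple[int, int]:
        return self.block.span_a if self.ref_side == "a" else self.block.span_b

    def ref_chromosome(self) -> str:
        return self.block.chrom_a if self.ref_side == "a" else self.block.chrom_b

    def anchors_ref_first(self):
        """Anchors as (ref_rank, target_rank, identity, ref_gene, target_gene)."""
        if self.ref_side == "a":
            return list(self.block.anchors)
        return [(rb, ra, ident, gb, ga) for (ra, rb, ident, ga, gb) in self.block.anchors]


def expected_multiplicity(genome_id: str, tree: EventTree) -> int:
    """Number of homology columns a genome contributes to the alignment table.

    2^(WGDs on the lineage, root WGD included), summed over subgenome donors
    for a merged polyploid: a post-root-WGD diploid contributes 2, a genome
    with one extra WGD 4, a three-way hexaploid 6.
    """
    merge = tree.merge_for(genome_id)
    if merge is not None:
        return sum(2 ** len(tree.wgds_on_lineage(d)) for _, d in merge.donors)
    if genome_id not in tree.tip_names():
        raise ValueError(f"unknown genome {genome_id!r}")
    return 2 ** len(tree.wgds_on_lineage(genome_id))


#: identity differences below this many percentage points are treated as one
#: similarity layer, within which collinear gene number decides the ranking
IDENTITY_BIN = 3.0


def _rank_key(lb: LabeledBlock):
    return (
        -math.floor(lb.block.mean_identity / IDENTITY_BIN),
        -lb.block.size,
        -lb.block.mean_identity,
        lb.block.block_id,
    )


def _is_tie(a: LabeledBlock, b: LabeledBlock) -> bool:
    return (
        a.block.size == b.block.size
        and abs(a.block.mean_identity - b.block.mean_identity) < 1e-12
    )


@dataclass
class _Verdict:
    primary_frac: float
    primary_slot: int  # most common winning slot, 0-based
    secondary_frac: float
    secondary_slot: int
    tie_frac: float


def _position_competition(
    views: list[LabeledBlock], quota: int
) -> list[_Verdict]:
    """Rank competing blocks position-by-position along the reference.

    At every covered reference rank, the blocks spanning it are ordered by
    (identity layer, size, identity); the first ``quota`` take the primary
    slots, the next ``quota`` the secondary (outparalog) slots.  Each view's
    verdict records the fraction of its own span where it wins each slot
    class, and where an exact (size, identity) tie straddles the primary
    acceptance boundary.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, v in enumerate(views):
        by_chrom.setdefault(v.ref_chromosome(), []).append(i)
    p_wins = [Counter() for _ in views]
    s_wins = [Counter() for _ in views]
    ties = [0] * len(views)
    for idxs in by_chrom.values():
        positions: dict[int, list[int]] = {}
        for i in idxs:
            lo, hi = views[i].ref_span()
            for p in range(lo, hi + 1):
                positions.setdefault(p, []).append(i)
        for p, cover in positions.items():
            order = sorted(cover, key=lambda i: _rank_key(views[i]))
            for s, i in enumerate(order):
                if s < quota:
                    p_wins[i][s] += 1
                elif s < 2 * quota:
                    s_wins[i][s - quota] += 1
            if len(order) > quota and _is_tie(
                views[order[quota - 1]], views[order[quota]]
            ):
                ties[order[quota - 1]] += 1
                ties[order[quota]] += 1
    out = []
    for i, v in enumerate(views):
        lo, hi = v.ref_span()
        span = hi - lo + 1
        pf = sum(p_wins[i].values()) / span
        sf = sum(s_wins[i].values()) / span
        p_slot = min(p_wins[i], key=lambda s: (-p_wins[i][s], s), default=0)
        s_slot = min(s_wins[i], key=lambda s: (-s_wins[i][s], s), default=0)
        out.append(_Verdict(pf, p_slot, sf, s_slot, ties[i] / span))
    return out


def classify_blocks(
    blocks: list[CollinearBlock],
    tree: EventTree,
    ref: str,
) -> list[LabeledBlock]:
    """Label blocks involving the reference genome, plus all within-genome
    blocks, with the event that created their homology.

    Competition is local: at every reference gene rank, the blocks of one
    target genome spanning it are ranked by (identity layer, collinear gene
    number, identity) and the top ``expected_multiplicity/2`` slots are the
    ortholog tracks, the next slots the shared-WGD outparalog tracks.  A
    block adopts the slot class it wins over the majority of its span;
    within-genome blocks are assigned to the youngest polyploidy of their
    lineage first.  An exact (size, identity) tie across the acceptance
    boundary leaves the tied blocks unassigned.
    """
    root_wgd = tree.root.branch_wgds[0].id if tree.root.branch_wgds else None
    events = tree.events()

    wrapped: list[LabeledBlock] = []
    for b in sorted(blocks, key=lambda b: b.block_id):
        if b.genome_a == b.genome_b:
            wrapped.append(LabeledBlock(b, EventLabel("unassigned", None, 0.0), 0, "a"))
        elif b.genome_a == ref or b.genome_b == ref:
            side = "a" if b.genome_a == ref else "b"
            wrapped.append(LabeledBlock(b, EventLabel("unassigned", None, 0.0), 0, side))
        # blocks between two non-reference genomes are outside the layered
        # classification (they feed only the pairwise homology summaries)

    out: list[LabeledBlock] = []
    by_group: dict[tuple[str, str], list[LabeledBlock]] = {}
    for lb in wrapped:
        kind = "self" if lb.block.genome_a == lb.block.genome_b else "cross"
        by_group.setdefault((lb.target_genome, kind), []).append(lb)

    for (genome, kind), items in sorted(by_group.items()):
        if kind == "cross":
            out.extend(_classify_cross(items, genome, tree, ref, root_wgd))
        else:
            out.extend(_classify_self(items, genome, tree, root_wgd))
    return out


def _verdict_label(
    lb: LabeledBlock,
    verdict: _Verdict,
    relation: str,
    event_id: str | None,
    fallback_event: str | None,
) -> LabeledBlock:
    if verdict.tie_frac >= 0.5:
        log.info(
            "unresolvable (size, identity) tie at quota boundary: %s",
            lb.block.block_id,
        )
        return LabeledBlock(lb.block, EventLabel("unassigned", None, 0.0), 0,
                            lb.ref_side)
    if verdict.primary_frac >= 0.5:
        return LabeledBlock(
            lb.block,
            EventLabel(relation, event_id, verdict.primary_frac),
            verdict.primary_slot + 1, lb.ref_side)
    if fallback_event is None:
        return LabeledBlock(lb.block, EventLabel("unassigned", None, 0.0), 0,
                            lb.ref_side)
    track = verdict.secondary_slot + 1 if verdict.secondary_frac >= 0.5 else 0
    conf = max(verdict.secondary_frac, 1.0 - verdict.primary_frac - verdict.secondary_frac)
    return LabeledBlock(
        lb.block, EventLabel("gct_paralog", fallback_event, min(1.0, conf)),
        track, lb.ref_side)


def _classify_cross(
    items: list[LabeledBlock],
    genome: str,
    tree: EventTree,
    ref: str,
    root_wgd: str | None,
) -> list[LabeledBlock]:
    quota = expected_multiplicity(genome, tree) // 2
    merge = tree.merge_for(genome)
    ref_tip = ref
    ref_merge = tree.merge_for(ref)
    if ref_merge is not None:
        ref_tip = ref_merge.donors[0][1]
    if merge is not None:
        # oldest divergence among the donors, so co-orthologs of every
        # subgenome fall under one speciation event
        spec = max(
            (tree.speciation_between(ref_tip, d) for _, d in merge.donors),
            key=lambda e: e.time,
        )
    else:
        spec = tree.speciation_between(ref_tip, genome)
    verdicts = _position_competition(items, quota)
    return [
        _verdict_label(lb, v, "ortholog", spec.id, root_wgd)
        for lb, v in zip(items, verdicts)
    ]


def _classify_self(
    items: list[LabeledBlock],
    genome: str,
    tree: EventTree,
    root_wgd: str | None,
) -> list[LabeledBlock]:
    merge = tree.merge_for(genome)
    if merge is not None:
        quota = len(merge.donors) - 1
        relation, event_id = "homoeolog_merge", merge.event.id
    else:
        lineage_wgds = tree.wgds_on_lineage(genome)
        extra = [w for w in lineage_wgds if root_wgd is None or w.id != root_wgd]
        if extra:
            # youngest lineage-specific WGD claims the top slot
            young = min(extra, key=lambda w: w.time)
            quota = 1
            relation, event_id = f"{young.id}_paralog", young.id
        else:
            # a once-duplicated diploid: every self block traces to the root WGD
            return [
                LabeledBlock(
                    lb.block, EventLabel("gct_paralog", root_wgd, 1.0), 1, lb.ref_side
                )
                if root_wgd is not None
                else LabeledBlock(lb.block, EventLabel("unassigned", None, 0.0), 0, lb.ref_side)
                for lb in items
            ]
    # a within-genome block competes on both of its chromosomes; its final
    # label is the best it achieves in either view (young events outrank
    # the shared root WGD)
    views: list[LabeledBlock] = []
    for lb in items:
        views.append(LabeledBlock(lb.block, lb.label, 0, "a"))
        if lb.block.chrom_a != lb.block.chrom_b:
            views.append(LabeledBlock(lb.block, lb.label, 0, "b"))
    verdicts = _position_competition(views, quota)
    labeled_views = [
        _verdict_label(v, verd, relation, event_id, root_wgd)
        for v, verd in zip(views, verdicts)
    ]
    precedence = {relation: 0, "gct_paralog": 1, "unassigned": 2}
    best: dict[str, LabeledBlock] = {}
    for v in labeled_views:
        cur = best.get(v.block.block_id)
        if cur is None or precedence[v.label.relation] < precedence[cur.label.relation]:
            best[v.block.block_id] = v
    return [best[lb.block.block_id] for lb in items]


# ---------------------------------------------------------------------------
# karyotype correspondence
# ---------------------------------------------------------------------------

def karyotype_map(
    labeled: list[LabeledBlock],
    ref_ann: GenomeAnnotation,
    subgenomes: Mapping[str, Mapping[str, str]] | None = None,
    coverage_min: float = 0.10,
    split_min: float = 0.20,
) -> pd.DataFrame:
    """Chromosome-level correspondence between the reference and each target.

    For every reference chromosome and target unit (a genome, or one
    subgenome of a merged polyploid when ``subgenomes`` names its chromosome
    prefixes), lists the target chromosomes whose ortholog-labeled blocks
    cover at least ``coverage_min`` of the reference chromosome's genes.  A
    reference chromosome backed by >= 2 target chromosomes each covering >=
    ``split_min`` is flagged split — the signature of a chromosome fission
    on the target lineage.
    """
    subgenomes = subgenomes or {}
    cover: dict[tuple[str, str, str], set[int]] = {}
    for lb in labeled:
        if lb.label.relation != "ortholog":
            continue
        tgt_genome = lb.target_genome
        anchors = lb.anchors_ref_first()
        tgt_chrom = (
            lb.block.chrom_b if lb.ref_side == "a" else lb.block.chrom_a
        )
        if tgt_genome in subgenomes and "." in tgt_chrom:
            unit = f"{tgt_genome}:{tgt_chrom.split('.', 1)[0]}"
        else:
            unit = tgt_genome
        key = (lb.ref_chromosome(), unit, tgt_chrom)
        cover.setdefault(key, set()).update(a[0] for a in anchors)
    rows = []
    for (ref_chrom, unit, tgt_chrom), ranks in sorted(cover.items()):
        n_ref = ref_ann.chromosome_length(ref_chrom)
        frac = len(ranks) / n_ref if n_ref else 0.0
        rows.append((ref_chrom, unit, tgt_chrom, frac))
    df = pd.DataFrame(
        rows, columns=["ref_chromosome", "target", "target_chromosome", "fraction"]
    )
    df = df[df["fraction"] >= coverage_min].reset_index(drop=True)
    if df.empty:
        df["split"] = pd.Series(dtype=bool)
        return df
    n_strong = (
        df[df["fraction"] >= split_min]
        .groupby(["ref_chromosome", "target"])
        .size()
        .rename("n_strong")
    )
    df = df.join(n_strong, on=["ref_chromosome", "target"])
    df["split"] = df["n_strong"].fillna(0).astype(int) >= 2
    return df.drop(columns=["n_strong"])


# ---------------------------------------------------------------------------
# truth-based evaluation
# ---------------------------------------------------------------------------

def recovery_metrics(
    labeled: list[LabeledBlock],
    truth: pd.DataFrame,
    genome_of: Mapping[str, str],
) -> pd.DataFrame:
    """Precision/recall/F1 per relation over anchor gene pairs.

    A pair predicted by a block inherits the block's relation
    (``homoeolog_merge`` is scored against the truth relation
    ``homoeolog``).  Recall is computed over truth pairs whose genome pair
    is covered by at least one labeled block, so comparisons the classifier
    never saw are out of scope.
    """
    covered: set[tuple[str, str]] = set()
    predicted: dict[tuple[str, str], str] = {}
    for lb in sorted(labeled, key=lambda lb: (-lb.block.size, lb.block.block_id)):
        covered.add(tuple(sorted((lb.block.genome_a, lb.block.genome_b))))
        if lb.label.relation == "unassigned":
            continue
        rel = lb.label.relation
        if rel == "homoeolog_merge":
            rel = "homoeolog"
        for (_, _, _, ga, gb) in lb.block.anchors:
            pair = tuple(sorted((ga, gb)))
            predicted.setdefault(pair, rel)

    t = truth.copy()
    t["pair"] = [
        tuple(sorted(p)) for p in zip(t["gene_a"], t["gene_b"])
    ]
    t["gpair"] = [
        tuple(sorted((genome_of.get(a, "?"), genome_of.get(b, "?"))))
        for a, b in zip(t["gene_a"], t["gene_b"])
    ]
    in_scope = t[t["gpair"].isin(covered)]
    truth_rel = dict(zip(in_scope["pair"], in_scope["relation"]))

    relations = sorted(
        set(truth_rel.values()) | set(predicted.values())
    )
    rows = []
    for rel in relations:
        tp = sum(
            1 for pair, r in predicted.items() if r == rel and truth_rel.get(pair) == rel
        )
        n_pred = sum(1 for r in predicted.values() if r == rel)
        n_true = sum(1 for r in truth_rel.values() if r == rel)
        precision = tp / n_pred if n_pred else 0.0
        recall = tp / n_true if n_true else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        rows.append((rel, n_pred, n_true, tp, precision, recall, f1))
    return pd.DataFrame(
        rows,
        columns=["relation", "n_predicted", "n_truth", "tp", "precision", "recall", "f1"],
    )


LABELED_TSV_COLUMNS = [
    "block_id", "genome_a", "chrom_a", "genome_b", "chrom_b", "size",
    "mean_identity", "pvalue", "relation", "event_id", "subgenome_track",
    "confidence", "ref_side",
]


def read_labeled_blocks(labeled_path, anchors_path) -> list[LabeledBlock]:
    """Reload labeled blocks from the TSVs written by write_labeled_blocks
    and the block-anchor membership file."""
    meta = pd.read_csv(labeled_path, sep="\t", comment="#", keep_default_na=False)
    amem = pd.read_csv(anchors_path, sep="\t", comment="#")
    grouped = {
        str(bid): sorted(
            (int(r.rank_a), int(r.rank_b), float(r.identity), str(r.gene_a),
             str(r.gene_b))
            for r in grp.itertuples(index=False)
        )
        for bid, grp in amem.groupby("block_id", sort=False)
    }
    out = []
    for r in meta.itertuples(index=False):
        anchors = grouped.get(str(r.block_id), [])
        orientation = "parallel"
        if len(anchors) >= 2 and anchors[1][1] < anchors[0][1]:
            orientation = "inverted"
        b = CollinearBlock(
            genome_a=str(r.genome_a), chrom_a=str(r.chrom_a),
            genome_b=str(r.genome_b), chrom_b=str(r.chrom_b),
            anchors=anchors, orientation=orientation,
            block_id=str(r.block_id), pvalue=float(r.pvalue),
        )
        event = None if r.event_id in (".", "") else str(r.event_id)
        out.append(
            LabeledBlock(
                block=b,
                label=EventLabel(str(r.relation), event, float(r.confidence)),
                subgenome_track=int(r.subgenome_track),
                ref_side=str(r.ref_side),
            )
        )
    return out


def write_labeled_blocks(labeled: list[LabeledBlock], path) -> None:
    from .io import _header_line

    with open(path, "w") as fh:
        fh.write(_header_line() + "\n")
        fh.write("\t".join(LABELED_TSV_COLUMNS) + "\n")
        for lb in labeled:
            b = lb.block
            fh.write(
                f"{b.block_id}\t{b.genome_a}\t{b.chrom_a}\t{b.genome_b}\t{b.chrom_b}"
                f"\t{b.size}\t{b.mean_identity:.2f}\t{b.pvalue:.6g}"
                f"\t{lb.label.relation}\t{lb.label.event_id or '.'}"
                f"\t{lb.subgenome_track}\t{lb.label.confidence:.3f}\t{lb.ref_side}\n"
            )
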