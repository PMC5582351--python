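"""From homology hits to per-chromosome-pair anchor sets.

The stage applies the two hit filters used throughout grass comparative
genomics — an E-value cutoff (default E < 1e-5) and a best-N rule (default
top five matches per query per target genome) — collapses tandem arrays to a
single representative gene, and projects the surviving hits onto gene-rank
coordinates, one anchor set per pair of chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .model import HIT_COLUMNS, Gene, GenomeAnnotation

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """Hit-filtering parameters.

    max_evalue
        keep hits with E-value strictly below this (default 1e-5).
    top_n
        per query and per target genome, keep the best ``top_n`` hits by
        bitscore (default 5).
    tandem_max_gap
        within-genome homologs at rank distance <= this are one tandem array
        (default 1, i.e. adjacent genes).
    """

    max_evalue: float = 1e-5
    top_n: int = 5
    tandem_max_gap: int = 1

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.tandem_max_gap < 1:
            raise ValueError("tandem_max_gap must be >= 1")


@dataclass
class AnchorSet:
    """Anchors (homologous gene pairs in rank coordinates) between two
    chromosomes.

    ``len_a``/``len_b`` carry the chromosome lengths in rank units; they are
    the grid dimensions of the block-significance null model.
    """

    genome_a: str
    chrom_a: str
    genome_b: str
    chrom_b: str
    len_a: int
    len_b: int
    #: rows (rank_a, rank_b, identity, gene_a, gene_b), sorted by (rank_a, rank_b)
    anchors: list[tuple[int, int, float, str, str]] = field(default_factory=list)

    @property
    def key(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return ((self.genome_a, self.chrom_a), (self.genome_b, self.chrom_b))

    def __len__(self) -> int:
        return len(self.anchors)


def filter_hits(
    hits: pd.DataFrame,
    params: FilterParams = FilterParams(),
    genome_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Apply the E-value cutoff and the per-query, per-target-genome best-N rule.

    ``genome_of`` maps gene ids to genome ids; without it all subjects count
    as a single target genome.  The operation is idempotent.
    """
    if hits.empty:
        return hits.copy()
    kept = hits[hits["evalue"] < params.max_evalue].copy()
    if kept.empty:
        return kept.reset_index(drop=True)
    if genome_of is None:
        kept["_tgenome"] = ""
    else:
        kept["_tgenome"] = kept["subject"].map(genome_of)
    # rank best-first: bitscore desc, identity desc, subject id asc
    kept = kept.sort_values(
        ["query", "_tgenome", "bitscore", "identity", "subject"],
        ascending=[True, True, False, False, True],
        kind="mergesort",
    )
    kept["_rank"] = kept.groupby(["query", "_tgenome"]).cumcount()
    kept = kept[kept["_rank"] < params.top_n]
    return kept[HIT_COLUMNS].sort_values(HIT_COLUMNS[:2], kind="mergesort").reset_index(
        drop=True
    )


def tandem_arrays(
    ann: GenomeAnnotation,
    hits: pd.DataFrame,
    params: FilterParams = FilterParams(),
) -> list[list[Gene]]:
    """Group genes of one genome into tandem arrays.

    Two genes are tandem partners when they appear as a within-genome hit pair
    and sit on the same chromosome at rank distance <= ``tandem_max_gap``;
    arrays are the transitive closure of that relation.  Only arrays of two or
    more genes are returned, each sorted by rank.
    """
    idx = ann.gene_index
    graph = nx.Graph()
    pairs = hits[hits["query"].isin(idx) & hits["subject"].isin(idx)]
    for row in pairs.itertuples(index=False):
        ga, gb = idx[row.query], idx[row.subject]
        if ga.chromosome == gb.chromosome and abs(ga.rank - gb.rank) <= params.tandem_max_gap:
            graph.add_edge(ga.gene_id, gb.gene_id)
    arrays = []
    for comp in nx.connected_components(graph):
        if len(comp) >= 2:
            arrays.append(sorted((idx[g] for g in comp), key=lambda g: g.rank))
    arrays.sort(key=lambda a: (a[0].chromosome, a[0].rank))
    return arrays


def collapse_tandems(
    ann: GenomeAnnotation,
    hits: pd.DataFrame,
    params: FilterParams = FilterParams(),
) -> tuple[GenomeAnnotation, pd.DataFrame]:
    """Replace each tandem array by its lowest-rank representative.

    The returned annotation keeps the original rank values (gaps are measured
    on the original gene order); hits are rewritten onto representatives,
    rows that become self-hits are dropped, and duplicate (query, subject)
    rows are merged keeping the best bitscore.
    """
    arrays = tandem_arrays(ann, hits, params)
    rep_of: dict[str, str] = {}
    drop: set[str] = set()
    for arr in arrays:
        rep = arr[0].gene_id
        for g in arr[1:]:
            rep_of[g.gene_id] = rep
            drop.add(g.gene_id)
    if drop:
        log.info(
            "%s: collapsed %d tandem arrays (%d genes removed)",
            ann.genome_id, len(arrays), len(drop),
        )
    chroms = {
        chrom: [g for g in genes if g.gene_id not in drop]
        for chrom, genes in ann.chromosomes.items()
    }
    new_ann = GenomeAnnotation(
        genome_id=ann.genome_id, chromosomes=chroms, rank_gaps_ok=True
    )
    new_hits = hits.copy()
    new_hits["query"] = new_hits["query"].map(lambda g: rep_of.get(g, g))
    new_hits["subject"] = new_hits["subject"].map(lambda g: rep_of.get(g, g))
    new_hits = new_hits[new_hits["query"] != new_hits["subject"]]
    new_hits = (
        new_hits.sort_values(
            ["query", "subject", "bitscore", "identity"],
            ascending=[True, True, False, False],
            kind="mergesort",
        )
        .drop_duplicates(["query", "subject"], keep="first")
        .reset_index(drop=True)
    )
    return new_ann, new_hits


def build_anchor_sets(
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
    hits: pd.DataFrame,
) -> list[AnchorSet]:
    """Project filtered hits between two genomes onto rank coordinates.

    Returns one :class:`AnchorSet` per chromosome pair with at least one
    anchor.  For a self-comparison (``ann_a`` is the same genome as
    ``ann_b``) the trivial self-diagonal is excluded and each unordered gene
    pair appears once, on the canonically ordered chromosome pair
    (lexicographically; equal chromosomes use the rank_a <= rank_b
    convention).
    """
    self_cmp = ann_a.genome_id == ann_b.genome_id
    idx_a = ann_a.gene_index
    idx_b = ann_b.gene_index
    pools: dict[tuple[str, str], dict[tuple[int, int], tuple[float, str, str]]] = {}

    def add(ga: Gene, gb: Gene, ident: float) -> None:
        if self_cmp:
            if ga.gene_id == gb.gene_id:
                return
            if (ga.chromosome, ga.rank) > (gb.chromosome, gb.rank):
                ga, gb = gb, ga
        key = (ga.chromosome, gb.chromosome)
        pool = pools.setdefault(key, {})
        rk = (ga.rank, gb.rank)
        prev = pool.get(rk)
        cand = (ident, ga.gene_id, gb.gene_id)
        if prev is None or cand > prev:
            pool[rk] = cand

    ordered = hits.sort_values(HIT_COLUMNS[:2], kind="mergesort")
    for row in ordered.itertuples(index=False):
        q_a, s_b = idx_a.get(row.query), idx_b.get(row.subject)
        q_b, s_a = idx_b.get(row.query), idx_a.get(row.subject)
        if q_a is None and q_b is None:
            raise ValueError(f"gene {row.query!r} not found in either annotation")
        if s_a is None and s_b is None:
            raise ValueError(f"gene {row.subject!r} not found in either annotation")
        if q_a is not None and s_b is not None:
            add(q_a, s_b, row.identity)
        elif not self_cmp and q_b is not None and s_a is not None:
            add(s_a, q_b, row.identity)
        # rows not connecting ann_a to ann_b are silently out of scope

    out: list[AnchorSet] = []
    for (ca, cb) in sorted(pools):
        pool = pools[(ca, cb)]
        anchors = [
            (ra, rb, val[0], val[1], val[2])
            for (ra, rb), val in sorted(pool.items())
        ]
        out.append(
            AnchorSet(
                genome_a=ann_a.genome_id,
                chrom_a=ca,
                genome_b=ann_b.genome_id,
                chrom_b=cb,
                len_a=ann_a.chromosome_length(ca),
                len_b=ann_b.chromosome_length(cb),
                anchors=anchors,
            )
        )
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

ANCHOR_TSV_COLUMNS = [
    "genome_a", "chrom_a", "genome_b", "chrom_b",
    "len_a", "len_b", "rank_a", "rank_b", "gene_a", "gene_b", "identity",
]


def write_anchor_sets(asets: list[AnchorSet], path: str | Path) -> None:
    from .io import _header_line

    with open(Path(path), "w") as fh:
        fh.write(_header_line() + "\n")
        fh.write("\t".join(ANCHOR_TSV_COLUMNS) + "\n")
        for a in asets:
            for (ra, rb, ident, ga, gb) in a.anchors:
                fh.write(
                    f"{a.genome_a}\t{a.chrom_a}\t{a.genome_b}\t{a.chrom_b}"
                    f"\t{a.len_a}\t{a.len_b}\t{ra}\t{rb}\t{ga}\t{gb}\t{ident:.2f}\n"
                )


def read_anchor_sets(path: str | Path) -> list[AnchorSet]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    if df.empty:
        return out
    for key, grp in df.groupby(
        ["genome_a", "chrom_a", "genome_b", "chrom_b", "len_a", "len_b"], sort=True
    ):
        ga, ca, gb, cb, la, lb = key
        anchors = sorted(
            (int(r.rank_a), int(r.rank_b), float(r.identity), str(r.gene_a), str(r.gene_b))
            for r in grp.itertuples(index=False)
        )
        out.append(
            AnchorSet(
                genome_a=str(ga), chrom_a=str(ca), genome_b=str(gb), chrom_b=str(cb),
                len_a=int(la), len_b=int(lb), anchors=anchors,
            )
        )
    return out
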