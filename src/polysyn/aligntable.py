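"""Reference-anchored multi-genome alignment table and homology summaries.

The table has one row per reference gene and a fixed column schema derived
from the event tree: the reference contributes two columns (its gene and the
shared-WGD paralog), and every other genome contributes one column per
subgenome copy and per reference column — 24 columns in total for the
nine-genome grass configuration.  A cell holds the collinear homolog
assigned to that (row, column), or a dot when no gene fills the expected
location (loss, translocation or assembly gap; the table does not
distinguish them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .classify import LabeledBlock, expected_multiplicity
from .collinearity import CollinearBlock
from .model import GenomeAnnotation
from .simulate import EventTree

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Column:
    genome_id: str
    track: int  # 1-based subgenome slot
    parent: int  # which reference column (1 or 2) this column is orthologous to

    @property
    def name(self) -> str:
        return f"{self.genome_id}.p{self.parent}.t{self.track}"


@dataclass
class ColumnSchema:
    reference: str
    columns: list[Column]

    def column_names(self) -> list[str]:
        names = [f"{self.reference}.1", f"{self.reference}.2"]
        names += [c.name for c in self.columns[2:]]
        return names

    def index_of(self, genome_id: str, parent: int, track: int) -> int | None:
        key = Column(genome_id, track, parent)
        try:
            return self.columns.index(key)
        except ValueError:
            return None

    def __len__(self) -> int:
        return len(self.columns)


@dataclass
class TableRow:
    ref_chromosome: str
    ref_rank: int
    ref_gene: str
    ref_start_bp: int
    ref_end_bp: int
    cells: dict[int, str | None] = field(default_factory=dict)


@dataclass
class AlignmentTable:
    schema: ColumnSchema
    rows: list[TableRow]

    @property
    def n_missing(self) -> int:
        total = 0
        for row in self.rows:
            total += sum(
                1 for i in range(len(self.schema)) if not row.cells.get(i)
            )
        return total

    def column_cells(self, index: int) -> list[str | None]:
        return [row.cells.get(index) for row in self.rows]


def allocate_columns(tree: EventTree, ref: str) -> ColumnSchema:
    """Build the deterministic column schema for a reference genome.

    The reference's two shared-WGD columns come first, then every other
    genome in tree order with its orthologous (parent-1) tracks followed by
    its outparalogous (parent-2) tracks.
    """
    if not tree.has_root_wgd():
        raise ValueError(
            "event tree has no root WGD: the two reference columns are "
            "defined by the shared polyploidization"
        )
    if expected_multiplicity(ref, tree) != 2:
        raise ValueError(
            f"reference {ref!r} must be a diploid descendant of the root WGD"
        )
    cols = [Column(ref, 1, 1), Column(ref, 1, 2)]
    for genome in tree.genome_ids():
        if genome == ref:
            continue
        k = expected_multiplicity(genome, tree) // 2
        for parent in (1, 2):
            for track in range(1, k + 1):
                cols.append(Column(genome, track, parent))
    return ColumnSchema(reference=ref, columns=cols)


def fill_table(
    schema: ColumnSchema,
    labeled: list[LabeledBlock],
    annotations: dict[str, GenomeAnnotation],
) -> AlignmentTable:
    """Place every anchor of the classified blocks into the table.

    Ortholog-labeled blocks feed the parent-1 column of their subgenome
    track; shared-WGD outparalog blocks feed parent-2; reference self blocks
    feed the reference's second column symmetrically.  Cell conflicts are
    resolved by larger block, then higher identity, then lexicographic gene
    id; each target gene occupies at most one cell per column.
    """
    ref = schema.reference
    ref_ann = annotations[ref]
    rows: list[TableRow] = []
    row_of: dict[str, int] = {}
    for chrom in sorted(ref_ann.chromosomes):
        for g in ref_ann.chromosomes[chrom]:
            row_of[g.gene_id] = len(rows)
            rows.append(
                TableRow(chrom, g.rank, g.gene_id, g.start_bp, g.end_bp,
                         {0: g.gene_id})
            )

    # candidate cell writes: (priority, row, col, gene)
    candidates: list[tuple[tuple, int, int, str]] = []

    def priority(block: CollinearBlock, gene: str) -> tuple:
        return (-block.size, -block.mean_identity, gene, block.block_id)

    n_unplaced = 0
    for lb in labeled:
        b = lb.block
        if b.genome_a == ref and b.genome_b == ref:
            if lb.label.relation == "unassigned":
                continue
            for (ra, rb, ident, ga, gb) in b.anchors:
                for src, dst in ((ga, gb), (gb, ga)):
                    if src not in row_of:
                        raise ValueError(f"anchor references unknown reference gene {src!r}")
                    candidates.append((priority(b, dst), row_of[src], 1, dst))
            continue
        if ref not in (b.genome_a, b.genome_b):
            continue
        if lb.label.relation == "ortholog":
            parent = 1
        elif lb.label.relation == "gct_paralog":
            parent = 2
        else:
            continue
        if lb.subgenome_track < 1:
            n_unplaced += 1
            continue
        col = schema.index_of(lb.target_genome, parent, lb.subgenome_track)
        if col is None:
            n_unplaced += 1
            continue
        for (rr, _tr, ident, rg, tg) in lb.anchors_ref_first():
            if rg not in row_of:
                raise ValueError(f"anchor references unknown reference gene {rg!r}")
            candidates.append((priority(b, tg), row_of[rg], col, tg))
    if n_unplaced:
        log.info("%d blocks exceeded their genome's column quota", n_unplaced)

    candidates.sort(key=lambda c: c[0])
    used: dict[int, set[str]] = {}
    n_conflicts = 0
    for _prio, row_i, col, gene in candidates:
        row = rows[row_i]
        if row.cells.get(col) is not None:
            n_conflicts += 1
            continue
        col_used = used.setdefault(col, set())
        if gene in col_used:
            n_conflicts += 1
            continue
        row.cells[col] = gene
        col_used.add(gene)
    if n_conflicts:
        log.info("%d anchor placements lost cell conflicts", n_conflicts)
    return AlignmentTable(schema=schema, rows=rows)


def extract_region(
    table: AlignmentTable,
    ref_chromosome: str,
    rank_start: int | None = None,
    rank_end: int | None = None,
    bp_start: int | None = None,
    bp_end: int | None = None,
) -> AlignmentTable:
    """Contiguous rows of one reference chromosome, all columns retained.

    Rank intervals are inclusive on both ends; bp intervals are inclusive
    and select rows whose reference gene lies entirely inside the interval.
    An empty region yields an empty sub-table.
    """
    by_rank = rank_start is not None or rank_end is not None
    by_bp = bp_start is not None or bp_end is not None
    if by_rank and by_bp:
        raise ValueError("specify a rank interval or a bp interval, not both")
    picked = []
    for row in table.rows:
        if row.ref_chromosome != ref_chromosome:
            continue
        if by_rank:
            if rank_start is not None and row.ref_rank < rank_start:
                continue
            if rank_end is not None and row.ref_rank > rank_end:
                continue
        elif by_bp:
            if bp_start is not None and row.ref_start_bp < bp_start:
                continue
            if bp_end is not None and row.ref_end_bp > bp_end:
                continue
        picked.append(row)
    return AlignmentTable(schema=table.schema, rows=picked)


# ---------------------------------------------------------------------------
# pairwise homology summaries
# ---------------------------------------------------------------------------

@dataclass
class HomologySummary:
    """Block / gene-pair / gene counts per genome (or subgenome) pair.

    ``block_counts[t]`` and ``pair_counts[t]`` are symmetric unit x unit
    matrices counting blocks of size >= t and their collinear gene pairs.
    ``gene_counts`` gives distinct collinear genes belonging to the *row*
    unit (so cell (i, j) and cell (j, i) report the two sides of one
    comparison); ``gene_pct`` scales those by each unit's annotated gene
    count.
    """

    units: list[str]
    thresholds: tuple[int, ...]
    block_counts: dict[int, pd.DataFrame]
    pair_counts: dict[int, pd.DataFrame]
    gene_counts: pd.DataFrame
    gene_pct: pd.DataFrame

    def to_files(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for t in self.thresholds:
            self.block_counts[t].to_csv(outdir / f"blocks_ge{t}.tsv", sep="\t")
            self.pair_counts[t].to_csv(outdir / f"gene_pairs_ge{t}.tsv", sep="\t")
        self.gene_counts.to_csv(outdir / "genes.tsv", sep="\t")
        self.gene_pct.round(1).to_csv(outdir / "gene_pct.tsv", sep="\t")


def _unit_of(genome: str, chrom: str, subgenomes) -> str:
    if subgenomes and genome in subgenomes and "." in chrom:
        return f"{genome}:{chrom.split('.', 1)[0]}"
    return genome


def summarize_homology(
    blocks: list[CollinearBlock],
    annotations: dict[str, GenomeAnnotation],
    thresholds: tuple[int, ...] = (4, 10, 20, 50),
    subgenomes: dict[str, dict[str, str]] | None = None,
) -> HomologySummary:
    """Count blocks, collinear gene pairs and distinct collinear genes per
    genome pair at nested block-size thresholds.

    When ``subgenomes`` names the chromosome prefixes of a merged polyploid,
    that genome is split into per-subgenome units so homoeologous and
    within-subgenome homology are reported separately.
    """
    thresholds = tuple(sorted(thresholds))
    units: list[str] = []
    annotated: dict[str, int] = {}
    for genome, ann in annotations.items():
        labels = sorted(subgenomes[genome]) if subgenomes and genome in subgenomes else None
        if labels:
            for lab in labels:
                unit = f"{genome}:{lab}"
                units.append(unit)
                annotated[unit] = sum(
                    len(genes) for chrom, genes in ann.chromosomes.items()
                    if chrom.split(".", 1)[0] == lab
                )
        else:
            units.append(genome)
            annotated[genome] = ann.n_genes

    def zeros() -> pd.DataFrame:
        return pd.DataFrame(0, index=units, columns=units)

    block_counts = {t: zeros() for t in thresholds}
    pair_counts = {t: zeros() for t in thresholds}
    genes_by_pair: dict[tuple[str, str], tuple[set, set]] = {}

    for b in blocks:
        ua = _unit_of(b.genome_a, b.chrom_a, subgenomes)
        ub = _unit_of(b.genome_b, b.chrom_b, subgenomes)
        side_a = [a[3] for a in b.anchors]
        side_b = [a[4] for a in b.anchors]
        if units.index(ua) > units.index(ub):
            ua, ub = ub, ua
            side_a, side_b = side_b, side_a
        for t in thresholds:
            if b.size >= t:
                block_counts[t].loc[ua, ub] += 1
                pair_counts[t].loc[ua, ub] += b.size
        if b.size >= thresholds[0]:
            sa, sb = genes_by_pair.setdefault((ua, ub), (set(), set()))
            sa.update(side_a)
            sb.update(side_b)

    for t in thresholds:
        for df in (block_counts[t], pair_counts[t]):
            upper = df.to_numpy()
            sym = upper + upper.T
            for i in range(len(units)):
                sym[i, i] = upper[i, i]
            df.loc[:, :] = sym

    gene_counts = zeros()
    for (ua, ub), (sa, sb) in genes_by_pair.items():
        if ua == ub:
            gene_counts.loc[ua, ub] = len(sa | sb)
        else:
            gene_counts.loc[ua, ub] = len(sa)
            gene_counts.loc[ub, ua] = len(sb)
    gene_pct = gene_counts.astype(float)
    for u in units:
        n = annotated[u] or 1
        gene_pct.loc[u, :] = gene_counts.loc[u, :] / n * 100.0

    return HomologySummary(
        units=units,
        thresholds=thresholds,
        block_counts=block_counts,
        pair_counts=pair_counts,
        gene_counts=gene_counts,
        gene_pct=gene_pct,
    )
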