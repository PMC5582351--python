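"""Core in-memory data model shared by every pipeline stage.

Collinearity is computed in *gene-rank* coordinates: the i-th gene along a
chromosome has rank i (1-based), regardless of its base-pair span.  All gap
parameters downstream are expressed in genes, so the model stores both the
base-pair interval (as annotated) and the rank derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

#: Column order of the normalized homology-hit table.
HIT_COLUMNS = ["query", "subject", "identity", "evalue", "bitscore"]


@dataclass(frozen=True)
class Gene:
    """A single gene feature with both bp and rank coordinates.

    ``start_bp``/``end_bp`` are 1-based inclusive (GFF3 convention); ``rank``
    is the 1-based order index of the gene along its chromosome.
    """

    gene_id: str
    genome_id: str
    chromosome: str
    rank: int
    start_bp: int
    end_bp: int
    strand: str = "?"

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"gene {self.gene_id}: start_bp {self.start_bp} > end_bp {self.end_bp}"
            )


@dataclass
class GenomeAnnotation:
    """Ordered genes of one genome, grouped by chromosome.

    Invariants: gene ids are unique within the genome, and within each
    chromosome the stored ranks are exactly the list positions (1..n).
    """

    genome_id: str
    chromosomes: dict[str, list[Gene]] = field(default_factory=dict)
    #: True after tandem collapsing: ranks keep their original values, so the
    #: gap-free rank <-> position correspondence no longer holds.
    rank_gaps_ok: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for chrom, genes in self.chromosomes.items():
            prev_rank = 0
            for pos, g in enumerate(genes, start=1):
                if self.rank_gaps_ok:
                    if g.rank <= prev_rank:
                        raise ValueError(
                            f"{self.genome_id}/{chrom}: ranks not strictly "
                            f"increasing at {g.gene_id}"
                        )
                    prev_rank = g.rank
                elif g.rank != pos:
                    raise ValueError(
                        f"{self.genome_id}/{chrom}: gene {g.gene_id} has rank "
                        f"{g.rank} at list position {pos}"
                    )
                if g.chromosome != chrom:
                    raise ValueError(
                        f"{self.genome_id}: gene {g.gene_id} filed under {chrom} "
                        f"but annotated on {g.chromosome}"
                    )
                if g.gene_id in seen:
                    raise ValueError(
                        f"{self.genome_id}: duplicate gene id {g.gene_id!r}"
                    )
                seen.add(g.gene_id)

    # -- convenience accessors -------------------------------------------------

    def __iter__(self) -> Iterator[Gene]:
        for genes in self.chromosomes.values():
            yield from genes

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    @property
    def gene_index(self) -> dict[str, Gene]:
        """Mapping gene_id -> Gene (rebuilt on each call; cache if hot)."""
        return {g.gene_id: g for g in self}

    def chromosome_length(self, chrom: str) -> int:
        """Chromosome length in rank units (the largest assigned rank)."""
        genes = self.chromosomes[chrom]
        return genes[-1].rank if genes else 0

    @classmethod
    def from_genes(cls, genome_id: str, genes: Iterable[Gene]) -> "GenomeAnnotation":
        """Build an annotation, assigning ranks by (chromosome, start, end, id)."""
        by_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        chroms: dict[str, list[Gene]] = {}
        for chrom in sorted(by_chrom):
            ordered = sorted(
                by_chrom[chrom], key=lambda g: (g.start_bp, g.end_bp, g.gene_id)
            )
            chroms[chrom] = [
                Gene(
                    gene_id=g.gene_id,
                    genome_id=genome_id,
                    chromosome=chrom,
                    rank=i,
                    start_bp=g.start_bp,
                    end_bp=g.end_bp,
                    strand=g.strand,
                )
                for i, g in enumerate(ordered, start=1)
            ]
        return cls(genome_id=genome_id, chromosomes=chroms)


def empty_hit_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query": pd.Series(dtype=str),
            "subject": pd.Series(dtype=str),
            "identity": pd.Series(dtype=float),
            "evalue": pd.Series(dtype=float),
            "bitscore": pd.Series(dtype=float),
        }
    )


def normalize_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Return a hit table in canonical column order with self-hits removed."""
    out = hits.loc[hits["query"] != hits["subject"], HIT_COLUMNS].copy()
    return out.reset_index(drop=True)
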