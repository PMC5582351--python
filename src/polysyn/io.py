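"""Readers and writers for the standard interchange formats.

Supported formats:

* gene annotations — GFF3 (1-based inclusive; only features of a chosen type,
  ``gene`` by default) or a BED-like TSV (0-based half-open:
  ``chrom  start  end  gene_id  [score  strand]``);
* homology hits — 12-column BLAST tabular (``-outfmt 6``);
* the multi-genome alignment table — TSV with ``.`` for missing cells.

Readers are lossless: no filtering beyond dropping self-hits and malformed
numeric rows (counted).  Every writer emits a ``#`` comment line recording the
tool version and the parameters used.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from . import __version__
from .model import HIT_COLUMNS, Gene, GenomeAnnotation, normalize_hits

if TYPE_CHECKING:  # pragma: no cover
    from .aligntable import AlignmentTable

log = logging.getLogger(__name__)

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _header_line(params: dict | None = None) -> str:
    extra = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    return f"# polysyn {__version__}" + (f" {extra}" if extra else "")


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

def read_annotation(
    path: str | Path,
    format: str = "gff3",
    genome_id: str | None = None,
    feature_type: str = "gene",
) -> GenomeAnnotation:
    """Read a per-genome gene annotation and assign rank coordinates.

    Ranks are assigned by sorting genes on ``(chromosome, start, end, id)``,
    so they are a deterministic function of the file alone.

    Raises
    ------
    ValueError
        on a duplicate gene id (named in the message) or an annotation that
        yields zero genes.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    genes: list[Gene] = []
    seen: set[str] = set()
    if format == "gff3":
        import gffutils.iterators

        for feat in gffutils.iterators.DataIterator(str(path)):
            if feat.featuretype != feature_type:
                continue
            gid = feat.attributes.get("ID", [None])[0] or feat.attributes.get(
                "Name", [None]
            )[0]
            if gid is None:
                raise ValueError(
                    f"{path}: {feature_type} feature at {feat.seqid}:{feat.start} "
                    f"has no ID attribute"
                )
            _check_dup(gid, seen, path)
            genes.append(
                Gene(
                    gene_id=gid,
                    genome_id=genome_id,
                    chromosome=feat.seqid,
                    rank=0,
                    start_bp=feat.start,
                    end_bp=feat.end,
                    strand=feat.strand if feat.strand in "+-" else "?",
                )
            )
        if not genes:
            raise ValueError(
                f"{path}: no {feature_type!r} features found; if genes are "
                f"annotated under another feature type, pass feature_type=..."
            )
    elif format == "bed_tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: BED line has <4 columns")
                chrom, start, end, gid = fields[:4]
                strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "?"
                _check_dup(gid, seen, path)
                # BED is 0-based half-open; internal model is 1-based inclusive.
                genes.append(
                    Gene(
                        gene_id=gid,
                        genome_id=genome_id,
                        chromosome=chrom,
                        rank=0,
                        start_bp=int(start) + 1,
                        end_bp=int(end),
                        strand=strand,
                    )
                )
        if not genes:
            raise ValueError(f"{path}: annotation contains zero genes")
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return GenomeAnnotation.from_genes(genome_id, genes)


def _check_dup(gid: str, seen: set[str], path: Path) -> None:
    if gid in seen:
        raise ValueError(f"{path}: duplicate gene id {gid!r}")
    seen.add(gid)


def write_annotation(
    ann: GenomeAnnotation, path: str | Path, format: str = "gff3"
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            fh.write(_header_line({"genome": ann.genome_id}) + "\n")
            for g in ann:
                fh.write(
                    f"{g.chromosome}\tpolysyn\tgene\t{g.start_bp}\t{g.end_bp}\t."
                    f"\t{g.strand if g.strand in '+-' else '.'}\t."
                    f"\tID={g.gene_id}\n"
                )
        elif format == "bed_tsv":
            fh.write(_header_line({"genome": ann.genome_id}) + "\n")
            for g in ann:
                strand = g.strand if g.strand in "+-" else "."
                fh.write(
                    f"{g.chromosome}\t{g.start_bp - 1}\t{g.end_bp}\t{g.gene_id}"
                    f"\t0\t{strand}\n"
                )
        else:
            raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# homology hits (BLAST -outfmt 6)
# ---------------------------------------------------------------------------

def read_hits(path: str | Path) -> pd.DataFrame:
    """Read BLAST tabular hits into the normalized hit table.

    Rows whose numeric fields do not parse are dropped with a single counted
    warning; a row with fewer than 12 columns is a hard error (extra columns
    are ignored).  Self-hits (query == subject) are removed.
    """
    path = Path(path)
    rows: list[tuple[str, str, float, float, float]] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                rows.append(
                    (
                        fields[0],
                        fields[1],
                        float(fields[2]),
                        float(fields[10]),
                        float(fields[11]),
                    )
                )
            except ValueError:
                n_bad += 1
    if n_bad:
        warnings.warn(f"{path}: dropped {n_bad} rows with unparseable numeric fields")
        log.warning("%s: dropped %d malformed rows", path, n_bad)
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return normalize_hits(hits)


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    """Write a hit table as 12-column BLAST tabular.

    Only identity/evalue/bitscore are meaningful; alignment-coordinate columns
    are filled consistently (length 100, full-span coordinates).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_line({"columns": "outfmt6"}) + "\n")
        for row in hits.itertuples(index=False):
            fh.write(
                f"{row.query}\t{row.subject}\t{row.identity:.2f}\t100\t0\t0"
                f"\t1\t100\t1\t100\t{row.evalue:.3e}\t{row.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# alignment table
# ---------------------------------------------------------------------------

MISSING = "."


def write_alignment_table(table: "AlignmentTable", path: str | Path) -> None:
    """Write the multi-genome alignment table as TSV.

    The header row carries the column schema names; body rows are ordered by
    reference chromosome then rank, and empty cells are rendered as ``.``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_line({"reference": table.schema.reference}) + "\n")
        names = table.schema.column_names()
        meta = ["ref_chromosome", "ref_rank", "ref_start_bp", "ref_end_bp"]
        fh.write("\t".join(meta + names) + "\n")
        for row in table.rows:
            cells = [row.cells.get(i) or MISSING for i in range(len(names))]
            lead = [row.ref_chromosome, str(row.ref_rank), str(row.ref_start_bp),
                    str(row.ref_end_bp)]
            fh.write("\t".join(lead + cells) + "\n")


def read_alignment_table(path: str | Path) -> pd.DataFrame:
    """Read an alignment-table TSV back as a DataFrame (cells as strings)."""
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
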