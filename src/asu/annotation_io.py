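"""Gene models, UTR extension and annotation I/O.

All coordinates in this package are 0-based half-open. GFF3 input
(1-based closed) is converted on read. The 5' end of a half-open
interval on the '-' strand is its ``end`` coordinate and the 3' end is
its ``start``; that convention is stated here once and used everywhere.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, TextIO, Union

import gffutils.feature

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Annotation",
    "AnnotationError",
    "ParseError",
    "read_annotation",
    "read_utr_table",
    "read_bed_intervals",
    "write_bed_intervals",
    "write_annotation_bed",
    "transcript_span",
    "neighbors",
]

PathLike = Union[str, Path, TextIO]


class AnnotationError(ValueError):
    """Invalid annotation content (duplicate ids, unknown chromosome...)."""


class ParseError(AnnotationError):
    """A record that could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A stranded (or unstranded, strand='.') half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"interval start must precede end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """5'-most coordinate: start on '+', end on '-'."""
        return self.end if self.strand == "-" else self.start

    @property
    def three_prime(self) -> int:
        """3'-most coordinate: end on '+', start on '-'."""
        return self.start if self.strand == "-" else self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Length of the intersection with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between the two intervals; 0 when they overlap or touch."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.end <= other.start:
            return other.start - self.end
        if other.end <= self.start:
            return self.start - other.end
        return 0


@dataclass(frozen=True)
class GeneModel:
    """An annotated ORF with UTR extensions.

    ``utr5_len``/``utr3_len`` extend the ORF into the transcript span
    (the "known transcript boundaries"); when no measured estimate is
    available both default to 100 bp.
    """

    gene_id: str
    chrom: str
    strand: str
    orf_start: int
    orf_end: int
    utr5_len: int = 100
    utr3_len: int = 100

    def __post_init__(self):
        if self.orf_start >= self.orf_end:
            raise ValueError(
                f"{self.gene_id}: ORF start must precede end "
                f"({self.orf_start} >= {self.orf_end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError(f"{self.gene_id}: UTR lengths must be non-negative")

    @property
    def orf(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.orf_start, self.orf_end, self.strand, self.gene_id
        )


@dataclass
class Annotation:
    """A set of gene models plus chromosome lengths."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for gene in self.genes.values():
            self._check_chrom(gene)

    def _check_chrom(self, gene: GeneModel) -> None:
        if gene.chrom not in self.chrom_lengths:
            raise AnnotationError(
                f"gene {gene.gene_id} lies on unknown chromosome {gene.chrom!r}"
            )

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise AnnotationError(f"duplicate gene_id {gene.gene_id!r}")
        self._check_chrom(gene)
        self.genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterable[GeneModel]:
        return iter(self.genes.values())

    def on_chrom(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.chrom == chrom]


def transcript_span(gene: GeneModel, chrom_length: Optional[int] = None) -> GenomicInterval:
    """UTR-extended transcript span of a gene, clipped to the chromosome.

    On '+' the 5' UTR extends upstream of ``orf_start`` and the 3' UTR
    downstream of ``orf_end``; on '-' the roles are swapped. Clipping at
    chromosome bounds is silent: published UTR estimates can overrun
    contig ends.
    """
    if gene.strand == "+":
        start = gene.orf_start - gene.utr5_len
        end = gene.orf_end + gene.utr3_len
    else:
        start = gene.orf_start - gene.utr3_len
        end = gene.orf_end + gene.utr5_len
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(gene.chrom, start, end, gene.strand, gene.gene_id)


def annotation_spans(annotation: Annotation) -> dict[str, GenomicInterval]:
    """Transcript spans for every gene, clipped to their chromosomes."""
    return {
        g.gene_id: transcript_span(g, annotation.chrom_lengths.get(g.chrom))
        for g in annotation
    }


def neighbors(
    annotation: Annotation, interval: GenomicInterval, margin: int
) -> list[tuple[GeneModel, int]]:
    """Genes whose transcript span lies within ``margin`` bp of ``interval``.

    Returns (gene, distance) pairs; overlap counts as distance 0. Sorted
    by distance, ties broken by gene_id so the result is deterministic.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if interval.chrom not in annotation.chrom_lengths:
        raise AnnotationError(f"unknown chromosome {interval.chrom!r}")
    out = []
    for gene in annotation.on_chrom(interval.chrom):
        span = transcript_span(gene, annotation.chrom_lengths.get(gene.chrom))
        d = interval.distance_to(span)
        if d <= margin:
            out.append((gene, d))
    out.sort(key=lambda pair: (pair[1], pair[0].gene_id))
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _open_lines(source: PathLike):
    if hasattr(source, "read"):
        return source, False
    return open(source), True


def read_utr_table(source: PathLike) -> dict[str, tuple[int, int]]:
    """Read a TSV of (gene_id, utr5_len, utr3_len); '#' starts a comment."""
    handle, close = _open_lines(source)
    table: dict[str, tuple[int, int]] = {}
    try:
        for i, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"expected 3 tab-separated fields, got {len(parts)}", i)
            gene_id = parts[0]
            try:
                utr5, utr3 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"non-integer UTR length: {exc}", i) from None
            if utr5 < 0 or utr3 < 0:
                raise ParseError("UTR lengths must be non-negative", i)
            table[gene_id] = (utr5, utr3)
    finally:
        if close:
            handle.close()
    return table


def _parse_bed6_gene(parts: list[str], line_number: int) -> GeneModel:
    if len(parts) < 6:
        raise ParseError("BED gene records need 6 columns (strand required)", line_number)
    chrom, start_s, end_s, name, _score, strand = parts[:6]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ParseError("non-integer BED coordinates", line_number) from None
    if start >= end:
        raise ParseError(f"start >= end ({start} >= {end})", line_number)
    if strand not in ("+", "-"):
        raise ParseError(f"invalid strand {strand!r}", line_number)
    try:
        return GeneModel(name, chrom, strand, start, end)
    except ValueError as exc:
        raise ParseError(str(exc), line_number) from None


def _parse_gff3_gene(line: str, line_number: int) -> Optional[GeneModel]:
    try:
        feat = gffutils.feature.feature_from_line(line)
    except Exception as exc:
        raise ParseError(f"malformed GFF3 record: {exc}", line_number) from None
    if feat.featuretype != "gene":
        return None
    gene_id = (feat.attributes.get("ID") or feat.attributes.get("Name") or [None])[0]
    if gene_id is None:
        raise ParseError("gene record without ID or Name attribute", line_number)
    if feat.strand not in ("+", "-"):
        raise ParseError(f"gene {gene_id}: invalid strand {feat.strand!r}", line_number)
    if feat.start > feat.end:
        raise ParseError(f"gene {gene_id}: start > end", line_number)
    # GFF3 is 1-based closed; convert to 0-based half-open.
    return GeneModel(gene_id, feat.seqid, feat.strand, feat.start - 1, feat.end)


def read_annotation(
    source: PathLike,
    utr_table: Optional[Union[PathLike, Mapping[str, tuple[int, int]]]] = None,
    default_utr: int = 100,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    fmt: Optional[str] = None,
) -> Annotation:
    """Read gene models from GFF3 (feature type ``gene``) or BED6/BED12.

    Parameters
    ----------
    source
        Path or open handle. Format is auto-detected (GFF3 when the file
        carries a ``##gff-version`` pragma or 9 columns with a GFF
        attribute field) unless ``fmt`` is ``"gff3"`` or ``"bed"``.
    utr_table
        Optional path/handle of a (gene_id, utr5, utr3) TSV, or an
        equivalent mapping. Genes without a row get ``default_utr`` on
        both sides.
    chrom_lengths
        Known chromosome lengths. Any chromosome not listed is sized to
        the right-most transcript end observed on it, so UTR clipping
        never truncates input genes by default.
    """
    if utr_table is None:
        utrs: Mapping[str, tuple[int, int]] = {}
    elif isinstance(utr_table, Mapping):
        utrs = utr_table
    else:
        utrs = read_utr_table(utr_table)

    handle, close = _open_lines(source)
    genes: dict[str, GeneModel] = {}
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()

    lines = text.splitlines()
    if fmt is None:
        fmt = "bed"
        for line in lines:
            if line.startswith("##gff-version"):
                fmt = "gff3"
                break
            if line.startswith("#") or not line.strip():
                continue
            ncol = len(line.split("\t"))
            if ncol == 9 and ("=" in line.split("\t")[8] or line.split("\t")[8] == "."):
                fmt = "gff3"
            break

    for i, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if fmt == "gff3":
            gene = _parse_gff3_gene(line, i)
            if gene is None:
                continue
        else:
            gene = _parse_bed6_gene(line.rstrip("\n").split("\t"), i)
        if gene.gene_id in genes:
            raise ParseError(f"duplicate gene_id {gene.gene_id!r}", i)
        utr5, utr3 = utrs.get(gene.gene_id, (default_utr, default_utr))
        genes[gene.gene_id] = replace(gene, utr5_len=utr5, utr3_len=utr3)

    lengths = dict(chrom_lengths or {})
    for gene in genes.values():
        span_end = max(gene.orf_end + gene.utr5_len, gene.orf_end + gene.utr3_len)
        lengths[gene.chrom] = max(lengths.get(gene.chrom, 0), span_end)
    return Annotation(genes=genes, chrom_lengths=lengths)


def write_annotation_bed(annotation: Annotation, dest: PathLike) -> None:
    """Echo the annotation's ORFs as BED6 (name = gene_id, score = 0)."""
    genes = sorted(annotation, key=lambda g: (g.chrom, g.orf_start, g.gene_id))
    _write_lines(
        dest,
        (
            f"{g.chrom}\t{g.orf_start}\t{g.orf_end}\t{g.gene_id}\t0\t{g.strand}"
            for g in genes
        ),
    )


def write_annotation_gff3(annotation: Annotation, dest: PathLike) -> None:
    """Echo the annotation's ORFs as GFF3 gene records (1-based closed)."""
    genes = sorted(annotation, key=lambda g: (g.chrom, g.orf_start, g.gene_id))
    lines = ["##gff-version 3"]
    lines += [
        f"{g.chrom}\tasu\tgene\t{g.orf_start + 1}\t{g.orf_end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        for g in genes
    ]
    _write_lines(dest, lines)


def write_utr_table(annotation: Annotation, dest: PathLike) -> None:
    """UTR lengths as a (gene_id, utr5, utr3) TSV."""
    genes = sorted(annotation, key=lambda g: g.gene_id)
    _write_lines(
        dest, (f"{g.gene_id}\t{g.utr5_len}\t{g.utr3_len}" for g in genes)
    )


def read_bed_intervals(source: PathLike) -> list[GenomicInterval]:
    """Read stranded intervals (units, fragments, external catalogs) from BED6."""
    handle, close = _open_lines(source)
    out = []
    try:
        for i, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError("BED6 record needs 6 columns", i)
            chrom, start_s, end_s, name, _score, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError("non-integer BED coordinates", i) from None
            if start >= end:
                raise ParseError(f"start >= end ({start} >= {end})", i)
            if strand not in ("+", "-"):
                raise ParseError(f"invalid strand {strand!r}", i)
            out.append(GenomicInterval(chrom, start, end, strand, name))
    finally:
        if close:
            handle.close()
    return out


def write_bed_intervals(
    intervals: Iterable[GenomicInterval],
    dest: PathLike,
    scores: Optional[Mapping[str, int]] = None,
) -> None:
    """Write stranded intervals as BED6; score looked up by name (default 0)."""
    scores = scores or {}
    _write_lines(
        dest,
        (
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
            f"\t{scores.get(iv.name, 0)}\t{iv.strand}"
            for iv in intervals
        ),
    )


def _write_lines(dest: PathLike, lines: Iterable[str]) -> None:
    if hasattr(dest, "write"):
        for line in lines:
            dest.write(line + "\n")
    else:
        with open(dest, "w") as handle:
            for line in lines:
                handle.write(line + "\n")
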