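"""Antisense-unit cataloging against UTR-extended gene models.

Assigns transcribed units to same-strand (sense) genes, calls antisense
units on the opposite strand of annotated transcripts with transcript-
and ORF-coverage fractions and a coverage tier, merges over-segmented
antisense units into curated units, compares a unit catalog against an
external one, and computes the library strand-specificity QC metric
(the fraction of fragments antisense to unambiguously annotated
positions).

Overlap fractions are formed with exact integer arithmetic (bp counts
and `fractions.Fraction`) before any float conversion, so tier
boundaries like "75% or more" are exact.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

from .annotation_io import (
    Annotation,
    GeneModel,
    GenomicInterval,
    transcript_span,
)
from .segmentation import TranscribedUnit, fragment_center

__all__ = [
    "Tier",
    "SenseAssignment",
    "AntisenseCall",
    "CuratedUnit",
    "CatalogMatch",
    "StrandSpecificityQC",
    "assign_sense",
    "detect_expressed_genes",
    "select_expressed",
    "call_antisense",
    "curate_units",
    "compare_catalogs",
    "antisense_read_fraction",
    "qc_strandness",
    "antisense_fractions",
]

UnitLike = Union[TranscribedUnit, GenomicInterval]


class Tier(str, enum.Enum):
    """ORF-coverage tier of an antisense call."""

    UTR_ONLY = "UTR_ONLY"  # covers the transcript but none of the ORF
    GE25 = "GE25"
    GE50 = "GE50"
    GE75 = "GE75"
    FULL = "FULL"  # covers the entire ORF


@dataclass(frozen=True)
class SenseAssignment:
    unit_id: str
    gene_id: str
    overlap_bp: int

    def __post_init__(self):
        if self.overlap_bp < 1:
            raise ValueError("a sense assignment requires >= 1 bp overlap")


@dataclass(frozen=True)
class AntisenseCall:
    """A unit <-> gene opposite-strand association with coverage fractions."""

    unit_id: str
    gene_id: str
    frac_transcript: float
    frac_orf: float
    tier: Tier


@dataclass(frozen=True)
class CuratedUnit:
    """Merged span of over-segmented antisense units opposite one gene."""

    curated_id: str
    member_unit_ids: tuple[str, ...]
    span: GenomicInterval
    call: AntisenseCall


@dataclass(frozen=True)
class CatalogMatch:
    unit_id: str
    best_external_id: Optional[str]
    overlap_frac: float
    matched: bool
    covered80: bool


@dataclass(frozen=True)
class StrandSpecificityQC:
    """Strand-leak estimate: antisense fragments / informative fragments."""

    antisense_read_fraction: float
    n_informative: int
    n_antisense: int

    def to_dict(self) -> dict:
        return {
            "antisense_read_fraction": self.antisense_read_fraction,
            "n_informative": self.n_informative,
        }


def _as_interval(unit: UnitLike) -> GenomicInterval:
    return unit.interval if isinstance(unit, TranscribedUnit) else unit


def _spans(annotation: Annotation) -> dict[str, GenomicInterval]:
    return {
        g.gene_id: transcript_span(g, annotation.chrom_lengths.get(g.chrom))
        for g in annotation
    }


def assign_sense(
    units: Sequence[UnitLike], annotation: Annotation
) -> list[SenseAssignment]:
    """Units assigned to same-strand genes with >= 1 bp transcript overlap."""
    spans = _spans(annotation)
    out = []
    for unit in units:
        iv = _as_interval(unit)
        for gene_id, span in spans.items():
            if span.strand != iv.strand:
                continue
            bp = iv.overlap_bp(span)
            if bp >= 1:
                out.append(SenseAssignment(iv.name, gene_id, bp))
    return out


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    prev_end = None
    for start, end in sorted(intervals):
        if prev_end is None or start >= prev_end:
            total += end - start
            prev_end = end
        elif end > prev_end:
            total += end - prev_end
            prev_end = end
    return total


def detect_expressed_genes(
    units: Sequence[UnitLike],
    annotation: Annotation,
    min_frac: float = 0.8,
    use_orf: bool = False,
) -> set[str]:
    """Genes whose transcript span is covered >= ``min_frac`` by same-strand units.

    ``use_orf`` measures coverage against the bare ORF instead of the
    UTR-extended transcript span.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    threshold = Fraction(min_frac)
    intervals = [_as_interval(u) for u in units]
    detected = set()
    for gene in annotation:
        target = (
            gene.orf
            if use_orf
            else transcript_span(gene, annotation.chrom_lengths.get(gene.chrom))
        )
        pieces = [
            (max(iv.start, target.start), min(iv.end, target.end))
            for iv in intervals
            if iv.strand == target.strand and iv.overlap_bp(target) > 0
        ]
        if pieces and Fraction(_union_length(pieces), len(target)) >= threshold:
            detected.add(gene.gene_id)
    return detected


def select_expressed(
    gene_counts: Mapping[str, int], top_frac: float = 0.85
) -> set[str]:
    """The top ``ceil(top_frac * N)`` genes by fragment count.

    Ties are broken by gene_id so the selection is deterministic.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    if not gene_counts:
        return set()
    ranked = sorted(gene_counts, key=lambda g: (-gene_counts[g], g))
    n_keep = -(-len(ranked) * Fraction(top_frac)).__floor__()  # ceil
    return set(ranked[: int(n_keep)])


def antisense_fractions(
    iv: GenomicInterval, gene: GeneModel, chrom_length: Optional[int] = None
) -> tuple[Fraction, Fraction]:
    """(transcript fraction, ORF fraction) covered by an opposite-strand interval."""
    span = transcript_span(gene, chrom_length)
    frac_tx = Fraction(iv.overlap_bp(span), len(span))
    frac_orf = Fraction(iv.overlap_bp(gene.orf), len(gene.orf))
    return frac_tx, frac_orf


def _tier(frac_orf: Fraction) -> Tier:
    if frac_orf == 0:
        return Tier.UTR_ONLY
    if frac_orf == 1:
        return Tier.FULL
    if frac_orf >= Fraction(3, 4):
        return Tier.GE75
    if frac_orf >= Fraction(1, 2):
        return Tier.GE50
    return Tier.GE25


def call_antisense(
    units: Sequence[UnitLike],
    annotation: Annotation,
    min_transcript_frac: float = 0.25,
) -> list[AntisenseCall]:
    """Antisense calls: opposite-strand units covering >= 25% of a transcript.

    One call is emitted per qualifying (unit, gene) pair; a unit
    antisense to two genes yields two calls. The transcript fraction is
    measured against the UTR-extended span, the ORF fraction against the
    ORF alone, and the tier follows the ORF fraction with closed lower
    bounds (exactly 0.75 is GE75).
    """
    if not 0 <= min_transcript_frac <= 1:
        raise ValueError("min_transcript_frac must be in [0, 1]")
    threshold = Fraction(min_transcript_frac)
    calls = []
    for unit in units:
        iv = _as_interval(unit)
        for gene in annotation:
            if gene.strand == iv.strand or gene.chrom != iv.chrom:
                continue
            frac_tx, frac_orf = antisense_fractions(
                iv, gene, annotation.chrom_lengths.get(gene.chrom)
            )
            if frac_tx == 0 or frac_tx < threshold:
                continue
            calls.append(
                AntisenseCall(iv.name, gene.gene_id, float(frac_tx), float(frac_orf), _tier(frac_orf))
            )
    return calls


def curate_units(
    units: Sequence[UnitLike],
    annotation: Annotation,
    merge_gap: int = 200,
    min_transcript_frac: float = 0.25,
    min_member_bp: int = 30,
) -> list[CuratedUnit]:
    """Merge over-segmented antisense units opposite the same gene.

    Same-strand units that each overlap the opposite strand of the same
    gene's transcript by at least ``min_member_bp`` are chained while
    consecutive gaps are <= ``merge_gap`` bp; each chain becomes one
    curated unit spanning min(start)..max(end), whose antisense
    fractions and tier are recomputed on the merged span. Chains whose
    merged span still covers less than ``min_transcript_frac`` of the
    transcript are dropped.

    ``min_member_bp`` (default 30, just above the widest span a
    noise blip can reach through max_gap-chaining of isolated
    strand-flip centers) keeps scattered opposite-strand leak signal
    in deep libraries from chaining into curated spans.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    threshold = Fraction(min_transcript_frac)
    intervals = [_as_interval(u) for u in units]

    by_gene: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        for gene in annotation:
            if gene.strand == iv.strand or gene.chrom != iv.chrom:
                continue
            span = transcript_span(gene, annotation.chrom_lengths.get(gene.chrom))
            if iv.overlap_bp(span) >= max(1, min_member_bp):
                by_gene[gene.gene_id].append(iv)

    curated: list[CuratedUnit] = []
    for gene_id in sorted(by_gene):
        gene = annotation.genes[gene_id]
        members = sorted(by_gene[gene_id], key=lambda iv: (iv.start, iv.end, iv.name))
        chains: list[list[GenomicInterval]] = [[members[0]]]
        for iv in members[1:]:
            if iv.start - chains[-1][-1].end <= merge_gap:
                chains[-1].append(iv)
            else:
                chains.append([iv])
        for chain in chains:
            span = GenomicInterval(
                chain[0].chrom,
                min(iv.start for iv in chain),
                max(iv.end for iv in chain),
                chain[0].strand,
            )
            frac_tx, frac_orf = antisense_fractions(
                span, gene, annotation.chrom_lengths.get(gene.chrom)
            )
            if frac_tx < threshold:
                continue
            curated.append(
                CuratedUnit(
                    curated_id="",
                    member_unit_ids=tuple(iv.name for iv in chain),
                    span=span,
                    call=AntisenseCall("", gene_id, float(frac_tx), float(frac_orf), _tier(frac_orf)),
                )
            )

    curated.sort(key=lambda c: (c.span.chrom, c.span.strand, c.span.start, c.call.gene_id))
    out = []
    for i, c in enumerate(curated, start=1):
        cid = f"Curated{i}"
        span = GenomicInterval(c.span.chrom, c.span.start, c.span.end, c.span.strand, cid)
        call = AntisenseCall(cid, c.call.gene_id, c.call.frac_transcript, c.call.frac_orf, c.call.tier)
        out.append(CuratedUnit(cid, c.member_unit_ids, span, call))
    return out


def compare_catalogs(
    units: Sequence[UnitLike],
    external_units: Sequence[GenomicInterval],
    min_overlap: float = 0.5,
    covered_frac: float = 0.8,
) -> list[CatalogMatch]:
    """Match each unit to the best same-strand external unit.

    The overlap fraction is normalized by *our* unit's length. The best
    external unit maximizes that fraction; ties go to the longer
    external unit, then to the lexicographically smaller id. A unit is
    matched iff the best fraction >= ``min_overlap`` and covered80 iff
    it also reaches ``covered_frac``.
    """
    if not 0 < min_overlap <= 1 or not 0 < covered_frac <= 1:
        raise ValueError("thresholds must be in (0, 1]")
    matches = []
    for unit in units:
        iv = _as_interval(unit)
        best: Optional[tuple[Fraction, int, str]] = None
        for ext in external_units:
            if ext.strand != iv.strand:
                continue
            bp = iv.overlap_bp(ext)
            if bp == 0:
                continue
            key = (Fraction(bp, len(iv)), len(ext), ext.name)
            if best is None or (key[0], key[1], _NegStr(key[2])) > (
                best[0], best[1], _NegStr(best[2])
            ):
                best = key
        if best is None:
            matches.append(CatalogMatch(iv.name, None, 0.0, False, False))
        else:
            frac = best[0]
            matches.append(
                CatalogMatch(
                    iv.name,
                    best[2],
                    float(frac),
                    frac >= Fraction(min_overlap),
                    frac >= Fraction(covered_frac),
                )
            )
    return matches


class _NegStr(str):
    """Reverses string comparison so 'smaller id wins' composes with max."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def _qc_counts(
    frags: Sequence[GenomicInterval], annotation: Annotation
) -> tuple[int, int]:
    # per-base counts of covering transcript spans, one array per strand,
    # so each fragment center is classified in O(1)
    import numpy as np

    cover: dict[str, tuple] = {}
    for chrom, length in annotation.chrom_lengths.items():
        cover[chrom] = (np.zeros(length + 1, dtype=np.int32),
                        np.zeros(length + 1, dtype=np.int32))
    for gene in annotation:
        span = transcript_span(gene, annotation.chrom_lengths.get(gene.chrom))
        arr = cover[gene.chrom][0 if gene.strand == "+" else 1]
        arr[span.start] += 1
        arr[span.end] -= 1
    for chrom in cover:
        cover[chrom] = tuple(np.cumsum(arr)[:-1] for arr in cover[chrom])

    n_informative = n_antisense = 0
    by_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    for frag in frags:
        by_key[(frag.chrom, frag.strand)].append(fragment_center(frag))
    for (chrom, strand), centers in by_key.items():
        if chrom not in cover:
            continue
        idx = np.asarray(centers, dtype=np.int64)
        plus, minus = cover[chrom]
        # centers past the annotated chromosome end lie outside every span
        idx = idx[(idx >= 0) & (idx < plus.size)]
        n_plus, n_minus = plus[idx], minus[idx]
        # informative = the center lies in exactly one gene's transcript;
        # this drops positions with annotated transcription on both strands
        informative = (n_plus + n_minus) == 1
        n_informative += int(informative.sum())
        anti = n_minus if strand == "+" else n_plus
        n_antisense += int((informative & (anti == 1)).sum())
    return n_informative, n_antisense


def antisense_read_fraction(
    frags: Sequence[GenomicInterval], annotation: Annotation
) -> float:
    """Fraction of informative fragments antisense to their covering gene.

    A fragment is informative when its center lies inside exactly one
    gene's transcript span. This is the library strand-specificity QC
    metric (0.62% for the original dUTP library).
    """
    if len(annotation) == 0:
        raise ValueError("annotation must be non-empty")
    n_informative, n_antisense = _qc_counts(frags, annotation)
    if n_informative == 0:
        raise ValueError(
            "no informative fragments: every center lies outside or in "
            "ambiguous (both-strand) annotation"
        )
    return n_antisense / n_informative


def qc_strandness(
    frags: Sequence[GenomicInterval], annotation: Annotation
) -> StrandSpecificityQC:
    """Strand-specificity QC with the counts behind the fraction."""
    if len(annotation) == 0:
        raise ValueError("annotation must be non-empty")
    n_informative, n_antisense = _qc_counts(frags, annotation)
    if n_informative == 0:
        raise ValueError("no informative fragments")
    return StrandSpecificityQC(n_antisense / n_informative, n_informative, n_antisense)
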