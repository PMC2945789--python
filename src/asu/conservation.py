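"""Cross-species projection of antisense loci through ortholog maps.

An antisense unit is expressed in coordinates relative to its sense
gene's ORF (fractional offsets from the ORF 5' end, allowed outside
[0, 1] for UTR overhangs) and the same fractions are applied to the
ortholog's ORF, strand-aware, to predict a candidate antisense region
in the other species. Orthology and synteny are consumed as input
truth: a record without an ortholog, or with a broken synteny block,
yields no candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .annotation_io import GeneModel, GenomicInterval
from .expression_stats import Regulation

__all__ = [
    "OrthologRecord",
    "ProjectedRegion",
    "SpeciesCall",
    "project_antisense",
    "conservation_matrix",
    "read_ortholog_table",
]


@dataclass(frozen=True)
class OrthologRecord:
    source_gene_id: str
    species: str
    ortholog_gene_id: Optional[str]
    synteny_ok: bool

    @property
    def projectable(self) -> bool:
        return self.ortholog_gene_id is not None and self.synteny_ok


@dataclass(frozen=True)
class ProjectedRegion:
    species: str
    region: GenomicInterval
    source_unit_id: str
    clipped: bool


def _orf_offset(gene: GeneModel, coord: int) -> float:
    """Fractional position of ``coord`` along the ORF from its 5' end."""
    length = gene.orf_end - gene.orf_start
    if gene.strand == "+":
        return (coord - gene.orf_start) / length
    return (gene.orf_end - coord) / length


def _orf_coord(gene: GeneModel, frac: float) -> float:
    length = gene.orf_end - gene.orf_start
    if gene.strand == "+":
        return gene.orf_start + frac * length
    return gene.orf_end - frac * length


def project_antisense(
    unit: GenomicInterval,
    sense_gene: GeneModel,
    ortholog: Optional[GeneModel],
    species: str = "",
    synteny_ok: bool = True,
    chrom_length: Optional[int] = None,
    restrict_to_orf: bool = False,
) -> Optional[ProjectedRegion]:
    """Project an antisense unit onto an ortholog's coordinates.

    Unit endpoints become fractional offsets along the sense ORF from
    its 5' end; the same fractions are laid out along the ortholog ORF
    from *its* 5' end, and the projected strand is the opposite of the
    ortholog's. Fractional endpoints are rounded to the nearest base
    with ties toward the unit interior. ``restrict_to_orf`` clamps the
    fractions to [0, 1], dropping UTR overhangs; otherwise overhangs
    project linearly beyond the ortholog ORF. Returns ``None`` when
    there is no ortholog or synteny is broken.
    """
    if ortholog is None or not synteny_ok:
        return None
    if sense_gene.orf_end <= sense_gene.orf_start or ortholog.orf_end <= ortholog.orf_start:
        raise ValueError("zero-length ORF")
    fracs = sorted((_orf_offset(sense_gene, unit.start), _orf_offset(sense_gene, unit.end)))
    if restrict_to_orf:
        fracs = [min(1.0, max(0.0, f)) for f in fracs]
        if fracs[0] == fracs[1]:
            return None
    coords = sorted((_orf_coord(ortholog, fracs[0]), _orf_coord(ortholog, fracs[1])))
    # round ties toward the interior so start < end is preserved
    start = math.floor(coords[0] + 0.5)
    end = math.ceil(coords[1] - 0.5)
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    if start >= end:
        return None
    strand = "+" if ortholog.strand == "-" else "-"
    return ProjectedRegion(
        species=species,
        region=GenomicInterval(ortholog.chrom, start, end, strand, unit.name),
        source_unit_id=unit.name,
        clipped=clipped,
    )


@dataclass(frozen=True)
class SpeciesCall:
    """Per-(species, gene) antisense presence and regulation summary."""

    species: str
    gene_id: str
    has_candidate: bool
    antisense_present: bool
    sense_call: Optional[Regulation] = None
    antisense_call: Optional[Regulation] = None


_CATEGORIES = ("concordant_anti", "present_no_anticorr", "absent", "no_candidate")


def conservation_matrix(calls: Iterable[SpeciesCall]) -> pd.DataFrame:
    """Species x gene categorical matrix of antisense conservation.

    ``concordant_anti`` marks pairs where sense and antisense move in
    opposite directions between the two conditions (sense induced with
    antisense repressed, or the mirror); ``present_no_anticorr`` marks
    detected antisense without that pattern; ``absent`` means no
    antisense transcription detected; ``no_candidate`` means no
    orthologous locus to look at.
    """
    seen = set()
    cells: dict[tuple[str, str], str] = {}
    for call in calls:
        key = (call.species, call.gene_id)
        if key in seen:
            raise ValueError(f"duplicate (species, gene) record {key}")
        seen.add(key)
        if not call.has_candidate:
            cat = "no_candidate"
        elif not call.antisense_present:
            cat = "absent"
        elif (
            call.sense_call == Regulation.INDUCED
            and call.antisense_call == Regulation.REPRESSED
        ) or (
            call.sense_call == Regulation.REPRESSED
            and call.antisense_call == Regulation.INDUCED
        ):
            cat = "concordant_anti"
        else:
            cat = "present_no_anticorr"
        cells[key] = cat
    species = sorted({k[0] for k in cells})
    genes = sorted({k[1] for k in cells})
    df = pd.DataFrame(index=species, columns=genes, dtype=object)
    for (sp, gene), cat in cells.items():
        df.loc[sp, gene] = cat
    return df


def read_ortholog_table(source) -> list[OrthologRecord]:
    """TSV of (source_gene, species, ortholog_gene, synteny_ok).

    ``ortholog_gene`` empty, '.', 'NA' or 'none' means no ortholog;
    ``synteny_ok`` parses 1/0/true/false.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    required = {"source_gene", "species", "ortholog_gene", "synteny_ok"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples():
        ortholog = row.ortholog_gene
        if ortholog in ("", ".", "NA", "none", "None"):
            ortholog = None
        synteny = row.synteny_ok.strip().lower() in ("1", "true", "yes")
        records.append(OrthologRecord(row.source_gene, row.species, ortholog, synteny))
    return records
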