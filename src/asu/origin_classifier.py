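"""Origin classification of antisense units and supporting statistics.

Each antisense unit is assigned exactly one plausible transcriptional
origin by walking a strict precedence ladder against nearby gene
boundaries (default margin 400 bp):

1. ``SENSE_3UTR_EXTENSION`` — the unit could be the long 3' UTR of a
   same-strand gene ending just upstream of the unit's 5' end.
2. ``SENSE_5UTR_EXTENSION`` — the unit could be the long 5' UTR of a
   same-strand gene starting just downstream of the unit's 3' end.
3. ``DIVERGENT_PROMOTER`` — an opposite-strand gene starts near the
   unit's 5' end and reads away from it (5'-to-5' configuration);
   head-on proximity does not qualify.
4. ``ADJACENT_3NFR`` — any gene's 3' end (a candidate 3'-UTR
   nucleosome-free region) lies near the unit's 5' end, either strand.
5. ``UNEXPLAINED`` otherwise.

The precedence order mirrors classification by successive exclusion:
a unit matching several rules keeps the earliest label only.
Separately, units whose 3' end terminates close (< 200 bp by default)
to the 3' end of a convergent gene are flagged as candidate blockers of
runthrough transcription.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .annotation_io import Annotation, AnnotationError, GenomicInterval, transcript_span

__all__ = [
    "OriginClass",
    "OriginCall",
    "RunthroughFlag",
    "classify_origin",
    "classify_origin_detail",
    "flag_runthrough",
    "wilcoxon_rank_sum",
    "neighbor_expression_correlation",
]


class OriginClass(str, enum.Enum):
    SENSE_3UTR_EXTENSION = "SENSE_3UTR_EXTENSION"
    SENSE_5UTR_EXTENSION = "SENSE_5UTR_EXTENSION"
    DIVERGENT_PROMOTER = "DIVERGENT_PROMOTER"
    ADJACENT_3NFR = "ADJACENT_3NFR"
    UNEXPLAINED = "UNEXPLAINED"


@dataclass(frozen=True)
class OriginCall:
    unit_id: str
    origin: OriginClass
    gene_id: Optional[str]  # supporting gene, None for UNEXPLAINED
    distance_bp: Optional[int]


@dataclass(frozen=True)
class RunthroughFlag:
    unit_id: str
    blocked_gene_id: Optional[str]
    distance_bp: Optional[int]

    @property
    def flagged(self) -> bool:
        return self.blocked_gene_id is not None


def _upstream_offset(unit: GenomicInterval, coord: int) -> int:
    """How far ``coord`` lies upstream of the unit's 5' end (>=0 = upstream)."""
    return unit.five_prime - coord if unit.strand == "+" else coord - unit.five_prime


def _downstream_offset(unit: GenomicInterval, coord: int) -> int:
    """How far ``coord`` lies downstream of the unit's 3' end."""
    return coord - unit.three_prime if unit.strand == "+" else unit.three_prime - coord


def classify_origin_detail(
    unit: GenomicInterval, annotation: Annotation, margin: int = 400
) -> OriginCall:
    """Classify one antisense unit; first precedence rule to fire wins.

    Distances are boundary-to-boundary in bp; a gene span overlapping
    the unit counts as distance 0 for the same-strand and 3'-NFR rules.
    Within a rule the nearest gene supports the call, ties broken by
    gene_id.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if unit.strand not in ("+", "-"):
        raise ValueError("unit must be stranded")
    if unit.chrom not in annotation.chrom_lengths:
        raise AnnotationError(f"unknown chromosome {unit.chrom!r}")

    spans = [
        (g, transcript_span(g, annotation.chrom_lengths.get(g.chrom)))
        for g in annotation.on_chrom(unit.chrom)
    ]

    def best(candidates):
        if not candidates:
            return None
        return min(candidates, key=lambda c: (c[1], c[0]))

    rules = []

    # (1) same-strand gene 3' end <= margin upstream of the unit 5' end
    hits = []
    for g, span in spans:
        if span.strand != unit.strand:
            continue
        off = _upstream_offset(unit, span.three_prime)
        if unit.overlap_bp(span) > 0:
            hits.append((g.gene_id, 0))
        elif 0 <= off <= margin:
            hits.append((g.gene_id, off))
    rules.append((OriginClass.SENSE_3UTR_EXTENSION, best(hits)))

    # (2) same-strand gene 5' end <= margin downstream of the unit 3' end
    hits = []
    for g, span in spans:
        if span.strand != unit.strand:
            continue
        off = _downstream_offset(unit, span.five_prime)
        if unit.overlap_bp(span) > 0:
            hits.append((g.gene_id, 0))
        elif 0 <= off <= margin:
            hits.append((g.gene_id, off))
    rules.append((OriginClass.SENSE_5UTR_EXTENSION, best(hits)))

    # (3) opposite-strand gene 5' end near the unit 5' end, reading away
    hits = []
    for g, span in spans:
        if span.strand == unit.strand:
            continue
        off = _upstream_offset(unit, span.five_prime)
        if 0 <= off <= margin:
            hits.append((g.gene_id, off))
    rules.append((OriginClass.DIVERGENT_PROMOTER, best(hits)))

    # (4) any gene 3' end within margin of the unit 5' end; pure boundary
    # distance here — the sense gene always overlaps its antisense unit,
    # so an overlap shortcut would make this class absorb every unit
    hits = []
    for g, span in spans:
        d = abs(span.three_prime - unit.five_prime)
        if d <= margin:
            hits.append((g.gene_id, d))
    rules.append((OriginClass.ADJACENT_3NFR, best(hits)))

    for origin, hit in rules:
        if hit is not None:
            return OriginCall(unit.name, origin, hit[0], hit[1])
    return OriginCall(unit.name, OriginClass.UNEXPLAINED, None, None)


def classify_origin(
    unit: GenomicInterval, annotation: Annotation, margin: int = 400
) -> OriginClass:
    """Origin label only (see :func:`classify_origin_detail`)."""
    return classify_origin_detail(unit, annotation, margin).origin


def flag_runthrough(
    unit: GenomicInterval, annotation: Annotation, max_dist: int = 200
) -> RunthroughFlag:
    """Flag a unit whose 3' end is < ``max_dist`` bp from a convergent
    gene's transcript 3' end (candidate runthrough blocker).

    Reports the nearest qualifying opposite-strand gene; unflagged units
    get ``blocked_gene_id = None`` and, when any opposite-strand gene
    exists on the chromosome, the distance to the nearest 3' end.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be non-negative")
    nearest: Optional[tuple[int, str]] = None
    for g in annotation.on_chrom(unit.chrom):
        if g.strand == unit.strand:
            continue
        span = transcript_span(g, annotation.chrom_lengths.get(g.chrom))
        d = abs(span.three_prime - unit.three_prime)
        if nearest is None or (d, g.gene_id) < nearest:
            nearest = (d, g.gene_id)
    if nearest is not None and nearest[0] < max_dist:
        return RunthroughFlag(unit.name, nearest[1], nearest[0])
    return RunthroughFlag(unit.name, None, None if nearest is None else nearest[0])


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _midranks(values: Sequence[float]) -> np.ndarray:
    return stats.rankdata(values, method="average")


def wilcoxon_rank_sum(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two_sided",
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Wilcoxon rank-sum test with midranks for ties.

    Returns ``(W, p)`` where W is the rank sum of ``group_a`` in the
    pooled midranking. The p-value is exact by enumeration of all
    C(n_a + n_b, n_a) group assignments when the combined sample size is
    at most ``exact_max_n``; otherwise the normal approximation with tie
    correction and a 0.5 continuity correction is used. The two-sided
    p doubles the smaller tail (capped at 1).
    """
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = _midranks(np.concatenate([a, b]))
    w_obs = float(ranks[:n_a].sum())

    if n <= exact_max_n:
        sums = [sum(c) for c in combinations(ranks, n_a)]
        total = len(sums)
        eps = 1e-9
        p_less = sum(s <= w_obs + eps for s in sums) / total
        p_greater = sum(s >= w_obs - eps for s in sums) / total
    else:
        mean = n_a * (n + 1) / 2.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var == 0:
            p_less = p_greater = 1.0
        else:
            sd = math.sqrt(var)
            p_less = stats.norm.cdf((w_obs - mean + 0.5) / sd)
            p_greater = stats.norm.sf((w_obs - mean - 0.5) / sd)

    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return w_obs, float(p)


def neighbor_expression_correlation(
    pairs: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Pearson correlation (r, r^2) between antisense and neighbor-gene
    differential expression log-ratios.

    A low r^2 argues against co-regulation of the antisense unit with
    the neighbor it could share a promoter or 3'-UTR NFR with.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (antisense, neighbor) pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs must be finite")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError("zero variance in one coordinate")
    r = float(stats.pearsonr(arr[:, 0], arr[:, 1]).statistic)
    return r, r * r
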