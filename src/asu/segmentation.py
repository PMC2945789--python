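"""Strand-specific segmentation of fragment-center coverage.

Each mapped paired-end fragment is reduced to its center position; per
(chromosome, strand) the center counts are segmented into maximal runs
of "signal" positions (count >= ``min_cov``, default 2, i.e. coverage
strictly greater than 1) whose internal gaps of non-signal positions
are each at most ``max_gap`` bp (default 20). The resulting transcribed
units are the pipeline's unit of putative transcription.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .annotation_io import GenomicInterval, PathLike, _write_lines

__all__ = [
    "FragmentAlignment",
    "CenterCoverage",
    "TranscribedUnit",
    "fragment_center",
    "compute_center_coverage",
    "call_units",
    "call_units_reference",
    "units_to_intervals",
    "write_units_bed",
    "write_bedgraph",
]

# A fragment alignment is the stranded outer span of a read pair.
FragmentAlignment = GenomicInterval

StrandKey = tuple[str, str]  # (chrom, strand)


@dataclass(frozen=True)
class TranscribedUnit:
    """A maximal strand-specific segment of fragment-center coverage."""

    unit_id: str
    chrom: str
    strand: str
    start: int
    end: int
    n_centers: int
    peak_coverage: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.unit_id}: start >= end")
        if self.n_centers < 1:
            raise ValueError(f"{self.unit_id}: a unit needs at least one center")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand, self.unit_id)

    def __len__(self) -> int:
        return self.end - self.start


class CenterCoverage:
    """Sparse per-(chrom, strand) counts of fragment centers."""

    def __init__(self, counts: Optional[Mapping[StrandKey, Mapping[int, int]]] = None):
        self._counts: dict[StrandKey, Counter] = defaultdict(Counter)
        if counts:
            for key, positions in counts.items():
                chrom, strand = key
                if strand not in ("+", "-"):
                    raise ValueError(f"invalid strand {strand!r}")
                for pos, count in positions.items():
                    if count < 1:
                        raise ValueError("stored center counts must be >= 1")
                    self._counts[(chrom, strand)][int(pos)] = int(count)

    def add(self, chrom: str, strand: str, position: int, count: int = 1) -> None:
        self._counts[(chrom, strand)][position] += count

    def keys(self) -> list[StrandKey]:
        return sorted(self._counts)

    def positions(self, chrom: str, strand: str) -> Counter:
        return self._counts.get((chrom, strand), Counter())

    def total_mass(self) -> int:
        return sum(sum(c.values()) for c in self._counts.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, CenterCoverage):
            return NotImplemented
        return {k: dict(v) for k, v in self._counts.items()} == {
            k: dict(v) for k, v in other._counts.items()
        }


def fragment_center(frag: FragmentAlignment) -> int:
    """Center of the fragment's outer span; even lengths take the lower median."""
    return (frag.start + frag.end) // 2


def compute_center_coverage(frags: Iterable[FragmentAlignment]) -> CenterCoverage:
    """Count fragment centers per (chrom, strand, position)."""
    cov = CenterCoverage()
    for frag in frags:
        if frag.strand not in ("+", "-"):
            raise ValueError("fragments must be stranded ('+' or '-')")
        cov.add(frag.chrom, frag.strand, fragment_center(frag))
    return cov


def _segment_positions(
    positions: Mapping[int, int], min_cov: int, max_gap: int
) -> list[tuple[int, int]]:
    """Half-open runs of signal positions with internal gaps <= max_gap."""
    signal = sorted(p for p, c in positions.items() if c >= min_cov)
    runs: list[tuple[int, int]] = []
    for pos in signal:
        # gap = count of non-signal positions strictly between neighbors
        if runs and pos - runs[-1][1] <= max_gap:
            runs[-1] = (runs[-1][0], pos + 1)
        else:
            runs.append((pos, pos + 1))
    return runs


def call_units(
    cov: CenterCoverage, min_cov: int = 2, max_gap: int = 20
) -> list[TranscribedUnit]:
    """Segment center coverage into transcribed units.

    A position is signal iff its center count >= ``min_cov``; maximal
    runs of signal positions whose internal non-signal gaps are each
    <= ``max_gap`` form one unit spanning [first signal, last signal + 1).
    Units are sorted by (chrom, strand, start) and numbered "Unit1",
    "Unit2", ... in that order.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    units: list[TranscribedUnit] = []
    for chrom, strand in cov.keys():
        positions = cov.positions(chrom, strand)
        for start, end in _segment_positions(positions, min_cov, max_gap):
            in_span = {p: c for p, c in positions.items() if start <= p < end}
            units.append(
                TranscribedUnit(
                    unit_id="",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    n_centers=sum(in_span.values()),
                    peak_coverage=max(in_span.values()),
                )
            )
    units.sort(key=lambda u: (u.chrom, u.strand, u.start))
    return [
        TranscribedUnit(f"Unit{i}", u.chrom, u.strand, u.start, u.end, u.n_centers, u.peak_coverage)
        for i, u in enumerate(units, start=1)
    ]


def call_units_reference(
    cov: CenterCoverage, min_cov: int = 2, max_gap: int = 20
) -> list[TranscribedUnit]:
    """Brute-force reference segmentation: scan every base position.

    Walks the dense position range of each (chrom, strand), closing a
    unit once more than ``max_gap`` consecutive non-signal positions
    have been seen. Independent of the sparse implementation; used as
    an oracle in tests.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    units: list[TranscribedUnit] = []
    for chrom, strand in cov.keys():
        positions = cov.positions(chrom, strand)
        if not positions:
            continue
        lo, hi = min(positions), max(positions)
        unit_start = None
        last_signal = None
        for p in range(lo, hi + 2):
            is_signal = positions.get(p, 0) >= min_cov
            if is_signal:
                if unit_start is not None and (p - last_signal - 1) > max_gap:
                    units.append(_make_unit(chrom, strand, unit_start, last_signal + 1, positions))
                    unit_start = None
                if unit_start is None:
                    unit_start = p
                last_signal = p
            elif unit_start is not None and (p - last_signal - 1) > max_gap:
                units.append(_make_unit(chrom, strand, unit_start, last_signal + 1, positions))
                unit_start = None
        if unit_start is not None:
            units.append(_make_unit(chrom, strand, unit_start, last_signal + 1, positions))
    units.sort(key=lambda u: (u.chrom, u.strand, u.start))
    return [
        TranscribedUnit(f"Unit{i}", u.chrom, u.strand, u.start, u.end, u.n_centers, u.peak_coverage)
        for i, u in enumerate(units, start=1)
    ]


def _make_unit(chrom, strand, start, end, positions) -> TranscribedUnit:
    in_span = {p: c for p, c in positions.items() if start <= p < end}
    return TranscribedUnit("", chrom, strand, start, end, sum(in_span.values()), max(in_span.values()))


def units_to_intervals(units: Sequence[TranscribedUnit]) -> list[GenomicInterval]:
    return [u.interval for u in units]


def write_units_bed(units: Sequence[TranscribedUnit], dest: PathLike) -> None:
    """Units as BED6 with name = unit_id and score = peak coverage."""
    _write_lines(
        dest,
        (
            f"{u.chrom}\t{u.start}\t{u.end}\t{u.unit_id}\t{u.peak_coverage}\t{u.strand}"
            for u in units
        ),
    )


def write_bedgraph(cov: CenterCoverage, out_prefix: str) -> tuple[str, str]:
    """Per-strand center coverage as two bedGraph files (.plus/.minus)."""
    paths = (f"{out_prefix}.plus.bedgraph", f"{out_prefix}.minus.bedgraph")
    for strand, path in zip("+-", paths):
        lines = []
        for chrom, s in cov.keys():
            if s != strand:
                continue
            positions = cov.positions(chrom, s)
            run_start = run_val = None
            prev = None
            for p in sorted(positions):
                v = positions[p]
                if run_start is not None and p == prev + 1 and v == run_val:
                    prev = p
                    continue
                if run_start is not None:
                    lines.append(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val}")
                run_start, run_val, prev = p, v, p
            if run_start is not None:
                lines.append(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val}")
        _write_lines(path, lines)
    return paths
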