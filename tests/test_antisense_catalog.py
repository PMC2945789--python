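"""Sense assignment, antisense calls and tiers, curation, catalog matching, QC."""

from fractions import Fraction

import numpy as np
import pytest

from asu import (
    Annotation,
    GeneModel,
    GenomicInterval,
    Tier,
    antisense_read_fraction,
    assign_sense,
    call_antisense,
    compare_catalogs,
    curate_units,
    detect_expressed_genes,
    qc_strandness,
    select_expressed,
)
from asu.antisense_catalog import antisense_fractions


def iv(start, end, strand, name="u"):
    return GenomicInterval("chrI", start, end, strand, name)


class TestAssignSense:
    def test_same_strand_overlap_assigned(self, single_gene_annotation):
        out = assign_sense([iv(950, 2000, "+")], single_gene_annotation)
        assert [(a.gene_id, a.overlap_bp) for a in out] == [("YX1", 1050)]

    def test_opposite_strand_not_assigned(self, single_gene_annotation):
        assert assign_sense([iv(950, 2000, "-")], single_gene_annotation) == []

    def test_half_open_touch_is_not_overlap(self, single_gene_annotation):
        assert assign_sense([iv(2100, 2200, "+")], single_gene_annotation) == []


class TestDetectExpressed:
    def test_coverage_fraction_thresholds(self, single_gene_annotation):
        # transcript [900, 2100), length 1200
        assert detect_expressed_genes(
            [iv(900, 1900, "+")], single_gene_annotation
        ) == {"YX1"}  # 1000/1200 = 0.833
        assert (
            detect_expressed_genes([iv(900, 1800, "+")], single_gene_annotation)
            == set()
        )  # 900/1200 = 0.75

    def test_union_not_double_counted(self, single_gene_annotation):
        units = [iv(900, 1600, "+"), iv(1400, 1900, "+")]
        assert detect_expressed_genes(units, single_gene_annotation) == {"YX1"}

    def test_no_overlap_means_not_detected(self, single_gene_annotation):
        assert detect_expressed_genes([iv(5000, 6000, "+")], single_gene_annotation) == set()


class TestSelectExpressed:
    def test_top_85_percent_of_20_is_17(self):
        counts = {f"g{i:02d}": 100 - i for i in range(20)}
        assert len(select_expressed(counts, 0.85)) == 17

    def test_all_kept_at_full_fraction(self):
        counts = {"a": 1, "b": 2}
        assert select_expressed(counts, 1.0) == {"a", "b"}

    def test_equal_counts_break_ties_by_gene_id(self):
        counts = {f"g{i}": 7 for i in range(10)}
        assert select_expressed(counts, 0.85) == {f"g{i}" for i in range(9)}

    def test_empty_input(self):
        assert select_expressed({}, 0.85) == set()


class TestCallAntisense:
    def test_half_orf_coverage_is_ge50(self, single_gene_annotation):
        calls = call_antisense([iv(1500, 2100, "-")], single_gene_annotation)
        assert len(calls) == 1
        c = calls[0]
        assert c.gene_id == "YX1"
        assert c.frac_transcript == pytest.approx(600 / 1200)
        assert c.frac_orf == pytest.approx(0.5)
        assert c.tier == Tier.GE50

    def test_below_25pct_transcript_is_no_call(self, single_gene_annotation):
        assert call_antisense([iv(2050, 2300, "-")], single_gene_annotation) == []

    def test_utr_only_call(self):
        gene = GeneModel("YX1", "chrI", "+", 1000, 2000, 100, 400)
        annot = Annotation(genes={"YX1": gene}, chrom_lengths={"chrI": 10_000})
        calls = call_antisense([iv(2000, 2400, "-")], annot)
        assert len(calls) == 1
        assert calls[0].frac_transcript == pytest.approx(400 / 1500)
        assert calls[0].frac_orf == 0.0
        assert calls[0].tier == Tier.UTR_ONLY

    def test_tier_boundaries_are_closed_below(self, single_gene_annotation):
        # exactly 75% / 50% of the 1000 bp ORF
        assert call_antisense([iv(1250, 2100, "-")], single_gene_annotation)[0].tier == Tier.GE75
        assert call_antisense([iv(1500, 2100, "-")], single_gene_annotation)[0].tier == Tier.GE50
        full = call_antisense([iv(900, 2100, "-")], single_gene_annotation)[0]
        assert full.tier == Tier.FULL and full.frac_orf == 1.0

    def test_zero_threshold_emits_every_overlapping_pair(self, single_gene_annotation):
        calls = call_antisense([iv(2050, 2300, "-")], single_gene_annotation, 0.0)
        assert len(calls) == 1

    def test_unit_antisense_to_two_genes_yields_two_calls(self):
        genes = {
            "A": GeneModel("A", "chrI", "+", 1000, 2000, 100, 100),
            "B": GeneModel("B", "chrI", "+", 2300, 3300, 100, 100),
        }
        annot = Annotation(genes=genes, chrom_lengths={"chrI": 10_000})
        calls = call_antisense([iv(1400, 3000, "-")], annot)
        assert sorted(c.gene_id for c in calls) == ["A", "B"]


def test_overlap_fractions_match_per_base_counting_oracle():
    """Exact integer fractions agree with per-base counting."""
    rng = np.random.default_rng(5)
    for _ in range(200):
        a = int(rng.integers(500, 2000))
        b = a + int(rng.integers(200, 1500))
        utr5, utr3 = int(rng.integers(0, 300)), int(rng.integers(0, 300))
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneModel("g", "chrI", strand, a, b, utr5, utr3)
        us = int(rng.integers(0, 3000))
        ue = us + int(rng.integers(1, 2000))
        unit = iv(us, ue, "-" if strand == "+" else "+")
        frac_tx, frac_orf = antisense_fractions(unit, gene)
        from asu import transcript_span

        span = transcript_span(gene)
        tx_bp = sum(1 for p in range(span.start, span.end) if us <= p < ue)
        orf_bp = sum(1 for p in range(a, b) if us <= p < ue)
        assert frac_tx == Fraction(tx_bp, len(span))
        assert frac_orf == Fraction(orf_bp, b - a)


class TestCurateUnits:
    def test_small_gap_merges_to_full(self, single_gene_annotation):
        units = [iv(1000, 1300, "-", "u1"), iv(1350, 2000, "-", "u2")]
        curated = curate_units(units, single_gene_annotation)
        assert len(curated) == 1
        c = curated[0]
        assert c.member_unit_ids == ("u1", "u2")
        assert (c.span.start, c.span.end) == (1000, 2000)
        assert c.call.tier == Tier.FULL and c.call.frac_orf == 1.0

    def test_gap_above_threshold_does_not_merge(self, single_gene_annotation):
        units = [iv(1000, 1300, "-", "u1"), iv(1650, 2000, "-", "u2")]
        curated = curate_units(units, single_gene_annotation)
        assert len(curated) == 2

    def test_single_unit_is_identity(self, single_gene_annotation):
        curated = curate_units([iv(1000, 2000, "-", "u1")], single_gene_annotation)
        assert len(curated) == 1
        assert (curated[0].span.start, curated[0].span.end) == (1000, 2000)

    def test_tiny_members_are_ignored_as_noise(self, single_gene_annotation):
        units = [iv(1000, 2000, "-", "u1"), iv(2050, 2052, "-", "blip")]
        curated = curate_units(units, single_gene_annotation)
        assert curated[0].member_unit_ids == ("u1",)
        assert (curated[0].span.start, curated[0].span.end) == (1000, 2000)


class TestCompareCatalogs:
    def test_best_overlap_wins_and_covered80(self):
        unit = iv(100, 400, "+", "u1")
        ext = [iv(150, 400, "+", "A"), iv(90, 200, "+", "B")]
        (m,) = compare_catalogs([unit], ext)
        assert m.best_external_id == "A"
        assert m.overlap_frac == pytest.approx(250 / 300)
        assert m.matched and m.covered80

    def test_opposite_strand_catalog_never_matches(self):
        (m,) = compare_catalogs([iv(100, 400, "+", "u1")], [iv(100, 400, "-", "A")])
        assert m.best_external_id is None and not m.matched

    def test_fraction_below_half_is_unmatched(self):
        (m,) = compare_catalogs([iv(100, 400, "+", "u1")], [iv(280, 500, "+", "A")])
        assert m.overlap_frac == pytest.approx(0.4)
        assert not m.matched and not m.covered80

    def test_tie_prefers_longer_then_lexicographic(self):
        unit = iv(100, 200, "+", "u1")
        ext = [iv(100, 200, "+", "B"), iv(50, 200, "+", "A"), iv(100, 250, "+", "C")]
        (m,) = compare_catalogs([unit], ext)
        assert m.best_external_id == "A"  # both 150 bp, A < C


class TestStrandQC:
    def test_leak_fraction(self, single_gene_annotation):
        sense = [iv(1000 + i, 1100 + i, "+") for i in range(99)]
        anti = [iv(1500, 1600, "-")]
        assert antisense_read_fraction(sense + anti, single_gene_annotation) == pytest.approx(0.01)
        qc = qc_strandness(sense + anti, single_gene_annotation)
        assert qc.n_informative == 100 and qc.n_antisense == 1

    def test_all_sense_is_zero(self, single_gene_annotation):
        frags = [iv(1000, 1100, "+"), iv(1200, 1400, "+")]
        assert antisense_read_fraction(frags, single_gene_annotation) == 0.0

    def test_double_stranded_regions_are_uninformative(self, two_strand_annotation):
        frags = [iv(1200, 1400, "+"), iv(1300, 1500, "-")]
        with pytest.raises(ValueError, match="informative"):
            antisense_read_fraction(frags, two_strand_annotation)

    def test_empty_annotation_rejected(self):
        annot = Annotation(chrom_lengths={"chrI": 1000})
        with pytest.raises(ValueError):
            antisense_read_fraction([iv(0, 10, "+")], annot)
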