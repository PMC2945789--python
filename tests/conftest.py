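import pytest

from asu import Annotation, GeneModel


@pytest.fixture
def single_gene_annotation():
    """One '+' gene, ORF [1000, 2000), 100 bp UTRs -> transcript [900, 2100)."""
    gene = GeneModel("YX1", "chrI", "+", 1000, 2000, 100, 100)
    return Annotation(genes={"YX1": gene}, chrom_lengths={"chrI": 10_000})


@pytest.fixture
def two_strand_annotation():
    """Two genes fully overlapping on opposite strands (ambiguous region)."""
    genes = {
        "PLUS": GeneModel("PLUS", "chrI", "+", 1000, 2000, 0, 0),
        "MINUS": GeneModel("MINUS", "chrI", "-", 1000, 2000, 0, 0),
    }
    return Annotation(genes=genes, chrom_lengths={"chrI": 10_000})
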