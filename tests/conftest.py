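import pytest

from exonact.annotate import annotate_gene
from exonact.fixtures import fixture_a


FIXTURE_A_TSV = "\n".join(
    ["\t".join(
        ["gene_id", "symbol", "organism", "chrom", "strand", "transcript_id",
         "protein_id", "ordinal", "exon_start", "exon_end", "cds_start", "cds_end"]
    )]
    + [
        "\t".join(map(str, row))
        for row in [
            ("GENE1", "GENE1", "synthetic", "chr1", "+", "T1", "T1.p", 1, 101, 200, 161, 770),
            ("GENE1", "GENE1", "synthetic", "chr1", "+", "T1", "T1.p", 2, 301, 399, 161, 770),
            ("GENE1", "GENE1", "synthetic", "chr1", "+", "T1", "T1.p", 3, 501, 600, 161, 770),
            ("GENE1", "GENE1", "synthetic", "chr1", "+", "T1", "T1.p", 4, 701, 800, 161, 770),
            ("GENE1", "GENE1", "synthetic", "chr1", "+", "T2", "T2.p", 1, 101, 200, 161, 770),
            ("GENE1", "GENE1", "synthetic", "chr1", "+", "T2", "T2.p", 2, 501, 600, 161, 770),
            ("GENE1", "GENE1", "synthetic", "chr1", "+", "T2", "T2.p", 3, 701, 800, 161, 770),
        ]
    ]
) + "\n"


@pytest.fixture
def fixture_a_tsv(tmp_path):
    p = tmp_path / "fixture_a.tsv"
    p.write_text(FIXTURE_A_TSV)
    return p


@pytest.fixture
def gene_a():
    gene, _ = fixture_a(with_sequence=True)
    return gene


@pytest.fixture
def ann_a(gene_a):
    return annotate_gene(gene_a)


@pytest.fixture
def gene_a_full():
    """FIXTURE-A with the alt-5'ss (T3), intron-retention (T4) transcripts."""
    gene, _ = fixture_a(include_t3=True, include_t4=True, with_sequence=False)
    return gene
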