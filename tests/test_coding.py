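"""Residue attribution: junction-codon ownership, phases, frame handling."""

import pytest

from exonact.annotate import annotate_gene
from exonact.coding import attribute_residues, coding_status
from exonact.fixtures import FixtureSpec, generate_fixture, oracle_attribution
from exonact.gene_model import (
    ExonRecord,
    GenomicInterval,
    TranscriptModel,
)


def _ranges(a):
    return [(e.ordinal, e.residue_range) for e in a.entries]


class TestFixtureA:
    def test_t1_residue_ranges_and_classes(self, gene_a):
        a = attribute_residues(gene_a.transcript("T1"))
        assert _ranges(a) == [(1, (1, 13)), (2, (14, 46)), (3, (47, 80)), (4, (81, 102))]
        assert [e.coding_class for e in a.entries] == [
            "partial", "coding", "coding", "partial",
        ]
        counts = [e.residue_range[1] - e.residue_range[0] + 1 for e in a.entries]
        assert counts == [13, 33, 34, 22] and sum(counts) == 102
        assert a.protein_length == 102 and a.stop_included

    def test_t2_skipping_an_exon_shifts_downstream_residues(self, gene_a):
        a = attribute_residues(gene_a.transcript("T2"))
        assert _ranges(a) == [(1, (1, 13)), (2, (14, 47)), (3, (48, 69))]
        assert a.protein_length == 69

    def test_attribution_matches_base_tracking_oracle(self):
        from exonact.fixtures import fixture_a

        gene, seq = fixture_a(with_sequence=True)
        for t in gene.transcripts:
            oracle_ranges, protein, stop_inc = oracle_attribution(t, seq)
            a = attribute_residues(t)
            assert {e.ordinal: e.residue_range for e in a.entries if e.residue_range} \
                == oracle_ranges
            assert a.protein_length == len(protein)
            assert a.stop_included == stop_inc


def test_single_exon_9nt_cds_attributes_two_residues():
    iv = GenomicInterval("chr1", 101, 200, "+")
    t = TranscriptModel(
        "S",
        exons=[ExonRecord(interval=iv, cds_part=GenomicInterval("chr1", 121, 129, "+"))],
    )
    a = attribute_residues(t, stop_included=True)
    (e,) = a.entries
    assert e.residue_range == (1, 2)
    assert (e.start_phase, e.end_phase) == (0, 0)
    assert a.protein_length == 2


def test_noncoding_transcript_yields_all_noncoding_entries():
    t = TranscriptModel(
        "NC", exons=[ExonRecord(interval=GenomicInterval("chr1", 101, 200, "+"))]
    )
    a = attribute_residues(t)
    assert a.protein_length == 0
    assert [e.coding_class for e in a.entries] == ["noncoding"]
    assert a.entries[0].residue_range is None


def test_phases_chain_across_coding_exons(gene_a):
    a = attribute_residues(gene_a.transcript("T1"))
    coding = [e for e in a.entries if e.residue_range]
    for prev, nxt in zip(coding, coding[1:]):
        assert prev.end_phase == nxt.start_phase
    # CDS pieces 40/99/100/70: phases 0->1->1->2->0
    assert [(e.start_phase, e.end_phase) for e in coding] == [
        (0, 1), (1, 1), (1, 2), (2, 0),
    ]


def test_frame_incomplete_cds_flags_and_truncates():
    # 40+100+70 = 210 is frame-complete; drop 1 base to break the frame
    iv1 = GenomicInterval("chr1", 101, 200, "+")
    iv2 = GenomicInterval("chr1", 301, 400, "+")
    t = TranscriptModel(
        "F",
        exons=[
            ExonRecord(interval=iv1, cds_part=GenomicInterval("chr1", 161, 200, "+"), ordinal=1),
            ExonRecord(interval=iv2, cds_part=GenomicInterval("chr1", 301, 399, "+"), ordinal=2),
        ],
    )
    a = attribute_residues(t)
    assert a.frame_incomplete
    assert not a.stop_included
    # 139 bases -> 46 full codons, trailing base unattributed
    assert a.protein_length == 46


def test_residue_partition_is_exact_on_random_fixtures():
    for seed in range(15):
        for strand in "+-":
            gene, _, _ = generate_fixture(FixtureSpec(seed=seed, strand=strand))
            ann = annotate_gene(gene)
            for tid, a in ann.attributions.items():
                ranges = [e.residue_range for e in a.entries if e.residue_range]
                covered = []
                for lo, hi in ranges:
                    covered.extend(range(lo, hi + 1))
                assert covered == list(range(1, a.protein_length + 1)), tid


def test_frameshift_skip_changes_downstream_peptides():
    """Skipping a length%3!=0 exon alters residues of downstream shared exons."""
    gene, truth, _ = generate_fixture(
        FixtureSpec(seed=4, events=("frameshift_skip",))
    )
    ann = annotate_gene(gene)
    ref = gene.transcript("T1")
    fs = gene.transcript("T3_fskip")
    assert ann.attributions["T3_fskip"].frame_incomplete
    # the last exon is shared; its attributed peptides must differ
    ref_entry = ann.attributions["T1"].entries[-1]
    fs_entry = ann.attributions["T3_fskip"].entries[-1]
    assert ref_entry.euid == fs_entry.euid  # same exon entity
    ref_pep = ref.protein_seq[ref_entry.residue_range[0] - 1 : ref_entry.residue_range[1]]
    fs_pep = fs.protein_seq[fs_entry.residue_range[0] - 1 : fs_entry.residue_range[1]]
    assert ref_pep != fs_pep


@pytest.mark.parametrize(
    "span,cds,expected",
    [((101, 200), (161, 200), "partial"),
     ((101, 200), (101, 200), "coding"),
     ((101, 200), None, "noncoding")],
)
def test_coding_status(span, cds, expected):
    e = ExonRecord(
        interval=GenomicInterval("chr1", *span, "+"),
        cds_part=GenomicInterval("chr1", *cds, "+") if cds else None,
    )
    assert coding_status(e) == expected
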