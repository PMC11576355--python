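"""Splice-site variant / IR classification and the EUID codec."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exonact.annotate import annotate_gene
from exonact.classify import (
    CapacityError,
    ExonVariant,
    classify_exon,
    decode_euid,
    decode_ir_euid,
    encode_euid,
    enumerate_variants,
    ir_euid,
)
from exonact.fixtures import FixtureSpec, fixture_a, generate_fixture
from exonact.gene_model import (
    ExonRecord,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)
from exonact.reference import build_rsoex


def _variant(cum="C", pos=1, occ=1, v5=0, v3=0):
    return ExonVariant(
        gene_id="G",
        position=pos,
        interval=GenomicInterval("chr1", 1, 10, "+"),
        five_prime_variant=v5,
        three_prime_variant=v3,
        occurrence=occ,
        cumulative_coding=cum,
    )


class TestClassifyExon:
    def test_shifted_5p_boundary_is_a_variant(self, gene_a):
        r = build_rsoex(gene_a)
        e = ExonRecord(interval=GenomicInterval("chr1", 311, 399, "+"))
        cls = classify_exon(e, r)
        assert (cls.kind, cls.position, cls.d5, cls.d3) == ("variant", 2, 1, 0)

    def test_exon_spanning_two_reference_exons_is_ir(self, gene_a):
        r = build_rsoex(gene_a)
        e = ExonRecord(interval=GenomicInterval("chr1", 301, 600, "+"))
        cls = classify_exon(e, r)
        assert (cls.kind, cls.positions) == ("ir", (2, 3))

    def test_exon_outside_every_reference_exon_is_an_error(self, gene_a):
        r = build_rsoex(gene_a)
        e = ExonRecord(interval=GenomicInterval("chr1", 901, 950, "+"))
        with pytest.raises(ValueError, match="intersects no reference exon"):
            classify_exon(e, r)

    def test_5p_semantics_follow_transcript_orientation(self):
        # on the minus strand the transcript-5' boundary is the genomic end
        ivs = [GenomicInterval("chr1", s, e, "-") for s, e in ((501, 600), (301, 400))]
        t = TranscriptModel("M1", exons=[ExonRecord(interval=iv) for iv in ivs])
        for i, e in enumerate(t.exons, 1):
            e.ordinal = i
        g = GeneModel("G", "G", "syn", "chr1", "-", [t])
        r = build_rsoex(g)
        shortened = ExonRecord(interval=GenomicInterval("chr1", 301, 390, "-"))
        cls = classify_exon(shortened, r)
        assert (cls.kind, cls.position, cls.d5, cls.d3) == ("variant", 2, 1, 0)


class TestEnumerateVariants:
    def test_alternative_boundary_gets_next_variant_index(self):
        gene, _ = fixture_a(include_t3=True, with_sequence=False)
        variants, ir = enumerate_variants(gene, build_rsoex(gene))
        assert ir == []
        at2 = {(v.interval.start, v.interval.end): v for v in variants if v.position == 2}
        assert set(at2) == {(301, 399), (311, 399)}
        canon, var = at2[(301, 399)], at2[(311, 399)]
        assert (canon.five_prime_variant, canon.three_prime_variant) == (0, 0)
        assert (var.five_prime_variant, var.three_prime_variant) == (1, 0)
        assert canon.occurrence == 1 and var.occurrence == 1

    def test_occurrence_counts_transcripts_with_exact_interval(self, gene_a):
        variants, _ = enumerate_variants(gene_a, build_rsoex(gene_a))
        occ = {v.position: v.occurrence for v in variants}
        assert occ == {1: 2, 2: 1, 3: 2, 4: 2}
        assert all(v.is_canonical for v in variants)

    def test_exon_coding_in_one_transcript_utr_in_another_is_mixed(self):
        # same exon: fully coding in TA, entirely 3'UTR in TB
        def t(tid, cds_by_exon):
            exons = []
            for i, (span, cds) in enumerate(cds_by_exon, 1):
                exons.append(
                    ExonRecord(
                        interval=GenomicInterval("chr1", *span, "+"),
                        cds_part=GenomicInterval("chr1", *cds, "+") if cds else None,
                        ordinal=i,
                    )
                )
            return TranscriptModel(tid, exons=exons)

        ta = t("TA", [((101, 160), (131, 160)), ((201, 300), (201, 300)),
                      ((401, 460), (401, 430))])
        tb = t("TB", [((101, 160), (131, 160)), ((201, 300), None)])
        g = GeneModel("G", "G", "syn", "chr1", "+", [ta, tb])
        variants, _ = enumerate_variants(g, build_rsoex(g))
        shared = next(v for v in variants if v.interval.start == 201)
        assert shared.cumulative_coding == "M"
        assert shared.occurrence == 2

    def test_occurrence_conservation_per_position(self):
        # sum of occurrences at a position == non-IR records mapping there
        gene, _, _ = generate_fixture(FixtureSpec(seed=3))
        r = build_rsoex(gene)
        variants, ir = enumerate_variants(gene, r)
        from collections import Counter

        per_pos = Counter()
        for t in gene.transcripts:
            for e in t.exons:
                cls = classify_exon(e, r)
                if cls.kind != "ir":
                    per_pos[cls.position] += 1
        got = Counter()
        for v in variants:
            got[v.position] += v.occurrence
        assert got == per_pos

    def test_variant_side_assignment_matches_boundary_comparison(self):
        # brute-force oracle: compare transcript-oriented boundary coordinates
        rng = random.Random(13)
        for seed in range(25):
            strand = rng.choice("+-")
            gene, _, _ = generate_fixture(FixtureSpec(seed=seed, strand=strand))
            r = build_rsoex(gene)
            variants, _ = enumerate_variants(gene, r)
            for v in variants:
                ref = r.by_position(v.position).interval
                assert (v.five_prime_variant > 0) == (
                    v.interval.five_prime != ref.five_prime
                )
                assert (v.three_prime_variant > 0) == (
                    v.interval.three_prime != ref.three_prime
                )

    def test_every_exon_gets_exactly_one_identifier(self, gene_a_full):
        ann = annotate_gene(gene_a_full)
        euids = ann.euid_by_interval
        seen = set()
        for t in gene_a_full.transcripts:
            for e in t.exons:
                key = (e.interval.start, e.interval.end)
                assert key in euids
                seen.add(euids[key])
        # distinct intervals -> distinct identifiers
        assert len(seen) == len({
            (e.interval.start, e.interval.end)
            for t in gene_a_full.transcripts
            for e in t.exons
        })


class TestEuidCodec:
    @pytest.mark.parametrize(
        "fields,code",
        [
            (("C", 2, 1, 0, 0), "C02100"),
            (("M", 11, 12, 1, 2), "M0BC12"),
            (("N", 1295, 35, 35, 35), "NZZZZZ"),
        ],
    )
    def test_encode_examples(self, fields, code):
        cum, pos, occ, v5, v3 = fields
        assert encode_euid(_variant(cum, pos, occ, v5, v3)) == code
        assert decode_euid(code) == fields

    def test_occurrence_saturates_at_35(self):
        assert encode_euid(_variant(occ=99))[3] == "Z"

    @pytest.mark.parametrize(
        "kwargs", [dict(pos=1296), dict(v5=36), dict(v3=40)]
    )
    def test_capacity_errors(self, kwargs):
        with pytest.raises(CapacityError):
            encode_euid(_variant(**kwargs))

    @given(
        cum=st.sampled_from("CNM"),
        pos=st.integers(1, 1295),
        occ=st.integers(1, 35),
        v5=st.integers(0, 35),
        v3=st.integers(0, 35),
    )
    @settings(derandomize=True, max_examples=300)
    def test_decode_inverts_encode(self, cum, pos, occ, v5, v3):
        code = encode_euid(_variant(cum, pos, occ, v5, v3))
        assert len(code) == 6 and code[0] in "CNM"
        assert decode_euid(code) == (cum, pos, occ, v5, v3)

    def test_invalid_codes_rejected(self):
        for bad in ("X02100", "C0210", "C021$0"):
            with pytest.raises(ValueError):
                decode_euid(bad)


class TestIrEuid:
    def test_ir_combination_joins_component_euids_in_position_order(self):
        gene, _ = fixture_a(include_t4=True, with_sequence=False)
        variants, ir = enumerate_variants(gene, build_rsoex(gene))
        (ev,) = ir
        assert ev.transcript_id == "T4"
        assert ev.spanned_positions == (2, 3)
        assert ir_euid(ev) == "C02100+C03200"
        assert decode_ir_euid(ir_euid(ev)) == [
            ("C", 2, 1, 0, 0), ("C", 3, 2, 0, 0),
        ]

    def test_three_position_ir_yields_three_components(self):
        ivs = [(101, 160), (201, 260), (301, 360), (401, 460)]

        def t(tid, spans):
            exons = [
                ExonRecord(interval=GenomicInterval("chr1", s, e, "+"), ordinal=i)
                for i, (s, e) in enumerate(spans, 1)
            ]
            return TranscriptModel(tid, exons=exons)

        g = GeneModel(
            "G", "G", "syn", "chr1", "+",
            [t("A", ivs), t("B", [ivs[0], (201, 360), ivs[3]]),
             t("C", [(101, 360), ivs[3]])],
        )
        variants, ir = enumerate_variants(g, build_rsoex(g))
        spans = {ev.transcript_id: ev.spanned_positions for ev in ir}
        assert spans == {"B": (2, 3), "C": (1, 2, 3)}
        ev_c = next(ev for ev in ir if ev.transcript_id == "C")
        assert ir_euid(ev_c).count("+") == 2
        positions = [decode_euid(p)[1] for p in ir_euid(ev_c).split("+")]
        assert positions == sorted(positions) == [1, 2, 3]
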