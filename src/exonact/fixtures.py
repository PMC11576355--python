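"""Synthetic gene-model generator with ground-truth tables.

Generates multi-isoform gene models exhibiting the classical alternative
splicing and transcript-end events — exon skipping (in-frame and
frameshifting), alternative 5'/3' splice sites, intron retention, cassette
exon gain, alternative transcription/translation initiation and termination
— together with a truth table stating, for every generated exon, its
expected relative position, classification, splice-site variant indices,
occurrence, coding status and attributed residue range. The truth table is
derived *by construction* and by an independent per-base translation oracle,
never by running the annotator, so the two code paths check each other.

Sequence design: genomic bases are drawn from {A, C, G}; the letter T enters
only through deliberately placed motifs (ATG at translation starts, TAA at
stops, GT at splice donors, with the following base constrained). Since
every stop codon requires a T, no transcript reading frame can contain a
premature stop, whatever combination of events a transcript carries. The
price is an unrealistic base composition; see the methods note.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .annotate import GeneAnnotation
from .gene_model import (
    ExonRecord,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    assign_cds_to_exons,
)

__all__ = [
    "FixtureSpec",
    "TruthRow",
    "TruthTable",
    "FixtureError",
    "ALL_EVENTS",
    "min_positions",
    "generate_fixture",
    "reflect_gene",
    "compare_annotation",
    "oracle_attribution",
    "fixture_a",
    "worked_example_gene",
    "write_fixture",
]

ALL_EVENTS = (
    "skip",
    "frameshift_skip",
    "alt5",
    "alt3",
    "ir",
    "cassette_gain",
    "ati",
    "att",
)

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class FixtureError(ValueError):
    """Infeasible fixture specification."""


def min_positions(events: tuple[str, ...]) -> int:
    """Smallest reference-isoform exon count that can host ``events``.

    Each of skip / frameshift_skip / alt5 / alt3 needs its own internal
    fully-coding exon (indices 3..K-1); intron retention and alternative
    initiation need K >= 5.
    """
    n_slots = sum(
        1 for ev in ("skip", "frameshift_skip", "alt5", "alt3") if ev in events
    )
    k = max(4, 3 + n_slots)
    if "ir" in events or "ati" in events:
        k = max(k, 5)
    return k


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_positions: int = 7  # exon count of the reference isoform
    events: tuple[str, ...] = ALL_EVENTS
    exon_length_range: tuple[int, int] = (60, 150)
    intron_length_range: tuple[int, int] = (40, 180)
    strand: str = "+"
    chrom: str = "chrS"
    gene_id: str = "SYNG1"


@dataclass
class TruthRow:
    """Expected annotation of one exon of one transcript."""

    transcript_id: str
    ordinal: int
    start: int
    end: int
    kind: str  # canonical | variant | ir
    positions: tuple[int, ...]
    v5: int
    v3: int
    occurrence: int
    cumulative: str  # C | N | M
    coding_class: str  # coding | partial | noncoding
    residue_range: Optional[tuple[int, int]]


@dataclass
class TruthTable:
    gene_id: str
    reference_transcript_id: str
    rsoex: dict[int, tuple[int, int]]  # position -> (start, end)
    rows: list[TruthRow] = field(default_factory=list)
    proteins: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# independent residue-attribution oracle (per-base labels + translation)


def oracle_attribution(
    t: TranscriptModel, chrom_seq: str
) -> tuple[dict[int, tuple[int, int]], str, bool]:
    """Residue ranges per exon ordinal via explicit per-base bookkeeping.

    Walks the mRNA base by base, labels every CDS base with its source exon
    ordinal, translates codon by codon with Biopython, and applies the
    base-majority rule (middle base on the 1+1+1 tie). Returns
    (ordinal -> residue range, protein string, stop_included).
    """
    from Bio.Seq import Seq

    strand = t.strand
    bases: list[tuple[str, int]] = []  # (nucleotide, source ordinal), 5'->3'
    for e in t.exons:
        if e.cds_part is None:
            continue
        chunk = chrom_seq[e.cds_part.start - 1 : e.cds_part.end]
        if strand == "-":
            chunk = _revcomp(chunk)
        bases.extend((b, e.ordinal) for b in chunk)
    if not bases:
        return {}, "", False

    n_codons = len(bases) // 3
    owners: list[int] = []
    aas: list[str] = []
    for c in range(n_codons):
        trip = bases[3 * c : 3 * c + 3]
        codon = "".join(b for b, _ in trip)
        labels = [o for _, o in trip]
        counts = {o: labels.count(o) for o in set(labels)}
        best = max(counts.values())
        owner = (
            labels[1] if best == 1 else next(o for o in labels if counts[o] >= 2)
        )
        owners.append(owner)
        aas.append(str(Seq(codon).translate()))
    stop_included = len(bases) % 3 == 0 and aas and aas[-1] == "*"
    if stop_included:
        owners = owners[:-1]
        aas = aas[:-1]
    if "*" in aas:
        raise AssertionError(f"premature stop in generated CDS of {t.transcript_id}")
    ranges: dict[int, tuple[int, int]] = {}
    for i, o in enumerate(owners, start=1):
        if o in ranges:
            lo, hi = ranges[o]
            if i != hi + 1:
                raise AssertionError("non-contiguous residue ownership")
            ranges[o] = (lo, i)
        else:
            ranges[o] = (i, i)
    return ranges, "".join(aas), stop_included


# ---------------------------------------------------------------------------
# geometry helpers


def reflect_gene(g: GeneModel, pivot: Optional[int] = None) -> GeneModel:
    """Mirror all coordinates about a point and flip the strand.

    Relative positions, classifications and attributions of the reflected
    gene are identical to the original's (strand symmetry).
    """
    coords = [e.interval for t in g.transcripts for e in t.exons]
    if pivot is None:
        pivot = min(iv.start for iv in coords) + max(iv.end for iv in coords)
    new_strand = "-" if g.strand == "+" else "+"

    def flip(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(iv.chrom, pivot - iv.end, pivot - iv.start, new_strand)

    transcripts = []
    for t in g.transcripts:
        exons = [
            ExonRecord(
                interval=flip(e.interval),
                cds_part=flip(e.cds_part) if e.cds_part else None,
                ordinal=e.ordinal,
            )
            for e in t.exons
        ]
        transcripts.append(
            TranscriptModel(
                transcript_id=t.transcript_id,
                protein_id=t.protein_id,
                protein_seq=t.protein_seq,
                exons=exons,
            )
        )
    return GeneModel(
        gene_id=g.gene_id,
        symbol=g.symbol,
        organism=g.organism,
        chrom=g.chrom,
        strand=new_strand,
        transcripts=transcripts,
    )


def _reflect_truth(truth: TruthTable, pivot: int) -> TruthTable:
    out = TruthTable(
        gene_id=truth.gene_id,
        reference_transcript_id=truth.reference_transcript_id,
        rsoex={p: (pivot - e, pivot - s) for p, (s, e) in truth.rsoex.items()},
        proteins=dict(truth.proteins),
    )
    for r in truth.rows:
        out.rows.append(
            TruthRow(
                transcript_id=r.transcript_id,
                ordinal=r.ordinal,
                start=pivot - r.end,
                end=pivot - r.start,
                kind=r.kind,
                positions=r.positions,
                v5=r.v5,
                v3=r.v3,
                occurrence=r.occurrence,
                cumulative=r.cumulative,
                coding_class=r.coding_class,
                residue_range=r.residue_range,
            )
        )
    return out


# ---------------------------------------------------------------------------
# the generator


def generate_fixture(spec: FixtureSpec) -> tuple[GeneModel, TruthTable, str]:
    """Build one synthetic gene model, its truth table and its contig sequence.

    Deterministic for a given spec. The reference isoform T1 carries
    ``n_positions`` exons: exon 1 is a pure 5'UTR exon, the CDS starts inside
    exon 2 and ends inside the last exon, exons in between are fully coding.
    One extra transcript is generated per requested event.
    """
    for ev in spec.events:
        if ev not in ALL_EVENTS:
            raise FixtureError(f"unknown event {ev!r}")
    if spec.strand not in ("+", "-"):
        raise FixtureError(f"bad strand {spec.strand!r}")
    K = spec.n_positions
    if K < 4:
        raise FixtureError("n_positions must be >= 4 (UTR exon + >= 2 coding + terminal)")
    rng = random.Random(spec.seed)
    events = set(spec.events)

    # --- slot assignment: internal fully coding exons are 3..K-1 (1-based)
    slots = list(range(3, K))
    slot_of: dict[str, int] = {}
    for ev in ("skip", "frameshift_skip", "alt5", "alt3"):
        if ev in events:
            if not slots:
                raise FixtureError(
                    f"n_positions={K} too small for events {sorted(events)}"
                )
            slot_of[ev] = slots.pop(0)
    if "ir" in events:
        if K < 5:
            raise FixtureError("ir needs n_positions >= 5")
        slot_of["ir"] = 3  # merges exons 3 and 4
    if "ati" in events and K < 5:
        raise FixtureError("ati needs n_positions >= 5")

    lo, hi = spec.exon_length_range
    ilo, ihi = spec.intron_length_range
    if lo < 45 or ilo < 30:
        raise FixtureError("exon lengths must be >= 45 and introns >= 30")

    # --- exon and intron lengths with per-event arithmetic constraints
    exon_len = [rng.randint(lo, hi) for _ in range(K)]
    if "skip" in events:
        s = slot_of["skip"] - 1
        exon_len[s] -= exon_len[s] % 3  # in-frame skip
    if "frameshift_skip" in events:
        s = slot_of["frameshift_skip"] - 1
        if exon_len[s] % 3 == 0:
            exon_len[s] += rng.choice((1, 2))
    intron_len = [rng.randint(ilo, ihi) for _ in range(K - 1)]
    cassette_len = rng.randint(45, 90) if "cassette_gain" in events else 0
    talt_len = rng.randint(45, 90) if "att" in events else 0
    if cassette_len:
        intron_len[0] = 35 + cassette_len + 35
    if talt_len:
        intron_len[K - 2] = 35 + talt_len + 35
    if "ir" in events:
        i = slot_of["ir"] - 1  # intron between exons slot and slot+1
        intron_len[i] -= intron_len[i] % 3  # retained intron keeps the frame

    # --- exon coordinates (built in + orientation, reflected at the end)
    g0 = 1001
    starts, ends = [], []
    pos = g0
    for i in range(K):
        starts.append(pos)
        ends.append(pos + exon_len[i] - 1)
        pos = ends[i] + 1 + (intron_len[i] if i < K - 1 else 0)
    chrom = spec.chrom

    def iv(s: int, e: int) -> GenomicInterval:
        return GenomicInterval(chrom, s, e, "+")

    ref_exons = [iv(starts[i], ends[i]) for i in range(K)]
    cassette_iv = (
        iv(ends[0] + 1 + 35, ends[0] + 35 + cassette_len) if cassette_len else None
    )
    talt_iv = (
        iv(ends[K - 2] + 1 + 35, ends[K - 2] + 35 + talt_len) if talt_len else None
    )

    # --- CDS geometry
    u = rng.randint(12, min(30, exon_len[1] - 12))  # 5'UTR inside exon 2
    cds_start = starts[1] + u
    w = rng.randint(12, min(30, exon_len[K - 1] - 12))  # 3'UTR inside last exon
    total = (exon_len[1] - u) + sum(exon_len[2 : K - 1]) + (exon_len[K - 1] - w)
    w += total % 3  # make the CDS frame-complete
    total -= total % 3
    cds_end = ends[K - 1] - w

    # --- transcripts
    def model(tid: str, exon_ivs: list[GenomicInterval], cds_span) -> TranscriptModel:
        exons = assign_cds_to_exons(exon_ivs, [cds_span], tid) if cds_span else [
            ExonRecord(interval=x) for x in exon_ivs
        ]
        return TranscriptModel(transcript_id=tid, exons=exons, protein_id=f"{tid}.p")

    cds_span = iv(cds_start, cds_end)
    transcripts = [model("T1", list(ref_exons), cds_span)]
    alt_iv: dict[str, GenomicInterval] = {}
    ati_start = att_end = None
    if "skip" in events:
        s = slot_of["skip"]
        transcripts.append(
            model("T2_skip", [x for i, x in enumerate(ref_exons, 1) if i != s], cds_span)
        )
    if "frameshift_skip" in events:
        s = slot_of["frameshift_skip"]
        transcripts.append(
            model("T3_fskip", [x for i, x in enumerate(ref_exons, 1) if i != s], cds_span)
        )
    if "alt5" in events:
        s = slot_of["alt5"]
        d = 3 * rng.randint(3, min(7, (exon_len[s - 1] - 20) // 3))
        alt_iv["alt5"] = iv(starts[s - 1] + d, ends[s - 1])
        exon_ivs = list(ref_exons)
        exon_ivs[s - 1] = alt_iv["alt5"]
        transcripts.append(model("T4_alt5", exon_ivs, cds_span))
    if "alt3" in events:
        s = slot_of["alt3"]
        d = 3 * rng.randint(3, min(7, (exon_len[s - 1] - 20) // 3))
        alt_iv["alt3"] = iv(starts[s - 1], ends[s - 1] - d)
        exon_ivs = list(ref_exons)
        exon_ivs[s - 1] = alt_iv["alt3"]
        transcripts.append(model("T5_alt3", exon_ivs, cds_span))
    if "ir" in events:
        s = slot_of["ir"]
        merged = iv(starts[s - 1], ends[s])
        exon_ivs = [x for i, x in enumerate(ref_exons, 1) if i not in (s, s + 1)]
        exon_ivs.append(merged)
        exon_ivs.sort(key=lambda x: x.start)
        transcripts.append(model("T6_ir", exon_ivs, cds_span))
        alt_iv["ir"] = merged
    if "cassette_gain" in events:
        exon_ivs = sorted(ref_exons + [cassette_iv], key=lambda x: x.start)
        transcripts.append(model("T7_cassette", exon_ivs, cds_span))
    if "ati" in events:
        o = rng.randint(6, 20)
        upstream = exon_len[2] - o  # CDS bases contributed by exon 3 from the new start
        rest = sum(exon_len[3 : K - 1]) + (exon_len[K - 1] - w)
        o += (upstream + rest) % 3  # keep the downstream frame complete
        ati_start = starts[2] + o
        transcripts.append(model("T8_ati", list(ref_exons[2:]), iv(ati_start, cds_end)))
    if "att" in events:
        # >= 21 CDS bases inside the alternative last exon so it owns >= 5
        # residues whatever the junction phase (exon peptides below the
        # mapper's length floor would break self-mapping round trips)
        m = 21
        upstream = (exon_len[1] - u) + sum(exon_len[2 : K - 1])
        m += (3 - (upstream + m) % 3) % 3
        att_end = talt_iv.start + m - 1
        exon_ivs = list(ref_exons[: K - 1]) + [talt_iv]
        transcripts.append(model("T9_att", exon_ivs, iv(cds_start, att_end)))

    gene = GeneModel(
        gene_id=spec.gene_id,
        symbol=spec.gene_id,
        organism="synthetic",
        chrom=chrom,
        strand="+",
        transcripts=sorted(transcripts, key=lambda t: t.transcript_id),
    )

    # --- contig sequence: {A,C,G} background + deliberate motifs
    seq_len = ends[K - 1] + 60
    seq = rng.choices("ACG", k=seq_len)

    def put(pos1: int, motif: str) -> None:
        seq[pos1 - 1 : pos1 - 1 + len(motif)] = list(motif)

    put(cds_start, "ATG")
    put(cds_start + 3, "C")
    put(cds_end - 2, "TAA")
    for i in range(K - 1):  # reference introns: GT...AG, donor followed by C
        put(ends[i] + 1, "GTC")
        put(starts[i + 1] - 2, "AG")
    if cassette_iv is not None:
        put(cassette_iv.start - 2, "AG")
        put(cassette_iv.end + 1, "GTC")
    if talt_iv is not None:
        put(talt_iv.start - 2, "AG")
        put(att_end - 2, "TAA")
    if ati_start is not None:
        put(ati_start, "ATG")
        put(ati_start + 3, "C")
    chrom_seq = "".join(seq)

    # --- truth: RSOEx positions by construction
    rsoex_ivs = list(ref_exons)
    if cassette_iv is not None:
        rsoex_ivs.append(cassette_iv)
    if talt_iv is not None:
        rsoex_ivs.append(talt_iv)
    rsoex_ivs.sort(key=lambda x: x.start)
    pos_of = {(x.start, x.end): i for i, x in enumerate(rsoex_ivs, 1)}
    truth = TruthTable(
        gene_id=spec.gene_id,
        reference_transcript_id="T1",
        rsoex={i: (x.start, x.end) for i, x in enumerate(rsoex_ivs, 1)},
    )

    # occurrence: exact-interval counts; cumulative: aggregated coding classes
    def cls_of(e: ExonRecord) -> str:
        if e.cds_part is None:
            return "noncoding"
        return "coding" if e.cds_part == e.interval else "partial"

    occ: dict[tuple[int, int], set[str]] = {}
    statuses: dict[tuple[int, int], set[str]] = {}
    for t in gene.transcripts:
        for e in t.exons:
            key = (e.interval.start, e.interval.end)
            if key in pos_of or key in {
                (x.start, x.end) for x in alt_iv.values() if x is not alt_iv.get("ir")
            }:
                occ.setdefault(key, set()).add(t.transcript_id)
                statuses.setdefault(key, set()).add(cls_of(e))

    def cumulative(key) -> str:
        st = statuses[key]
        if st == {"coding"}:
            return "C"
        if st == {"noncoding"}:
            return "N"
        return "M"

    # residue attribution truth via the per-base oracle
    residue_truth: dict[str, dict[int, tuple[int, int]]] = {}
    for t in gene.transcripts:
        ranges, protein, stop_inc = oracle_attribution(t, chrom_seq)
        residue_truth[t.transcript_id] = ranges
        if protein:
            t.protein_seq = protein
            truth.proteins[t.transcript_id] = protein

    ir_key = (
        (alt_iv["ir"].start, alt_iv["ir"].end) if "ir" in events else None
    )
    for t in gene.transcripts:
        for e in t.exons:
            key = (e.interval.start, e.interval.end)
            rr = residue_truth[t.transcript_id].get(e.ordinal)
            if key == ir_key:
                s = slot_of["ir"]
                p1 = pos_of[(starts[s - 1], ends[s - 1])]
                p2 = pos_of[(starts[s], ends[s])]
                truth.rows.append(
                    TruthRow(
                        t.transcript_id, e.ordinal, key[0], key[1], "ir",
                        (p1, p2), 0, 0, 0, "", cls_of(e), rr,
                    )
                )
                continue
            if key in pos_of:
                kind, v5, v3, p = "canonical", 0, 0, pos_of[key]
            else:
                # an alternative-boundary variant of a reference exon
                which = next(k for k, x in alt_iv.items() if (x.start, x.end) == key)
                s = slot_of[which]
                p = pos_of[(starts[s - 1], ends[s - 1])]
                kind = "variant"
                v5, v3 = (1, 0) if which == "alt5" else (0, 1)
            truth.rows.append(
                TruthRow(
                    t.transcript_id, e.ordinal, key[0], key[1], kind,
                    (p,), v5, v3, len(occ[key]), cumulative(key), cls_of(e), rr,
                )
            )

    if spec.strand == "-":
        # reverse-complementing a contig of length L maps coordinate x to
        # L - x + 1, i.e. reflection about pivot L + 1: sequence lookups
        # against the reflected coordinates stay valid
        pivot = seq_len + 1
        gene = reflect_gene(gene, pivot=pivot)
        truth = _reflect_truth(truth, pivot)
        chrom_seq = _revcomp(chrom_seq)
    return gene, truth, chrom_seq


# ---------------------------------------------------------------------------
# truth-table comparison


def compare_annotation(truth: TruthTable, ann: GeneAnnotation) -> list[str]:
    """Every way the annotation differs from the truth table (empty = agree)."""
    bad: list[str] = []
    if ann.rsoex.reference_transcript_id != truth.reference_transcript_id:
        bad.append(
            f"reference {ann.rsoex.reference_transcript_id} != "
            f"{truth.reference_transcript_id}"
        )
    got = {r.position: (r.interval.start, r.interval.end) for r in ann.rsoex.exons}
    if got != truth.rsoex:
        bad.append(f"RSOEx positions differ: {got} != {truth.rsoex}")
    variants_by_key = {(v.interval.start, v.interval.end): v for v in ann.variants}
    ir_by_key = {
        (ev.transcript_id, ev.interval.start, ev.interval.end): ev
        for ev in ann.ir_events
    }
    for row in truth.rows:
        where = f"{row.transcript_id} exon {row.ordinal} [{row.start},{row.end}]"
        a = ann.attributions[row.transcript_id]
        entry = a.entry_for(row.ordinal)
        if entry.residue_range != row.residue_range:
            bad.append(
                f"{where}: residues {entry.residue_range} != {row.residue_range}"
            )
        if entry.coding_class != row.coding_class:
            bad.append(f"{where}: class {entry.coding_class} != {row.coding_class}")
        if row.kind == "ir":
            ev = ir_by_key.get((row.transcript_id, row.start, row.end))
            if ev is None:
                bad.append(f"{where}: expected IR event not found")
            elif tuple(sorted(ev.spanned_positions)) != row.positions:
                bad.append(
                    f"{where}: IR spans {ev.spanned_positions} != {row.positions}"
                )
            continue
        v = variants_by_key.get((row.start, row.end))
        if v is None:
            bad.append(f"{where}: no exon entity for interval")
            continue
        if v.position != row.positions[0]:
            bad.append(f"{where}: position {v.position} != {row.positions[0]}")
        if (v.five_prime_variant, v.three_prime_variant) != (row.v5, row.v3):
            bad.append(
                f"{where}: variant indices ({v.five_prime_variant},"
                f"{v.three_prime_variant}) != ({row.v5},{row.v3})"
            )
        kind = "canonical" if v.is_canonical else "variant"
        if kind != row.kind:
            bad.append(f"{where}: kind {kind} != {row.kind}")
        if v.occurrence != row.occurrence:
            bad.append(f"{where}: occurrence {v.occurrence} != {row.occurrence}")
        if v.cumulative_coding != row.cumulative:
            bad.append(f"{where}: cumulative {v.cumulative_coding} != {row.cumulative}")
    for tid, protein in truth.proteins.items():
        if ann.gene.transcript(tid).protein_seq != protein:
            bad.append(f"{tid}: protein sequence changed")
        if ann.attributions[tid].protein_length != len(protein):
            bad.append(
                f"{tid}: protein length {ann.attributions[tid].protein_length} "
                f"!= {len(protein)}"
            )
    return bad


# ---------------------------------------------------------------------------
# hand-built fixtures


def _seq_for_fixture_a(seed: int = 2024) -> str:
    rng = random.Random(seed)
    seq = rng.choices("ACG", k=900)

    def put(pos1: int, motif: str) -> None:
        seq[pos1 - 1 : pos1 - 1 + len(motif)] = list(motif)

    put(161, "ATG")
    put(164, "C")
    put(768, "TAA")
    for end, nxt in ((200, 301), (399, 501), (600, 701)):
        put(end + 1, "GTC")
        put(nxt - 2, "AG")
    return "".join(seq)


def fixture_a(
    include_t3: bool = False,
    include_t4: bool = False,
    include_t5: bool = False,
    with_sequence: bool = True,
) -> tuple[GeneModel, str]:
    """A small hand-built plus-strand gene used throughout the test-suite.

    T1: four exons [101,200] [301,399] [501,600] [701,800], CDS 161-770
    (40+99+100+70 = 309 nt, stop included, 102-aa protein). T2 skips the
    second exon. Optionally: T3 with a 5'ss-shifted second exon [311,399],
    T4 with an intron-retaining exon [301,600], T5 with a cassette exon
    [431,470]. Returns the gene and its contig sequence ('' if disabled).
    """
    chrom, strand = "chr1", "+"

    def iv(s, e):
        return GenomicInterval(chrom, s, e, strand)

    x1, x2, x3, x4 = iv(101, 200), iv(301, 399), iv(501, 600), iv(701, 800)
    cds = iv(161, 770)

    def model(tid, exon_ivs, cds_span=cds):
        return TranscriptModel(
            transcript_id=tid,
            exons=assign_cds_to_exons(exon_ivs, [cds_span], tid),
            protein_id=f"{tid}.p",
        )

    transcripts = [model("T1", [x1, x2, x3, x4]), model("T2", [x1, x3, x4])]
    if include_t3:
        transcripts.append(model("T3", [x1, iv(311, 399), x3, x4]))
    if include_t4:
        transcripts.append(model("T4", [x1, iv(301, 600), x4]))
    if include_t5:
        transcripts.append(model("T5", [x1, x2, iv(431, 470), x3, x4]))
    gene = GeneModel(
        gene_id="GENE1",
        symbol="GENE1",
        organism="synthetic",
        chrom=chrom,
        strand=strand,
        transcripts=transcripts,
    )
    chrom_seq = ""
    if with_sequence:
        chrom_seq = _seq_for_fixture_a()
        for t in gene.transcripts:
            _, protein, _ = oracle_attribution(t, chrom_seq)
            if protein:
                t.protein_seq = protein
    return gene, chrom_seq


def worked_example_gene() -> GeneModel:
    """Synthetic stand-in for the published two-isoform worked example.

    A deterministic, hand-built gene (synthetic: no real accession is
    downloaded) reproducing the described isoform relationship: isoforms A
    and B share four of six exons; isoform A skips the fifth reference exon,
    carries a 5'-truncated sixth exon (variable 5'ss) and a non-coding
    seventh exon that isoform B lacks.
    """
    chrom, strand = "chrW", "+"

    def iv(s, e):
        return GenomicInterval(chrom, s, e, strand)

    exons = [
        iv(1001, 1120),  # 1
        iv(1201, 1290),  # 2
        iv(1401, 1490),  # 3
        iv(1601, 1690),  # 4
        iv(1801, 1890),  # 5 (length 90: in-frame skip)
        iv(2001, 2120),  # 6
    ]
    exon7 = iv(2201, 2280)  # 3'UTR exon, isoform A only
    cds_b = iv(1031, 2078)  # starts in exon 1, ends in exon 6; 528 nt = 176 codons

    def model(tid, exon_ivs, cds_span):
        return TranscriptModel(
            transcript_id=tid,
            exons=assign_cds_to_exons(exon_ivs, [cds_span], tid),
            protein_id=f"{tid}.p",
        )

    iso_b = model("ISO_B", list(exons), cds_b)
    exons_a = exons[:4] + [iv(2031, 2120), exon7]  # skip 5, truncate 6 by 30
    iso_a = model("ISO_A", exons_a, cds_b)
    return GeneModel(
        gene_id="WORKED1",
        symbol="WORKED1",
        organism="synthetic",
        chrom=chrom,
        strand=strand,
        transcripts=[iso_a, iso_b],
    )


# ---------------------------------------------------------------------------
# emission


def write_fixture(
    gene: GeneModel, truth: TruthTable, chrom_seq: str, outdir: str | Path
) -> list[Path]:
    """Emit GFF3 + genome FASTA + protein FASTA + truth TSV for one fixture."""
    from .gene_model import write_gene_models

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = gene.gene_id
    paths = []
    p = outdir / f"{stem}.gff3"
    write_gene_models([gene], p, format="gff3")
    paths.append(p)
    p = outdir / f"{stem}.genome.fa"
    with open(p, "w") as fh:
        fh.write(f">{gene.chrom}\n")
        for i in range(0, len(chrom_seq), 70):
            fh.write(chrom_seq[i : i + 70] + "\n")
    paths.append(p)
    p = outdir / f"{stem}.proteins.fa"
    with open(p, "w") as fh:
        for t in gene.transcripts:
            if t.protein_seq:
                fh.write(f">{t.protein_id or t.transcript_id}\n{t.protein_seq}\n")
    paths.append(p)
    p = outdir / f"{stem}.truth.tsv"
    with open(p, "w") as fh:
        fh.write(
            "transcript_id\tordinal\tstart\tend\tkind\tpositions\tv5\tv3\t"
            "occurrence\tcumulative\tcoding_class\tresidue_start\tresidue_end\n"
        )
        for r in truth.rows:
            rr = r.residue_range
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        r.transcript_id, r.ordinal, r.start, r.end, r.kind,
                        ",".join(map(str, r.positions)), r.v5, r.v3, r.occurrence,
                        r.cumulative or ".", r.coding_class,
                        rr[0] if rr else ".", rr[1] if rr else ".",
                    ]
                )
                + "\n"
            )
    paths.append(p)
    return paths
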