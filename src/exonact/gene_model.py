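"""Domain types for genes, transcripts and exons, plus readers/writers.

Coordinates are 1-based inclusive (GFF3 convention) everywhere; the GTF and
TSV readers normalize to this. "5'" and "3'" always refer to transcript
(mRNA) orientation: on the minus strand the exon with the largest genomic
end is exon 1, and an exon's transcript-5' boundary is its genomic *end*.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "ExonRecord",
    "TranscriptModel",
    "GeneModel",
    "Violation",
    "ModelError",
    "ParseError",
    "read_gene_models",
    "write_gene_models",
    "validate_gene_model",
    "attach_protein_sequences",
    "TSV_COLUMNS",
]


class ParseError(ValueError):
    """Malformed annotation input (bad coordinates, missing columns...)."""


class ModelError(ValueError):
    """Structurally impossible gene model (CDS outside exons, mixed strands)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval [start, end] on one strand of a contig."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParseError(
                f"interval start > end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ParseError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one genomic base."""
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @property
    def five_prime(self) -> int:
        """Transcript-5' boundary coordinate (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        """Transcript-3' boundary coordinate (strand-aware)."""
        return self.end if self.strand == "+" else self.start

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end)


@dataclass
class ExonRecord:
    """One exon of one transcript; ``cds_part`` is its coding sub-interval."""

    interval: GenomicInterval
    cds_part: Optional[GenomicInterval] = None
    ordinal: int = 1

    def __post_init__(self) -> None:
        if self.cds_part is not None and not self.interval.contains(self.cds_part):
            raise ModelError(
                f"CDS part {self.cds_part.start}-{self.cds_part.end} not contained "
                f"in exon {self.interval.start}-{self.interval.end}"
            )


@dataclass
class TranscriptModel:
    """An ordered (5'→3') list of exons with optional protein product."""

    transcript_id: str
    exons: list[ExonRecord] = field(default_factory=list)
    protein_id: Optional[str] = None
    protein_seq: Optional[str] = None

    @property
    def is_coding(self) -> bool:
        return any(e.cds_part is not None for e in self.exons)

    @property
    def coding_exon_count(self) -> int:
        return sum(1 for e in self.exons if e.cds_part is not None)

    @property
    def cds_length(self) -> int:
        return sum(e.cds_part.length for e in self.exons if e.cds_part is not None)

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand


@dataclass
class GeneModel:
    """A gene: all its transcript models on one contig and strand."""

    gene_id: str
    symbol: str
    organism: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass(frozen=True)
class Violation:
    """One broken invariant; violations are data, not exceptions.

    ``severity`` is "error" for structurally impossible models and "warning"
    for suspicious but workable ones (e.g. a frame-incomplete CDS whose full
    codons still match the attached protein).
    """

    rule: str
    where: str
    message: str
    severity: str = "error"


TSV_COLUMNS = [
    "gene_id",
    "symbol",
    "organism",
    "chrom",
    "strand",
    "transcript_id",
    "protein_id",
    "ordinal",
    "exon_start",
    "exon_end",
    "cds_start",
    "cds_end",
]


# ---------------------------------------------------------------------------
# construction helpers


def _sort_exons_5p_to_3p(exons: list[ExonRecord], strand: str) -> list[ExonRecord]:
    exons = sorted(exons, key=lambda e: e.interval.start, reverse=(strand == "-"))
    for i, e in enumerate(exons, start=1):
        e.ordinal = i
    return exons


def assign_cds_to_exons(
    exon_intervals: Sequence[GenomicInterval],
    cds_segments: Sequence[GenomicInterval],
    transcript_id: str = "?",
    allow_span: bool = True,
) -> list[ExonRecord]:
    """Attach CDS sub-intervals to their host exons by containment.

    ``cds_segments`` may be the full per-exon CDS pieces or (with
    ``allow_span``, the TSV convenience) a single genomic CDS span that is
    intersected with each exon. GFF3/GTF readers disable the span form: every
    CDS feature there must be contained in an exon of its transcript.
    """
    strand = exon_intervals[0].strand
    records = [ExonRecord(interval=iv) for iv in exon_intervals]
    if (
        allow_span
        and len(cds_segments) == 1
        and not any(iv.contains(cds_segments[0]) for iv in exon_intervals)
    ):
        # a single spanning CDS interval: intersect with each exon
        span = cds_segments[0]
        pieces = []
        for iv in exon_intervals:
            lo, hi = max(iv.start, span.start), min(iv.end, span.end)
            if lo <= hi:
                pieces.append(GenomicInterval(iv.chrom, lo, hi, strand))
        if not pieces:
            raise ModelError(
                f"CDS span {span.start}-{span.end} overlaps no exon of {transcript_id}"
            )
        cds_segments = pieces
    for seg in cds_segments:
        host = next((r for r in records if r.interval.contains(seg)), None)
        if host is None:
            raise ModelError(
                f"CDS segment {seg.start}-{seg.end} lies in no exon of "
                f"transcript {transcript_id}"
            )
        if host.cds_part is not None:
            # merge adjacent pieces (e.g. a GTF stop_codon abutting the CDS)
            merged = GenomicInterval(
                seg.chrom,
                min(host.cds_part.start, seg.start),
                max(host.cds_part.end, seg.end),
                strand,
            )
            host.cds_part = merged
        else:
            host.cds_part = seg
    out = _sort_exons_5p_to_3p(records, strand)
    return out


# ---------------------------------------------------------------------------
# readers


def read_gene_models(path: str | Path, format: Optional[str] = None) -> list[GeneModel]:
    """Read gene models from GFF3, GTF or the internal TSV dialect.

    ``format`` is one of ``gff3``, ``gtf``, ``tsv``; when omitted it is
    guessed from the file extension.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"gff": "gff3", "gff3": "gff3", "gtf": "gtf", "tsv": "tsv"}.get(suffix)
        if format is None:
            raise ParseError(f"cannot guess annotation format from {path.name!r}")
    if format == "tsv":
        return _read_tsv(path)
    if format in ("gff3", "gtf"):
        return _read_gff(path, dialect=format)
    raise ParseError(f"unknown annotation format {format!r}")


def _read_tsv(path: Path) -> list[GeneModel]:
    rows_by_gene: dict[str, list[dict]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(TSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ParseError(f"TSV missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                row["exon_start"] = int(row["exon_start"])
                row["exon_end"] = int(row["exon_end"])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad exon coordinates") from exc
            if row["exon_start"] > row["exon_end"]:
                raise ParseError(
                    f"line {lineno}: exon start > end "
                    f"({row['exon_start']} > {row['exon_end']})"
                )
            rows_by_gene.setdefault(row["gene_id"], []).append(row)
    genes = []
    for gene_id, rows in rows_by_gene.items():
        strand = rows[0]["strand"]
        chrom = rows[0]["chrom"]
        if any(r["strand"] != strand for r in rows):
            raise ModelError(f"mixed strands within gene {gene_id}")
        transcripts: dict[str, TranscriptModel] = {}
        for r in rows:
            tid = r["transcript_id"]
            t = transcripts.setdefault(
                tid,
                TranscriptModel(
                    transcript_id=tid, protein_id=(r["protein_id"] or None) or None
                ),
            )
            iv = GenomicInterval(chrom, r["exon_start"], r["exon_end"], strand)
            cds = None
            if r["cds_start"] not in (".", "", None):
                cds = GenomicInterval(chrom, int(r["cds_start"]), int(r["cds_end"]), strand)
                if not iv.contains(cds):
                    # a spanning CDS given on every row: intersect with this exon
                    lo, hi = max(iv.start, cds.start), min(iv.end, cds.end)
                    cds = GenomicInterval(chrom, lo, hi, strand) if lo <= hi else None
            t.exons.append(ExonRecord(interval=iv, cds_part=cds))
        for t in transcripts.values():
            t.exons = _sort_exons_5p_to_3p(t.exons, strand)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=rows[0].get("symbol") or gene_id,
                organism=rows[0].get("organism") or "synthetic",
                chrom=chrom,
                strand=strand,
                transcripts=sorted(transcripts.values(), key=lambda t: t.transcript_id),
            )
        )
    return genes


def _read_gff(path: Path, dialect: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    if dialect == "gtf":
        return _genes_from_gtf_db(db)
    return _genes_from_gff3_db(db)


def _attr1(feature, *names) -> Optional[str]:
    for n in names:
        if n in feature.attributes:
            return feature.attributes[n][0]
    return None


def _genes_from_gff3_db(db) -> list[GeneModel]:
    import gffutils  # noqa: F401

    genes: list[GeneModel] = []
    gene_features = list(db.features_of_type("gene"))
    for gf in gene_features:
        transcripts = []
        for tf in db.children(gf, level=1):
            if tf.featuretype not in ("mRNA", "transcript", "ncRNA", "lnc_RNA"):
                continue
            exon_ivs, cds_ivs, protein_id = [], [], None
            for child in db.children(tf, level=1):
                iv = GenomicInterval(child.seqid, child.start, child.end, child.strand)
                if child.featuretype == "exon":
                    exon_ivs.append(iv)
                elif child.featuretype == "CDS":
                    cds_ivs.append(iv)
                    protein_id = protein_id or _attr1(child, "protein_id", "Name")
            if not exon_ivs:
                continue
            if any(iv.strand != gf.strand for iv in exon_ivs):
                raise ModelError(f"mixed strands within gene {gf.id}")
            if cds_ivs:
                exons = assign_cds_to_exons(exon_ivs, cds_ivs, tf.id, allow_span=False)
            else:
                exons = _sort_exons_5p_to_3p(
                    [ExonRecord(interval=iv) for iv in exon_ivs], gf.strand
                )
            transcripts.append(
                TranscriptModel(
                    transcript_id=_attr1(tf, "transcript_id", "ID") or tf.id,
                    protein_id=protein_id,
                    exons=exons,
                )
            )
        if not transcripts:
            continue
        genes.append(
            GeneModel(
                gene_id=_attr1(gf, "gene_id", "ID") or gf.id,
                symbol=_attr1(gf, "Name", "gene_name") or gf.id,
                organism=_attr1(gf, "organism") or "unknown",
                chrom=gf.seqid,
                strand=gf.strand,
                transcripts=sorted(transcripts, key=lambda t: t.transcript_id),
            )
        )
    return genes


def _genes_from_gtf_db(db) -> list[GeneModel]:
    per_gene: dict[str, dict[str, dict]] = {}
    meta: dict[str, dict] = {}
    for ftype in ("exon", "CDS", "stop_codon"):
        for f in db.features_of_type(ftype):
            gid = _attr1(f, "gene_id")
            tid = _attr1(f, "transcript_id")
            if gid is None or tid is None:
                raise ParseError(f"GTF {ftype} feature lacks gene_id/transcript_id")
            slot = per_gene.setdefault(gid, {}).setdefault(
                tid, {"exon": [], "cds": [], "protein_id": None}
            )
            iv = GenomicInterval(f.seqid, f.start, f.end, f.strand)
            if ftype == "exon":
                slot["exon"].append(iv)
            else:  # CDS or stop_codon: stop codons are appended to the CDS
                slot["cds"].append(iv)
                slot["protein_id"] = slot["protein_id"] or _attr1(f, "protein_id")
            m = meta.setdefault(gid, {})
            m.setdefault("chrom", f.seqid)
            m.setdefault("strand", f.strand)
            m.setdefault("symbol", _attr1(f, "gene_name") or gid)
            if f.strand != m["strand"]:
                raise ModelError(f"mixed strands within gene {gid}")
    genes = []
    for gid, tdict in per_gene.items():
        transcripts = []
        for tid, slot in tdict.items():
            if slot["cds"]:
                exons = assign_cds_to_exons(slot["exon"], slot["cds"], tid, allow_span=False)
            else:
                exons = _sort_exons_5p_to_3p(
                    [ExonRecord(interval=iv) for iv in slot["exon"]],
                    meta[gid]["strand"],
                )
            transcripts.append(
                TranscriptModel(transcript_id=tid, protein_id=slot["protein_id"], exons=exons)
            )
        genes.append(
            GeneModel(
                gene_id=gid,
                symbol=meta[gid]["symbol"],
                organism="unknown",
                chrom=meta[gid]["chrom"],
                strand=meta[gid]["strand"],
                transcripts=sorted(transcripts, key=lambda t: t.transcript_id),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# writers


def write_gene_models(
    genes: Iterable[GeneModel], path: str | Path, format: str = "tsv"
) -> None:
    """Serialize gene models; formats ``tsv`` and ``gff3`` round-trip."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(TSV_COLUMNS)
            for g in sorted(genes, key=lambda g: g.gene_id):
                for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
                    for e in t.exons:
                        w.writerow(
                            [
                                g.gene_id,
                                g.symbol,
                                g.organism,
                                g.chrom,
                                g.strand,
                                t.transcript_id,
                                t.protein_id or "",
                                e.ordinal,
                                e.interval.start,
                                e.interval.end,
                                e.cds_part.start if e.cds_part else ".",
                                e.cds_part.end if e.cds_part else ".",
                            ]
                        )
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sorted(genes, key=lambda g: g.gene_id):
                gstart = min(e.interval.start for t in g.transcripts for e in t.exons)
                gend = max(e.interval.end for t in g.transcripts for e in t.exons)
                fh.write(
                    f"{g.chrom}\texonact\tgene\t{gstart}\t{gend}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id};Name={g.symbol};organism={g.organism}\n"
                )
                for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
                    tstart = min(e.interval.start for e in t.exons)
                    tend = max(e.interval.end for e in t.exons)
                    attrs = f"ID={t.transcript_id};Parent={g.gene_id}"
                    fh.write(
                        f"{g.chrom}\texonact\tmRNA\t{tstart}\t{tend}\t.\t{g.strand}\t.\t{attrs}\n"
                    )
                    for e in t.exons:
                        fh.write(
                            f"{g.chrom}\texonact\texon\t{e.interval.start}\t{e.interval.end}"
                            f"\t.\t{g.strand}\t.\tParent={t.transcript_id}\n"
                        )
                    for e in t.exons:
                        if e.cds_part is not None:
                            pid = f";protein_id={t.protein_id}" if t.protein_id else ""
                            fh.write(
                                f"{g.chrom}\texonact\tCDS\t{e.cds_part.start}\t{e.cds_part.end}"
                                f"\t.\t{g.strand}\t.\tParent={t.transcript_id}"
                                f"{pid}\n"
                            )
    else:
        raise ValueError(f"unknown output format {format!r}")


# ---------------------------------------------------------------------------
# validation


def validate_gene_model(g: GeneModel) -> list[Violation]:
    """Check every structural invariant; returns one Violation per breach."""
    out: list[Violation] = []
    if not g.transcripts:
        out.append(Violation("no-transcripts", g.gene_id, "gene has no transcripts"))
        return out
    seen_ids: set[str] = set()
    for t in g.transcripts:
        if t.transcript_id in seen_ids:
            out.append(
                Violation("duplicate-transcript-id", t.transcript_id, "transcript_id not unique")
            )
        seen_ids.add(t.transcript_id)
        if not t.exons:
            out.append(Violation("no-exons", t.transcript_id, "transcript has no exons"))
            continue
        for e in t.exons:
            if e.interval.chrom != g.chrom:
                out.append(
                    Violation("chrom-mismatch", t.transcript_id, f"exon on {e.interval.chrom}")
                )
            if e.interval.strand != g.strand:
                out.append(
                    Violation("strand-mismatch", t.transcript_id, f"exon on {e.interval.strand}")
                )
            if e.cds_part is not None and not e.interval.contains(e.cds_part):
                out.append(
                    Violation(
                        "cds-outside-exon",
                        t.transcript_id,
                        f"CDS {e.cds_part.start}-{e.cds_part.end} escapes exon",
                    )
                )
        # intra-transcript exon overlap
        ivs = sorted((e.interval for e in t.exons), key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.end >= b.start:
                out.append(
                    Violation(
                        "intra-transcript exon overlap",
                        t.transcript_id,
                        f"exons [{a.start},{a.end}] and [{b.start},{b.end}] overlap",
                    )
                )
        # ordinals consecutive and 5'->3' order consistent with strand
        ordinals = [e.ordinal for e in t.exons]
        if ordinals != list(range(1, len(t.exons) + 1)):
            out.append(Violation("ordinal-gap", t.transcript_id, f"ordinals {ordinals}"))
        starts = [e.interval.start for e in t.exons]
        expect = sorted(starts, reverse=(g.strand == "-"))
        if starts != expect:
            out.append(
                Violation(
                    "exon-order", t.transcript_id, "exon list not 5'->3' for strand"
                )
            )
        if t.protein_seq is not None:
            L = len(t.protein_seq)
            cds_len = t.cds_length
            if cds_len not in (3 * L, 3 * (L + 1)):  # stop annotated or not
                # a frame-incomplete CDS whose full codons still yield L
                # residues is workable (attribution drops the trailing bases)
                sev = "warning" if cds_len // 3 == L else "error"
                out.append(
                    Violation(
                        "CDS length/protein length mismatch",
                        t.transcript_id,
                        f"CDS length {cds_len} incompatible with protein length {L}",
                        severity=sev,
                    )
                )
    return out


def attach_protein_sequences(genes: Iterable[GeneModel], fasta_path: str | Path) -> None:
    """Attach protein sequences from a FASTA keyed by protein_id (fallback transcript_id)."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    for g in genes:
        for t in g.transcripts:
            for key in (t.protein_id, t.transcript_id):
                if key and key in seqs:
                    t.protein_seq = seqs[key]
                    break
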