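"""Per-transcript amino-acid attribution of exons and coding status.

Each residue of a protein is written by one codon whose three bases may
straddle an exon junction. The residue is attributed to the exon that
contributes the majority (>= 2) of the codon's bases; in the degenerate
1+1+1 split across three exons, the exon holding the middle base owns the
residue, so the residue→exon map is always a function. The stop codon is
attributed to no residue but its bases still advance phase bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .gene_model import ExonRecord, TranscriptModel

__all__ = [
    "AttributionEntry",
    "CodingAttribution",
    "attribute_residues",
    "coding_status",
    "verify_translation",
]


def coding_status(e: ExonRecord) -> str:
    """``coding`` (interval == CDS part), ``partial`` (proper CDS
    sub-interval: the exon carries UTR and CDS) or ``noncoding``."""
    if e.cds_part is None:
        return "noncoding"
    if e.cds_part == e.interval:
        return "coding"
    return "partial"


@dataclass
class AttributionEntry:
    ordinal: int
    euid: str
    residue_range: Optional[tuple[int, int]]  # inclusive 1-based, None if no residues
    coding_class: str  # coding | partial | noncoding
    start_phase: int
    end_phase: int


@dataclass
class CodingAttribution:
    transcript_id: str
    entries: list[AttributionEntry] = field(default_factory=list)
    protein_length: int = 0
    stop_included: bool = True
    frame_incomplete: bool = False

    def entry_for(self, ordinal: int) -> AttributionEntry:
        return self.entries[ordinal - 1]

    def residue_owner(self, residue: int) -> AttributionEntry:
        for e in self.entries:
            if e.residue_range and e.residue_range[0] <= residue <= e.residue_range[1]:
                return e
        raise KeyError(residue)


def _infer_stop_included(t: TranscriptModel, total: int) -> bool:
    if t.protein_seq is not None:
        return total == 3 * (len(t.protein_seq) + 1)
    # frame-incomplete CDS cannot end on a full stop codon
    return total % 3 == 0


def attribute_residues(
    t: TranscriptModel,
    euids: Optional[dict[tuple[int, int], str]] = None,
    stop_included: Optional[bool] = None,
) -> CodingAttribution:
    """Walk the concatenated CDS 5'→3' and attribute residues to exons.

    ``euids`` optionally maps (exon start, exon end) to the exon's unique
    identifier so attribution entries can carry it. A CDS whose length is not
    a multiple of 3 is flagged ``frame_incomplete``; the trailing sub-codon
    is attributed to no residue.
    """

    def euid_of(e: ExonRecord) -> str:
        if euids is None:
            return ""
        return euids.get((e.interval.start, e.interval.end), "")

    coding = [e for e in t.exons if e.cds_part is not None]
    if not coding:
        return CodingAttribution(
            transcript_id=t.transcript_id,
            entries=[
                AttributionEntry(e.ordinal, euid_of(e), None, "noncoding", 0, 0)
                for e in t.exons
            ],
            protein_length=0,
            stop_included=False,
        )

    total = sum(e.cds_part.length for e in coding)
    if stop_included is None:
        stop_included = _infer_stop_included(t, total)
    frame_incomplete = total % 3 != 0
    n_codons = total // 3
    n_residues = n_codons - 1 if (stop_included and not frame_incomplete) else n_codons

    # cumulative CDS base offsets: coding exon k covers CDS bases (lo_k..hi_k)
    offsets: dict[int, tuple[int, int]] = {}
    c = 0
    for e in coding:
        offsets[e.ordinal] = (c + 1, c + e.cds_part.length)
        c += e.cds_part.length

    def owner(residue: int) -> int:
        """Ordinal of the exon owning codon ``residue`` (majority rule)."""
        b0 = 3 * residue - 2
        best_ord, best_n = None, 0
        for e in coding:
            lo, hi = offsets[e.ordinal]
            n = min(hi, b0 + 2) - max(lo, b0) + 1
            if n >= 2:
                return e.ordinal
            if n == 1 and lo <= b0 + 1 <= hi:  # holds the middle base
                best_ord, best_n = e.ordinal, 1
        if best_ord is None:  # pragma: no cover - unreachable by construction
            raise AssertionError("codon with no owning exon")
        return best_ord

    # majority ownership is monotone along the CDS, so per-exon residue
    # ranges are found from the first residue owned at or after each boundary
    ranges: dict[int, tuple[int, int]] = {}
    if n_residues > 0:
        cur = owner(1)
        start = 1
        r = 1
        while r <= n_residues:
            o = owner(r)
            if o != cur:
                ranges[cur] = (start, r - 1)
                cur, start = o, r
            r += 1
        ranges[cur] = (start, n_residues)

    entries: list[AttributionEntry] = []
    phase = 0
    for e in t.exons:
        cls = coding_status(e)
        if e.cds_part is None:
            entries.append(AttributionEntry(e.ordinal, euid_of(e), None, cls, phase, phase))
        else:
            start_phase = phase
            phase = (phase + e.cds_part.length) % 3
            entries.append(
                AttributionEntry(
                    e.ordinal, euid_of(e), ranges.get(e.ordinal), cls, start_phase, phase
                )
            )
    return CodingAttribution(
        transcript_id=t.transcript_id,
        entries=entries,
        protein_length=n_residues,
        stop_included=stop_included,
        frame_incomplete=frame_incomplete,
    )


def verify_translation(t: TranscriptModel, chrom_seq: str) -> Optional[str]:
    """Translate the annotated CDS and compare with ``protein_seq``.

    Returns a warning string on mismatch, None when consistent or when no
    protein is attached. Mismatches are warnings, not errors (selenoproteins
    and other genetic-code exceptions exist). ``chrom_seq`` is the full
    contig sequence, 1-based coordinates indexing into it.
    """
    from Bio.Seq import Seq

    if t.protein_seq is None or not t.is_coding:
        return None
    parts = []
    for e in t.exons:  # exons are 5'->3'; reverse-complement each piece on -
        if e.cds_part is None:
            continue
        chunk = chrom_seq[e.cds_part.start - 1 : e.cds_part.end]
        if t.strand == "-":
            chunk = str(Seq(chunk).reverse_complement())
        parts.append(chunk)
    cds = "".join(parts)
    aa = str(Seq(cds[: 3 * (len(cds) // 3)]).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if aa != t.protein_seq:
        return (
            f"translated CDS of {t.transcript_id} differs from attached protein "
            f"({len(aa)} vs {len(t.protein_seq)} aa)"
        )
    return None
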