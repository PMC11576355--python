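"""Back-mapping a protein sequence onto the known exons of a gene.

The candidate set is every per-exon attributed peptide of every coding
transcript of the gene (junction residues belong to the exon owning them
under the majority rule, so the same exon can yield candidates differing by
a terminal residue across transcripts). The query is scanned left to right,
taking at each position the longest exactly matching candidate of at least
``min_len`` residues; uncovered stretches come out as UNMAPPED segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .annotate import GeneAnnotation

__all__ = ["MappedSegment", "MappingResult", "exon_peptides", "map_protein_to_exons"]

UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class MappedSegment:
    start: int  # query residues, 1-based inclusive
    end: int
    euid: str  # EUID or "UNMAPPED"
    transcript_id: Optional[str] = None
    position: Optional[int] = None  # RSOEx position of the matched exon
    note: str = ""  # e.g. other exons sharing the identical peptide

    @property
    def is_unmapped(self) -> bool:
        return self.euid == UNMAPPED


@dataclass
class MappingResult:
    query_id: str
    query_length: int
    segments: list[MappedSegment] = field(default_factory=list)

    @property
    def unmapped_residues(self) -> int:
        return sum(s.end - s.start + 1 for s in self.segments if s.is_unmapped)

    @property
    def matched_residues(self) -> int:
        return self.query_length - self.unmapped_residues

    def check_coverage(self) -> None:
        nxt = 1
        for s in self.segments:
            if s.start != nxt or s.end < s.start:
                raise AssertionError("segments do not partition the query")
            nxt = s.end + 1
        if nxt != self.query_length + 1:
            raise AssertionError("segments do not cover the full query")


@dataclass(frozen=True)
class _Candidate:
    peptide: str
    euid: str
    transcript_id: str
    position: int
    note: str = ""


def exon_peptides(ann: GeneAnnotation, min_len: int = 5) -> list[_Candidate]:
    """Deduplicated per-exon attributed peptides of every coding transcript.

    Identical peptide strings from several exons collapse onto the
    lowest-position EUID; the alternatives are listed in the note field.
    """
    raw: dict[str, list[tuple[int, str, str]]] = {}
    for t in ann.gene.transcripts:
        if t.protein_seq is None:
            continue
        a = ann.attributions[t.transcript_id]
        for entry in a.entries:
            if entry.residue_range is None:
                continue
            lo, hi = entry.residue_range
            pep = t.protein_seq[lo - 1 : hi]
            if len(pep) < min_len:
                continue
            euid = entry.euid
            if "+" in euid:  # IR exon: still a legitimate peptide source
                position = ann.ir_events[0].spanned_positions[0] if ann.ir_events else 0
                for ev in ann.ir_events:
                    if ev.transcript_id == t.transcript_id:
                        position = ev.spanned_positions[0]
                        break
            else:
                from .classify import decode_euid

                position = decode_euid(euid)[1]
            raw.setdefault(pep, []).append((position, euid, t.transcript_id))
    out = []
    for pep, hits in raw.items():
        hits = sorted(set(hits))
        position, euid, tid = hits[0]
        alternatives = sorted({h[1] for h in hits[1:]} - {euid})
        note = f"also matches {','.join(alternatives)}" if alternatives else ""
        out.append(_Candidate(pep, euid, tid, position, note))
    return out


def map_protein_to_exons(
    query: str,
    ann: GeneAnnotation,
    min_len: int = 5,
    query_id: str = "query",
) -> MappingResult:
    """Greedy longest-match tiling of ``query`` with known exon peptides."""
    if not query:
        raise ValueError("empty query sequence")
    if not any(t.protein_seq for t in ann.gene.transcripts):
        raise ValueError(
            f"no exon peptides available for gene {ann.gene.gene_id} "
            "(no coding transcript with a protein sequence)"
        )
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    candidates = exon_peptides(ann, min_len=min_len)
    by_first: dict[str, list[_Candidate]] = {}
    for c in candidates:
        by_first.setdefault(c.peptide[0], []).append(c)
    for lst in by_first.values():
        lst.sort(key=lambda c: (-len(c.peptide), c.position, c.euid))

    n = len(query)
    segments: list[MappedSegment] = []
    i = 0
    pending_unmapped_start: Optional[int] = None
    while i < n:
        hit = None
        for c in by_first.get(query[i], ()):
            if query.startswith(c.peptide, i):
                hit = c
                break
        if hit is None:
            if pending_unmapped_start is None:
                pending_unmapped_start = i + 1
            i += 1
            continue
        if pending_unmapped_start is not None:
            segments.append(MappedSegment(pending_unmapped_start, i, UNMAPPED))
            pending_unmapped_start = None
        segments.append(
            MappedSegment(
                start=i + 1,
                end=i + len(hit.peptide),
                euid=hit.euid,
                transcript_id=hit.transcript_id,
                position=hit.position,
                note=hit.note,
            )
        )
        i += len(hit.peptide)
    if pending_unmapped_start is not None:
        segments.append(MappedSegment(pending_unmapped_start, n, UNMAPPED))
    result = MappingResult(query_id=query_id, query_length=n, segments=segments)
    result.check_coverage()
    return result
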