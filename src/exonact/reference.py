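"""Reference isoform selection and the reference set of exons (RSOEx).

The RSOEx is the gene's positional scaffold: the exons of the reference
isoform (the transcript with the most coding exons) expanded with any exon
of another isoform that shares no genomic base with the set, then sorted in
transcript orientation and numbered 1..K. Every exon of every transcript
either sits at one of these relative positions (canonical or splice-site
variant) or spans several of them (intron retention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from intervaltree import IntervalTree

from .gene_model import GeneModel, GenomicInterval

__all__ = [
    "ReferenceExon",
    "ReferenceExonSet",
    "select_reference_isoform",
    "build_rsoex",
    "locate",
]


@dataclass(frozen=True)
class ReferenceExon:
    position: int
    interval: GenomicInterval
    source_transcript: str


@dataclass
class ReferenceExonSet:
    gene_id: str
    reference_transcript_id: str
    exons: list[ReferenceExon]
    _tree: Optional[IntervalTree] = field(default=None, repr=False, compare=False)

    def by_position(self, position: int) -> ReferenceExon:
        return self.exons[position - 1]

    @property
    def tree(self) -> IntervalTree:
        # interval tree uses half-open coordinates; shift end by +1
        if self._tree is None:
            self._tree = IntervalTree()
            for re_ in self.exons:
                self._tree.addi(re_.interval.start, re_.interval.end + 1, re_.position)
        return self._tree


def _ref_sort_key(g: GeneModel):
    # most coding exons; ties: longest CDS, then smallest transcript_id
    return lambda t: (-t.coding_exon_count, -t.cds_length, t.transcript_id)


def select_reference_isoform(g: GeneModel) -> str:
    """Pick the transcript with the most coding exons.

    Ties break on longest total CDS, then lexicographically smallest
    transcript_id. A gene with no coding transcript falls back to the
    transcript with the most exons (same tie-breaks on exon count).
    """
    if not g.transcripts:
        raise ValueError(f"gene {g.gene_id} has no transcripts")
    if any(t.is_coding for t in g.transcripts):
        best = min(g.transcripts, key=_ref_sort_key(g))
    else:
        best = min(
            g.transcripts, key=lambda t: (-len(t.exons), -t.cds_length, t.transcript_id)
        )
    return best.transcript_id


def build_rsoex(g: GeneModel) -> ReferenceExonSet:
    """Construct the reference exon set (deterministic for a given gene).

    Non-reference isoforms are visited in descending coding-exon count (then
    transcript_id), their exons 5'→3'; an exon joins the set iff it shares
    zero genomic bases with every exon already in the set. Passes repeat to a
    fixed point, then positions are assigned in transcript orientation.
    """
    ref_id = select_reference_isoform(g)
    ref = g.transcript(ref_id)
    chosen: list[tuple[GenomicInterval, str]] = [
        (e.interval, ref_id) for e in ref.exons
    ]

    def intersects_any(iv: GenomicInterval) -> bool:
        return any(iv.overlaps(other) for other, _ in chosen)

    others = sorted(
        (t for t in g.transcripts if t.transcript_id != ref_id),
        key=lambda t: (-t.coding_exon_count, t.transcript_id),
    )
    while True:
        added = False
        for t in others:
            for e in t.exons:
                if not intersects_any(e.interval):
                    chosen.append((e.interval, t.transcript_id))
                    added = True
        if not added:
            break

    chosen.sort(key=lambda pair: pair[0].start, reverse=(g.strand == "-"))
    exons = [
        ReferenceExon(position=i, interval=iv, source_transcript=src)
        for i, (iv, src) in enumerate(chosen, start=1)
    ]
    # non-overlap is structural; assert cheaply on every build
    ivs = sorted(e.interval for e in exons)
    for a, b in zip(ivs, ivs[1:]):
        if a.overlaps(b):
            raise AssertionError(f"RSOEx intervals overlap in gene {g.gene_id}")
    return ReferenceExonSet(gene_id=g.gene_id, reference_transcript_id=ref_id, exons=exons)


def locate(interval: GenomicInterval, r: ReferenceExonSet) -> set[int]:
    """Relative positions of the reference exons intersecting ``interval``."""
    return {hit.data for hit in r.tree.overlap(interval.start, interval.end + 1)}
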