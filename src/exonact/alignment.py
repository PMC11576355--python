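"""Multiple-transcript alignment on exon relative positions.

Rows are transcripts (reference isoform first, then lexicographic), columns
are the RSOEx positions 1..K. A cell holds the EUID of the exon the
transcript carries at that position, a gap, or — for intron retention — one
multi-column cell spanning all retained positions, so reading a row's
non-gap cells left to right always reproduces the transcript's exon order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import GeneAnnotation

__all__ = ["AlignmentCell", "AlignmentMatrix", "build_alignment_matrix", "shared_exon_count"]

GAP = "-"


@dataclass(frozen=True)
class AlignmentCell:
    kind: str  # exon | ir | gap
    start_col: int
    end_col: int  # == start_col except for IR spans
    euid: str = GAP

    @property
    def columns(self) -> range:
        return range(self.start_col, self.end_col + 1)


@dataclass
class AlignmentMatrix:
    gene_id: str
    n_columns: int
    rows: dict[str, list[AlignmentCell]] = field(default_factory=dict)
    row_order: list[str] = field(default_factory=list)

    def cell_at(self, transcript_id: str, column: int) -> AlignmentCell:
        for c in self.rows[transcript_id]:
            if c.start_col <= column <= c.end_col:
                return c
        raise KeyError(column)

    def to_grid(self) -> list[list[str]]:
        """Plain string grid; IR spans repeat their combination in each column."""
        grid = []
        for tid in self.row_order:
            row = [GAP] * self.n_columns
            for c in self.rows[tid]:
                for col in c.columns:
                    row[col - 1] = c.euid
            grid.append(row)
        return grid


def build_alignment_matrix(ann: GeneAnnotation) -> AlignmentMatrix:
    """Deterministic transcripts × positions grid of EUIDs."""
    g = ann.gene
    K = len(ann.rsoex.exons)
    ref = ann.rsoex.reference_transcript_id
    order = [ref] + sorted(
        t.transcript_id for t in g.transcripts if t.transcript_id != ref
    )
    euids = ann.euid_by_interval
    ir_by_key = {
        (ev.transcript_id, ev.interval.start, ev.interval.end): ev
        for ev in ann.ir_events
    }
    m = AlignmentMatrix(gene_id=g.gene_id, n_columns=K, row_order=order)
    for tid in order:
        t = g.transcript(tid)
        cells: list[AlignmentCell] = []
        occupied: set[int] = set()
        for e in t.exons:
            key = (e.interval.start, e.interval.end)
            ev = ir_by_key.get((tid, *key))
            if ev is not None:
                cells.append(
                    AlignmentCell(
                        kind="ir",
                        start_col=min(ev.spanned_positions),
                        end_col=max(ev.spanned_positions),
                        euid=ev.euid,
                    )
                )
                occupied.update(ev.spanned_positions)
            else:
                from .classify import decode_euid

                pos = decode_euid(euids[key])[1]
                cells.append(AlignmentCell(kind="exon", start_col=pos, end_col=pos, euid=euids[key]))
                occupied.add(pos)
        cells.sort(key=lambda c: c.start_col)
        for col in range(1, K + 1):
            if col not in occupied:
                cells.append(AlignmentCell(kind="gap", start_col=col, end_col=col))
        cells.sort(key=lambda c: c.start_col)
        m.rows[tid] = cells
        _check_row_fidelity(m, t)
    return m


def _check_row_fidelity(m: AlignmentMatrix, t) -> None:
    """Non-gap cells left to right must reproduce the transcript's exon order."""
    non_gap = [c for c in m.rows[t.transcript_id] if c.kind != "gap"]
    strand = t.exons[0].interval.strand
    exon_order = sorted(t.exons, key=lambda e: e.interval.start, reverse=(strand == "-"))
    if len(non_gap) != len(exon_order):
        raise AssertionError(
            f"row {t.transcript_id}: {len(non_gap)} cells for {len(exon_order)} exons"
        )


def shared_exon_count(m: AlignmentMatrix, t1: str, t2: str) -> int:
    """Columns where both transcripts carry the identical exon EUID.

    IR spans never count as shared single-column exons. Symmetric by
    construction.
    """
    r1 = {c.start_col: c.euid for c in m.rows[t1] if c.kind == "exon"}
    r2 = {c.start_col: c.euid for c in m.rows[t2] if c.kind == "exon"}
    return sum(1 for col, euid in r1.items() if r2.get(col) == euid)
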