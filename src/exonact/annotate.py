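"""End-to-end annotation of a gene model.

``annotate_gene`` ties the stages together: reference isoform selection and
RSOEx construction, exon classification and EUID assignment, per-transcript
residue attribution, and the transcript alignment matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import ExonVariant, IREvent, enumerate_variants
from .coding import CodingAttribution, attribute_residues
from .gene_model import GeneModel, validate_gene_model
from .reference import ReferenceExonSet, build_rsoex

__all__ = ["GeneAnnotation", "annotate_gene"]


@dataclass
class GeneAnnotation:
    """Everything derived from one gene model."""

    gene: GeneModel
    rsoex: ReferenceExonSet
    variants: list[ExonVariant]
    ir_events: list[IREvent]
    attributions: dict[str, CodingAttribution] = field(default_factory=dict)

    @property
    def euid_by_interval(self) -> dict[tuple[int, int], str]:
        """Map (start, end) of every exon entity to its EUID or IR combination."""
        out = {(v.interval.start, v.interval.end): v.euid for v in self.variants}
        for ev in self.ir_events:
            out[(ev.interval.start, ev.interval.end)] = ev.euid
        return out

    def variant_at(self, position: int, interval_key: tuple[int, int]) -> ExonVariant:
        for v in self.variants:
            if v.position == position and (v.interval.start, v.interval.end) == interval_key:
                return v
        raise KeyError((position, interval_key))

    def euid_of_exon(self, transcript_id: str, ordinal: int) -> str:
        t = self.gene.transcript(transcript_id)
        e = t.exons[ordinal - 1]
        return self.euid_by_interval[(e.interval.start, e.interval.end)]

    def summary(self) -> dict:
        """General gene properties: transcript count and exon composition."""
        comp = {"C": 0, "N": 0, "M": 0}
        for v in self.variants:
            comp[v.cumulative_coding] += 1
        return {
            "gene_id": self.gene.gene_id,
            "symbol": self.gene.symbol,
            "organism": self.gene.organism,
            "chrom": self.gene.chrom,
            "strand": self.gene.strand,
            "n_transcripts": len(self.gene.transcripts),
            "n_reference_positions": len(self.rsoex.exons),
            "reference_transcript": self.rsoex.reference_transcript_id,
            "n_exon_entities": len(self.variants),
            "n_ir_events": len(self.ir_events),
            "exon_coding_composition": comp,
        }


def annotate_gene(g: GeneModel, strict: bool = True) -> GeneAnnotation:
    """Run the full annotation pipeline on one gene model.

    With ``strict`` (default) any structural invariant violation raises; set
    it False to annotate best-effort (violations are still available through
    :func:`exonact.gene_model.validate_gene_model`).
    """
    if strict:
        errors = [v for v in validate_gene_model(g) if v.severity == "error"]
        if errors:
            lines = "; ".join(f"{v.rule}@{v.where}" for v in errors)
            raise ValueError(f"gene {g.gene_id} fails validation: {lines}")
    rsoex = build_rsoex(g)
    variants, ir_events = enumerate_variants(g, rsoex)
    ann = GeneAnnotation(gene=g, rsoex=rsoex, variants=variants, ir_events=ir_events)
    euids = ann.euid_by_interval
    for t in g.transcripts:
        ann.attributions[t.transcript_id] = attribute_residues(t, euids=euids)
    return ann
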