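"""Exon classification against the RSOEx and the EUID codec.

Every exon of every transcript is either *canonical* (identical to the
reference exon at its relative position), a *splice-site variant* (overlaps
exactly one reference exon but with one or both boundaries shifted), or an
*intron-retention* (IR) event (overlaps two or more reference exons).

The six-character EUID packs, in order:
  Block I   (char 1)    cumulative coding status: C / N / M
  Block II  (chars 2-3) relative position, base-36, zero-padded
            (char 4)    occurrence frequency, base-36, saturating at 35 ('Z')
  Block III (char 5)    5'-splice-site variant index, base-36
            (char 6)    3'-splice-site variant index, base-36

Occurrence counts the transcripts containing *exactly* this exon interval.
Variant indices number distinct alternative boundaries on a side by their
distance from the canonical boundary (0 = canonical). IR events carry no
single EUID; they are written as the '+'-joined EUIDs of the canonical exons
they span, in ascending position order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .coding import coding_status
from .gene_model import ExonRecord, GeneModel, GenomicInterval
from .reference import ReferenceExonSet, locate

__all__ = [
    "ExonVariant",
    "IREvent",
    "ExonClass",
    "CapacityError",
    "classify_exon",
    "enumerate_variants",
    "encode_euid",
    "decode_euid",
    "ir_euid",
    "decode_ir_euid",
]

_B36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class CapacityError(ValueError):
    """EUID field exceeds its base-36 capacity (position > 1295, index > 35)."""


@dataclass(frozen=True)
class ExonClass:
    """Outcome of classifying one exon record against the RSOEx."""

    kind: str  # canonical | variant | ir
    positions: tuple[int, ...]
    d5: int = 0  # 1 iff transcript-5' boundary differs from the reference exon's
    d3: int = 0

    @property
    def position(self) -> int:
        return self.positions[0]


@dataclass
class ExonVariant:
    """A unique exon entity: one exact interval at one relative position."""

    gene_id: str
    position: int
    interval: GenomicInterval
    five_prime_variant: int
    three_prime_variant: int
    occurrence: int
    cumulative_coding: str  # C | N | M
    transcripts: list[str] = field(default_factory=list)

    @property
    def is_canonical(self) -> bool:
        return self.five_prime_variant == 0 and self.three_prime_variant == 0

    @property
    def euid(self) -> str:
        return encode_euid(self)


@dataclass
class IREvent:
    """One transcript's intron-retaining exon spanning >= 2 reference exons."""

    gene_id: str
    transcript_id: str
    interval: GenomicInterval
    spanned_positions: tuple[int, ...]
    component_euids: list[str] = field(default_factory=list)

    @property
    def euid(self) -> str:
        return ir_euid(self)


def classify_exon(e: ExonRecord, r: ReferenceExonSet) -> ExonClass:
    """Classify one exon record: canonical, splice-site variant, or IR."""
    hits = locate(e.interval, r)
    if not hits:
        raise ValueError(
            f"exon {e.interval.start}-{e.interval.end} intersects no reference exon; "
            f"RSOEx was not built from this gene"
        )
    if len(hits) >= 2:
        return ExonClass(kind="ir", positions=tuple(sorted(hits)))
    pos = next(iter(hits))
    ref_iv = r.by_position(pos).interval
    d5 = int(e.interval.five_prime != ref_iv.five_prime)
    d3 = int(e.interval.three_prime != ref_iv.three_prime)
    kind = "canonical" if (d5 == 0 and d3 == 0) else "variant"
    return ExonClass(kind=kind, positions=(pos,), d5=d5, d3=d3)


def enumerate_variants(
    g: GeneModel, r: ReferenceExonSet
) -> tuple[list[ExonVariant], list[IREvent]]:
    """Group all exons of all transcripts into unique exon entities.

    Distinct alternative boundaries at a position are indexed 1, 2, ... by
    ascending distance from the canonical boundary (which gets 0); ties are
    impossible since boundary coordinates are distinct. Occurrence counts
    transcripts carrying the exact interval, and the cumulative coding status
    is C if the exon is fully coding in every such transcript, N if in none,
    M otherwise (partially coding exons included).
    """
    # exact-interval groups, with the per-transcript coding classes
    groups: dict[tuple[int, int], dict] = {}
    ir_events: list[IREvent] = []
    for t in g.transcripts:
        for e in t.exons:
            cls = classify_exon(e, r)
            if cls.kind == "ir":
                ir_events.append(
                    IREvent(
                        gene_id=g.gene_id,
                        transcript_id=t.transcript_id,
                        interval=e.interval,
                        spanned_positions=cls.positions,
                    )
                )
                continue
            key = (e.interval.start, e.interval.end)
            slot = groups.setdefault(
                key,
                {"interval": e.interval, "position": cls.position, "statuses": [], "tids": []},
            )
            slot["statuses"].append(coding_status(e))
            slot["tids"].append(t.transcript_id)

    # variant boundary indices, per position and per side
    by_pos: dict[int, list[dict]] = {}
    for slot in groups.values():
        by_pos.setdefault(slot["position"], []).append(slot)

    variants: list[ExonVariant] = []
    for pos, slots in by_pos.items():
        ref_iv = r.by_position(pos).interval
        fives = sorted(
            {s["interval"].five_prime for s in slots} - {ref_iv.five_prime},
            key=lambda b: abs(b - ref_iv.five_prime),
        )
        threes = sorted(
            {s["interval"].three_prime for s in slots} - {ref_iv.three_prime},
            key=lambda b: abs(b - ref_iv.three_prime),
        )
        five_idx = {ref_iv.five_prime: 0, **{b: i for i, b in enumerate(fives, 1)}}
        three_idx = {ref_iv.three_prime: 0, **{b: i for i, b in enumerate(threes, 1)}}
        for s in slots:
            statuses = set(s["statuses"])
            if statuses == {"coding"}:
                cum = "C"
            elif statuses == {"noncoding"}:
                cum = "N"
            else:
                cum = "M"
            variants.append(
                ExonVariant(
                    gene_id=g.gene_id,
                    position=pos,
                    interval=s["interval"],
                    five_prime_variant=five_idx[s["interval"].five_prime],
                    three_prime_variant=three_idx[s["interval"].three_prime],
                    occurrence=len(set(s["tids"])),
                    cumulative_coding=cum,
                    transcripts=sorted(set(s["tids"])),
                )
            )
    variants.sort(key=lambda v: (v.position, v.five_prime_variant, v.three_prime_variant))

    # IR component EUIDs: the canonical entity at each spanned position
    canonical_by_pos = {v.position: v for v in variants if v.is_canonical}
    for ev in ir_events:
        ev.component_euids = [
            encode_euid(canonical_by_pos[p]) for p in ev.spanned_positions
        ]
    return variants, ir_events


def encode_euid(v: ExonVariant) -> str:
    """Pack an exon entity's attributes into the six-character EUID."""
    if v.position < 1 or v.position > 1295:
        raise CapacityError(f"position {v.position} out of EUID range (gene {v.gene_id})")
    if v.five_prime_variant > 35 or v.three_prime_variant > 35:
        raise CapacityError(f"variant index > 35 (gene {v.gene_id})")
    if v.occurrence < 1:
        raise ValueError("occurrence must be >= 1")
    if v.cumulative_coding not in ("C", "N", "M"):
        raise ValueError(f"bad coding status {v.cumulative_coding!r}")
    pos = _B36[v.position // 36] + _B36[v.position % 36]
    occ = _B36[min(v.occurrence, 35)]
    return (
        v.cumulative_coding
        + pos
        + occ
        + _B36[v.five_prime_variant]
        + _B36[v.three_prime_variant]
    )


def decode_euid(code: str) -> tuple[str, int, int, int, int]:
    """Inverse of :func:`encode_euid`.

    Returns (cumulative_coding, position, occurrence, five_prime_variant,
    three_prime_variant). Occurrence saturates at 35 in the code, so values
    above 35 are not recoverable.
    """
    if len(code) != 6:
        raise ValueError(f"EUID must have 6 characters, got {code!r}")
    if code[0] not in ("C", "N", "M"):
        raise ValueError(f"EUID Block-I must be C/N/M, got {code!r}")
    try:
        position = _B36.index(code[1]) * 36 + _B36.index(code[2])
        occurrence = _B36.index(code[3])
        d5 = _B36.index(code[4])
        d3 = _B36.index(code[5])
    except ValueError as exc:
        raise ValueError(f"EUID contains non-base-36 character: {code!r}") from exc
    return (code[0], position, occurrence, d5, d3)


def ir_euid(ev: IREvent) -> str:
    """'+'-joined component EUIDs in ascending position order."""
    if not ev.component_euids:
        raise ValueError("IR event has no component EUIDs assigned")
    return "+".join(ev.component_euids)


def decode_ir_euid(code: str) -> list[tuple[str, int, int, int, int]]:
    """Split an IR combination on '+' and decode each component."""
    return [decode_euid(part) for part in code.split("+")]
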