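"""Serialization of annotation results: TSV, JSON, GFF3 and BED writers.

All writers are bit-stable for identical input: keys are sorted, ordering is
canonical, floats use a fixed format. Coordinate conventions per format are
stated in the file headers (BED is 0-based half-open; everything else is
1-based inclusive).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

from .alignment import AlignmentMatrix, build_alignment_matrix
from .annotate import GeneAnnotation
from .features import ExonFeatureSegment, segments_to_json_payload

__all__ = [
    "write_annotation_tsv",
    "write_attribution_tsv",
    "write_rsoex_bed",
    "write_annotation_gff3",
    "write_bundle_json",
    "write_outputs",
]


def write_annotation_tsv(ann: GeneAnnotation, path: str | Path) -> None:
    """Per transcript-exon rows: interval, EUID (or IR combination), coding class."""
    euids = ann.euid_by_interval
    with open(path, "w") as fh:
        fh.write(
            "gene_id\ttranscript_id\tordinal\tchrom\tstart\tend\tstrand\t"
            "euid\tcoding_class\tresidue_start\tresidue_end\n"
        )
        for t in sorted(ann.gene.transcripts, key=lambda t: t.transcript_id):
            a = ann.attributions[t.transcript_id]
            for e in t.exons:
                entry = a.entry_for(e.ordinal)
                rr = entry.residue_range
                fh.write(
                    "\t".join(
                        str(x)
                        for x in [
                            ann.gene.gene_id,
                            t.transcript_id,
                            e.ordinal,
                            e.interval.chrom,
                            e.interval.start,
                            e.interval.end,
                            e.interval.strand,
                            euids[(e.interval.start, e.interval.end)],
                            entry.coding_class,
                            rr[0] if rr else ".",
                            rr[1] if rr else ".",
                        ]
                    )
                    + "\n"
                )


def write_attribution_tsv(ann: GeneAnnotation, path: str | Path) -> None:
    """(transcript, EUID, residue range, coding class, phases) rows."""
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tordinal\teuid\tresidue_start\tresidue_end\t"
            "coding_class\tstart_phase\tend_phase\n"
        )
        for tid in sorted(ann.attributions):
            for entry in ann.attributions[tid].entries:
                rr = entry.residue_range
                fh.write(
                    "\t".join(
                        str(x)
                        for x in [
                            tid,
                            entry.ordinal,
                            entry.euid,
                            rr[0] if rr else ".",
                            rr[1] if rr else ".",
                            entry.coding_class,
                            entry.start_phase,
                            entry.end_phase,
                        ]
                    )
                    + "\n"
                )


def write_rsoex_bed(ann: GeneAnnotation, path: str | Path) -> None:
    """RSOEx as BED (0-based half-open; name = relative position)."""
    with open(path, "w") as fh:
        fh.write(f'track name="{ann.gene.gene_id}_rsoex" description="reference exon set (BED: 0-based half-open)"\n')
        for re_ in ann.rsoex.exons:
            iv = re_.interval
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tpos{re_.position}\t0\t{iv.strand}\n"
            )


def write_annotation_gff3(ann: GeneAnnotation, path: str | Path) -> None:
    """Gene model GFF3 with the EUID carried as an exon attribute."""
    g = ann.gene
    euids = ann.euid_by_interval
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        gstart = min(e.interval.start for t in g.transcripts for e in t.exons)
        gend = max(e.interval.end for t in g.transcripts for e in t.exons)
        fh.write(
            f"{g.chrom}\texonact\tgene\t{gstart}\t{gend}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id};Name={g.symbol}\n"
        )
        for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
            tstart = min(e.interval.start for e in t.exons)
            tend = max(e.interval.end for e in t.exons)
            fh.write(
                f"{g.chrom}\texonact\tmRNA\t{tstart}\t{tend}\t.\t{g.strand}\t.\t"
                f"ID={t.transcript_id};Parent={g.gene_id}\n"
            )
            for e in t.exons:
                euid = euids[(e.interval.start, e.interval.end)]
                fh.write(
                    f"{g.chrom}\texonact\texon\t{e.interval.start}\t{e.interval.end}\t.\t"
                    f"{g.strand}\t.\tParent={t.transcript_id};euid={euid}\n"
                )
            for e in t.exons:
                if e.cds_part is not None:
                    fh.write(
                        f"{g.chrom}\texonact\tCDS\t{e.cds_part.start}\t{e.cds_part.end}\t.\t"
                        f"{g.strand}\t.\tParent={t.transcript_id}\n"
                    )


def bundle_dict(
    ann: GeneAnnotation,
    matrix: Optional[AlignmentMatrix] = None,
    feature_segments: Optional[Iterable[ExonFeatureSegment]] = None,
) -> dict:
    """The full annotation as one JSON-serializable dictionary."""
    if matrix is None:
        matrix = build_alignment_matrix(ann)
    out = {
        "summary": ann.summary(),
        "rsoex": [
            {
                "position": r.position,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "strand": r.interval.strand,
                "source_transcript": r.source_transcript,
            }
            for r in ann.rsoex.exons
        ],
        "exon_entities": [
            {
                "euid": v.euid,
                "position": v.position,
                "start": v.interval.start,
                "end": v.interval.end,
                "five_prime_variant": v.five_prime_variant,
                "three_prime_variant": v.three_prime_variant,
                "occurrence": v.occurrence,
                "cumulative_coding": v.cumulative_coding,
                "transcripts": v.transcripts,
            }
            for v in ann.variants
        ],
        "ir_events": [
            {
                "euid": ev.euid,
                "transcript_id": ev.transcript_id,
                "start": ev.interval.start,
                "end": ev.interval.end,
                "spanned_positions": list(ev.spanned_positions),
            }
            for ev in sorted(
                ann.ir_events, key=lambda ev: (ev.transcript_id, ev.interval.start)
            )
        ],
        "attributions": {
            tid: {
                "protein_length": a.protein_length,
                "stop_included": a.stop_included,
                "frame_incomplete": a.frame_incomplete,
                "entries": [
                    {
                        "ordinal": e.ordinal,
                        "euid": e.euid,
                        "residue_start": e.residue_range[0] if e.residue_range else None,
                        "residue_end": e.residue_range[1] if e.residue_range else None,
                        "coding_class": e.coding_class,
                        "start_phase": e.start_phase,
                        "end_phase": e.end_phase,
                    }
                    for e in a.entries
                ],
            }
            for tid, a in sorted(ann.attributions.items())
        },
        "alignment": {
            "columns": matrix.n_columns,
            "row_order": matrix.row_order,
            "grid": matrix.to_grid(),
        },
    }
    if feature_segments is not None:
        out["feature_segments"] = segments_to_json_payload(feature_segments)
    return out


def write_bundle_json(
    ann: GeneAnnotation,
    path: str | Path,
    matrix: Optional[AlignmentMatrix] = None,
    feature_segments: Optional[Iterable[ExonFeatureSegment]] = None,
) -> None:
    with open(path, "w") as fh:
        json.dump(bundle_dict(ann, matrix, feature_segments), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_outputs(
    ann: GeneAnnotation,
    outdir: str | Path,
    formats: Iterable[str] = ("tsv", "json", "gff3", "bed"),
    feature_segments: Optional[Iterable[ExonFeatureSegment]] = None,
) -> list[Path]:
    """Write every requested serialization under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = ann.gene.gene_id
    written: list[Path] = []
    for fmt in formats:
        if fmt == "tsv":
            p = outdir / f"{stem}.annotation.tsv"
            write_annotation_tsv(ann, p)
            written.append(p)
            p = outdir / f"{stem}.attribution.tsv"
            write_attribution_tsv(ann, p)
            written.append(p)
        elif fmt == "json":
            p = outdir / f"{stem}.bundle.json"
            write_bundle_json(ann, p, feature_segments=feature_segments)
            written.append(p)
        elif fmt == "gff3":
            p = outdir / f"{stem}.annotated.gff3"
            write_annotation_gff3(ann, p)
            written.append(p)
        elif fmt == "bed":
            p = outdir / f"{stem}.rsoex.bed"
            write_rsoex_bed(ann, p)
            written.append(p)
        else:
            raise ValueError(f"unknown output format {fmt!r}")
    return written
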