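"""Mapping predicted protein features onto exons.

Features live in protein coordinates (secondary-structure states, domain
hits, disorder intervals, as produced by external predictors); the residue
attribution of a transcript projects them onto that transcript's exons.
UTR-only exons acquire no segments by construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .coding import CodingAttribution

__all__ = [
    "ProteinFeature",
    "ExonFeatureSegment",
    "FeatureError",
    "map_features_to_exons",
    "secondary_structure_fraction",
    "read_feature_tsv",
    "ss_string_to_features",
    "segments_to_json_payload",
]

FEATURE_KINDS = ("secondary_structure", "domain", "disorder")
_SS_LABELS = {"H": "helix", "E": "strand", "C": "coil"}


class FeatureError(ValueError):
    """Bad feature input (range outside protein, overlapping states...)."""


@dataclass(frozen=True)
class ProteinFeature:
    protein_id: str
    kind: str  # secondary_structure | domain | disorder
    label: str  # helix/strand/coil, domain name, ...
    start: int  # 1-based inclusive residue
    end: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise FeatureError(f"bad residue range {self.start}-{self.end} ({self.label})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ExonFeatureSegment:
    transcript_id: str
    euid: str
    kind: str
    label: str
    start: int  # residue sub-range, inclusive
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def map_features_to_exons(
    features: Sequence[ProteinFeature], a: CodingAttribution
) -> list[ExonFeatureSegment]:
    """Intersect each feature with each exon's attributed residue range.

    Every feature residue lands in exactly one segment (conservation), and
    segments come out ordered by residue coordinate.
    """
    segments: list[ExonFeatureSegment] = []
    for f in features:
        if f.end > a.protein_length:
            raise FeatureError(
                f"feature {f.label} ({f.start}-{f.end}) exceeds protein length "
                f"{a.protein_length} of {a.transcript_id}"
            )
        covered = 0
        for entry in a.entries:
            if entry.residue_range is None:
                continue
            lo = max(f.start, entry.residue_range[0])
            hi = min(f.end, entry.residue_range[1])
            if lo <= hi:
                segments.append(
                    ExonFeatureSegment(
                        transcript_id=a.transcript_id,
                        euid=entry.euid,
                        kind=f.kind,
                        label=f.label,
                        start=lo,
                        end=hi,
                    )
                )
                covered += hi - lo + 1
        if covered != f.length:
            raise AssertionError(
                f"feature {f.label} residues not conserved ({covered} != {f.length})"
            )
    segments.sort(key=lambda s: (s.start, s.end, s.kind, s.label))
    return segments


def secondary_structure_fraction(
    features: Sequence[ProteinFeature], L: int
) -> dict[str, float]:
    """Fraction of residues in each secondary-structure state.

    Returns one fraction per state plus their ``structured`` sum
    (helix + strand), all in [0, 1] relative to protein length ``L``.
    """
    if L < 1:
        raise FeatureError("protein length must be >= 1")
    ss = sorted(
        (f for f in features if f.kind == "secondary_structure"),
        key=lambda f: f.start,
    )
    for a, b in zip(ss, ss[1:]):
        if a.end >= b.start:
            raise FeatureError(
                f"overlapping secondary-structure ranges {a.start}-{a.end} / {b.start}-{b.end}"
            )
    totals: dict[str, int] = {}
    for f in ss:
        totals[f.label] = totals.get(f.label, 0) + f.length
    out = {label: n / L for label, n in sorted(totals.items())}
    out["structured"] = sum(
        n / L for label, n in totals.items() if label in ("helix", "strand")
    )
    return out


def read_feature_tsv(
    path: str | Path, columns: Optional[dict[str, str]] = None
) -> list[ProteinFeature]:
    """Read a flat feature TSV (protein_id, kind, label, start, end, score).

    ``columns`` maps our column names to the file's (so Pfam-style tables can
    be consumed with a column-mapping config); score may be '.' for missing.
    """
    colmap = {c: c for c in ("protein_id", "kind", "label", "start", "end", "score")}
    if columns:
        colmap.update(columns)
    feats: list[ProteinFeature] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            score_raw = row.get(colmap["score"], ".")
            feats.append(
                ProteinFeature(
                    protein_id=row[colmap["protein_id"]],
                    kind=row[colmap["kind"]],
                    label=row[colmap["label"]],
                    start=int(row[colmap["start"]]),
                    end=int(row[colmap["end"]]),
                    score=None if score_raw in (".", "", None) else float(score_raw),
                )
            )
    return feats


def ss_string_to_features(protein_id: str, ss: str) -> list[ProteinFeature]:
    """Convert a per-residue secondary-structure string (H/E/C) to intervals.

    Runs of the same state become one feature; characters outside the H/E/C
    alphabet are rejected.
    """
    bad = set(ss) - set(_SS_LABELS)
    if bad:
        raise FeatureError(f"unknown secondary-structure state(s): {sorted(bad)}")
    feats: list[ProteinFeature] = []
    i = 0
    while i < len(ss):
        j = i
        while j + 1 < len(ss) and ss[j + 1] == ss[i]:
            j += 1
        feats.append(
            ProteinFeature(
                protein_id=protein_id,
                kind="secondary_structure",
                label=_SS_LABELS[ss[i]],
                start=i + 1,
                end=j + 1,
            )
        )
        i = j + 1
    return feats


def segments_to_json_payload(
    segments: Iterable[ExonFeatureSegment],
) -> dict[str, dict[str, list[dict]]]:
    """Segments keyed by transcript then EUID (track-viewer payload)."""
    out: dict[str, dict[str, list[dict]]] = {}
    for s in sorted(segments, key=lambda s: (s.transcript_id, s.euid, s.start)):
        out.setdefault(s.transcript_id, {}).setdefault(s.euid, []).append(
            {"kind": s.kind, "label": s.label, "start": s.start, "end": s.end}
        )
    return out
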