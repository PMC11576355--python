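"""Protein-feature → exon mapping and secondary-structure fractions."""

import pytest

from exonact.annotate import annotate_gene
from exonact.coding import attribute_residues
from exonact.features import (
    FeatureError,
    ProteinFeature,
    map_features_to_exons,
    read_feature_tsv,
    secondary_structure_fraction,
    segments_to_json_payload,
    ss_string_to_features,
)
from exonact.fixtures import worked_example_gene


def _domain(start, end, label="DomX", protein_id="T1.p"):
    return ProteinFeature(protein_id, "domain", label, start, end)


def test_feature_spanning_junctions_splits_by_exon(ann_a):
    a = ann_a.attributions["T1"]
    segs = map_features_to_exons([_domain(10, 50)], a)
    assert [(s.start, s.end) for s in segs] == [(10, 13), (14, 46), (47, 50)]
    assert [s.length for s in segs] == [4, 33, 4]
    assert sum(s.length for s in segs) == 41 == 50 - 10 + 1
    euids = {e.euid for e in a.entries if e.residue_range}
    assert all(s.euid in euids for s in segs)


def test_feature_inside_one_exon_is_a_single_segment(ann_a):
    segs = map_features_to_exons([_domain(20, 40)], ann_a.attributions["T1"])
    assert [(s.start, s.end, s.kind, s.label) for s in segs] == [
        (20, 40, "domain", "DomX")
    ]


def test_feature_conservation_for_every_feature(ann_a):
    feats = [_domain(1, 102), _domain(13, 14), _domain(46, 81, "DomY")]
    segs = map_features_to_exons(feats, ann_a.attributions["T1"])
    per_label = {}
    for s in segs:
        per_label[(s.label, s.kind)] = per_label.get((s.label, s.kind), 0) + s.length
    assert per_label[("DomX", "domain")] == 102 + 2
    assert per_label[("DomY", "domain")] == 36


def test_mapping_segments_back_is_idempotent(ann_a):
    a = ann_a.attributions["T1"]
    segs = map_features_to_exons([_domain(10, 50)], a)
    again = map_features_to_exons(
        [ProteinFeature("T1.p", s.kind, s.label, s.start, s.end) for s in segs], a
    )
    assert [(s.start, s.end, s.euid) for s in again] == [
        (s.start, s.end, s.euid) for s in segs
    ]


def test_feature_beyond_protein_length_is_rejected(ann_a):
    with pytest.raises(FeatureError, match="exceeds protein length"):
        map_features_to_exons([_domain(90, 110)], ann_a.attributions["T1"])


def test_repeated_domain_counts_differ_between_isoforms():
    """Isoform-specific domain calls map to isoform-specific exon segments."""
    g = worked_example_gene()
    ann = annotate_gene(g)
    la = ann.attributions["ISO_A"].protein_length
    lb = ann.attributions["ISO_B"].protein_length
    assert lb > la > 0
    dom_b = [
        ProteinFeature("ISO_B.p", "domain", "Kinase", 20, 110),
        ProteinFeature("ISO_B.p", "domain", "Kinase", 150, min(240, lb)),
    ]
    dom_a = [ProteinFeature("ISO_A.p", "domain", "Kinase", 20, 110)]
    segs_b = map_features_to_exons(dom_b, ann.attributions["ISO_B"])
    segs_a = map_features_to_exons(dom_a, ann.attributions["ISO_A"])

    def occurrences(segs):
        # contiguous runs of same-label segments = domain occurrences
        runs, prev_end = 0, None
        for s in segs:
            if prev_end is None or s.start != prev_end + 1:
                runs += 1
            prev_end = s.end
        return runs

    assert occurrences(segs_b) == 2
    assert occurrences(segs_a) == 1


class TestSecondaryStructureFraction:
    def test_half_helix(self):
        f = [ProteinFeature("p", "secondary_structure", "helix", 1, 51)]
        assert secondary_structure_fraction(f, 102)["helix"] == 0.5

    def test_no_features_gives_zero_structured(self):
        out = secondary_structure_fraction([], 100)
        assert out == {"structured": 0.0}

    def test_two_states(self):
        f = [
            ProteinFeature("p", "secondary_structure", "helix", 1, 10),
            ProteinFeature("p", "secondary_structure", "strand", 11, 20),
        ]
        out = secondary_structure_fraction(f, 100)
        assert out["helix"] == 0.10 and out["strand"] == 0.10
        assert out["structured"] == pytest.approx(0.20)

    def test_overlapping_states_rejected(self):
        f = [
            ProteinFeature("p", "secondary_structure", "helix", 1, 10),
            ProteinFeature("p", "secondary_structure", "strand", 10, 20),
        ]
        with pytest.raises(FeatureError, match="overlapping"):
            secondary_structure_fraction(f, 100)


def test_ss_string_round_trips_through_intervals():
    ss = "HHHHECCCEEH"
    feats = ss_string_to_features("p1", ss)
    assert [(f.label, f.start, f.end) for f in feats] == [
        ("helix", 1, 4), ("strand", 5, 5), ("coil", 6, 8),
        ("strand", 9, 10), ("helix", 11, 11),
    ]
    assert sum(f.length for f in feats) == len(ss)
    with pytest.raises(FeatureError):
        ss_string_to_features("p1", "HHXX")


def test_feature_tsv_reader_with_column_mapping(tmp_path):
    p = tmp_path / "pfam.tsv"
    p.write_text(
        "acc\ttype\tname\tfrom\tto\tevalue\n"
        "T1.p\tdomain\tThymidylate_kin\t12\t90\t1e-30\n"
    )
    (f,) = read_feature_tsv(
        p,
        columns={"protein_id": "acc", "kind": "type", "label": "name",
                 "start": "from", "end": "to", "score": "evalue"},
    )
    assert (f.protein_id, f.label, f.start, f.end) == ("T1.p", "Thymidylate_kin", 12, 90)
    assert f.score == pytest.approx(1e-30)


def test_json_payload_is_keyed_by_transcript_then_euid(ann_a):
    segs = map_features_to_exons([_domain(10, 50)], ann_a.attributions["T1"])
    payload = segments_to_json_payload(segs)
    assert set(payload) == {"T1"}
    assert sum(len(v) for v in payload["T1"].values()) == 3
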