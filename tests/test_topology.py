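import random

import pytest

from topopalm.simulate import SynthParams, generate_proteome
from topopalm.topology import (
    ProteinRecord,
    SegmentKind,
    TMOrientation,
    TopologyError,
    TopologySegment,
    assign_tm_orientation,
    canonicalize_kind,
    parse_uniprot_feature_string,
    read_proteome,
    write_proteome,
)


class TestParseFeatureString:
    def test_plain_transmem_span(self):
        segs = parse_uniprot_feature_string("TRANSMEM 51..71")
        assert len(segs) == 1
        assert segs[0].kind is SegmentKind.TRANSMEMBRANE
        assert (segs[0].start, segs[0].end) == (51, 71)

    def test_topo_dom_keeps_raw_label(self):
        segs = parse_uniprot_feature_string('TOPO_DOM 1..50; /note="Lumenal"')
        assert (segs[0].start, segs[0].end) == (1, 50)
        assert segs[0].raw_label == "Lumenal"
        assert segs[0].kind is SegmentKind.EXTRACELLULAR

    @pytest.mark.parametrize(
        "text",
        ["TRANSMEM 71..51", "TRANSMEM a..b", 'TOPO_DOM 1..50'],
        ids=["inverted-span", "non-numeric", "topo-dom-without-note"],
    )
    def test_malformed_field_raises(self, text):
        with pytest.raises(TopologyError):
            parse_uniprot_feature_string(text, accession="P1")

    def test_triple_dot_dialect_accepted(self):
        segs = parse_uniprot_feature_string("TRANSMEM 51...71")
        assert (segs[0].start, segs[0].end) == (51, 71)

    def test_empty_text_gives_no_segments(self):
        assert parse_uniprot_feature_string("") == []
        assert parse_uniprot_feature_string(None) == []

    def test_multiple_features_sorted_by_start(self):
        text = (
            'TRANSMEM 90..110; /note="Helical"; '
            'TRANSMEM 51..71; /note="Helical"'
        )
        segs = parse_uniprot_feature_string(text)
        assert [s.start for s in segs] == [51, 90]


class TestCanonicalizeKind:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("Lumenal", SegmentKind.EXTRACELLULAR),
            ("Stromal", SegmentKind.EXTRACELLULAR),
            ("Extracellular", SegmentKind.EXTRACELLULAR),
            ("Cytoplasmic", SegmentKind.CYTOPLASMIC),
            ("Helical", SegmentKind.TRANSMEMBRANE),
        ],
    )
    def test_known_labels(self, label, expected):
        assert canonicalize_kind(label) is expected

    def test_unknown_label_is_explicit_error(self):
        with pytest.raises(TopologyError, match="Mitochondrial intermembrane"):
            canonicalize_kind("Mitochondrial intermembrane")


class TestOrientation:
    def _kinds(self, *triples):
        return [TopologySegment(kind=k, start=a, end=b) for k, a, b in triples]

    def test_extracellular_predecessor_means_inward(self):
        segs = assign_tm_orientation(
            self._kinds(
                (SegmentKind.EXTRACELLULAR, 1, 50),
                (SegmentKind.TRANSMEMBRANE, 51, 71),
                (SegmentKind.CYTOPLASMIC, 72, 120),
            )
        )
        assert segs[1].orientation is TMOrientation.INWARD

    def test_cytoplasmic_predecessor_means_outward(self):
        segs = assign_tm_orientation(
            self._kinds(
                (SegmentKind.CYTOPLASMIC, 1, 10),
                (SegmentKind.TRANSMEMBRANE, 11, 31),
                (SegmentKind.EXTRACELLULAR, 32, 60),
            )
        )
        assert segs[1].orientation is TMOrientation.OUTWARD

    def test_n_terminal_tm_without_predecessor_stays_unknown(self):
        segs = assign_tm_orientation(
            self._kinds(
                (SegmentKind.TRANSMEMBRANE, 1, 21),
                (SegmentKind.CYTOPLASMIC, 22, 60),
            )
        )
        assert segs[0].orientation is TMOrientation.UNKNOWN

    def test_orientation_invariant_to_input_order(self):
        triples = [
            (SegmentKind.CYTOPLASMIC, 1, 10),
            (SegmentKind.TRANSMEMBRANE, 11, 31),
            (SegmentKind.EXTRACELLULAR, 32, 60),
            (SegmentKind.TRANSMEMBRANE, 61, 80),
            (SegmentKind.CYTOPLASMIC, 81, 120),
        ]
        reference = assign_tm_orientation(self._kinds(*triples))
        rnd = random.Random(0)
        for _ in range(10):
            shuffled = self._kinds(*triples)
            rnd.shuffle(shuffled)
            assert assign_tm_orientation(shuffled) == reference

    def test_alternating_multipass_alternates_orientation(self, small_proteome):
        checked = 0
        for protein in small_proteome:
            tms = [
                s
                for s in protein.segments
                if s.kind is SegmentKind.TRANSMEMBRANE
            ]
            orientations = [t.orientation for t in tms]
            assert TMOrientation.UNKNOWN not in orientations
            for a, b in zip(orientations[:-1], orientations[1:]):
                assert a is not b
                checked += 1
        assert checked > 0


class TestRecordValidation:
    def test_segment_beyond_sequence_rejected(self):
        with pytest.raises(TopologyError):
            ProteinRecord(
                accession="P1",
                sequence="ACDEF",
                segments=(
                    TopologySegment(
                        kind=SegmentKind.TRANSMEMBRANE, start=1, end=10
                    ),
                ),
            )

    def test_overlapping_segments_rejected(self):
        with pytest.raises(TopologyError):
            ProteinRecord(
                accession="P1",
                sequence="A" * 60,
                segments=(
                    TopologySegment(SegmentKind.CYTOPLASMIC, 1, 30),
                    TopologySegment(SegmentKind.TRANSMEMBRANE, 25, 45),
                ),
            )


class TestProteomeIO:
    def test_join_semantics_and_exclusions(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(
            ">P1\nMAACDEFGHIKLMNPQRSTVWY\n"
            ">P2\nMCCDEFGHIKLMNPQRSTVWYA\n"
            ">P3\nMAADEFGHIKLMNPQRSTVWYC\n"
        )
        ann = tmp_path / "a.tsv"
        ann.write_text(
            "Entry\tTransmembrane\tTopological domain\n"
            'P1\tTRANSMEM 5..15; /note="Helical"\t'
            'TOPO_DOM 1..4; /note="Cytoplasmic"; '
            'TOPO_DOM 16..22; /note="Extracellular"\n'
            'P2\tTRANSMEM 3..13; /note="Helical"\t\n'
        )
        result = read_proteome(fasta, ann)
        assert sorted(r.accession for r in result.records) == ["P1", "P2"]
        assert ("P3", "no annotation row") in result.excluded

    def test_empty_annotation_excludes_everything(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(">P1\nMAAC\n>P2\nMCCA\n")
        ann = tmp_path / "a.tsv"
        ann.write_text("Entry\tTransmembrane\n")
        result = read_proteome(fasta, ann)
        assert result.records == []
        assert len(result.excluded) == 2

    def test_duplicate_accession_is_error(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(">P1\nMAAC\n>P1\nMCCA\n")
        ann = tmp_path / "a.tsv"
        ann.write_text("Entry\tTransmembrane\nP1\tTRANSMEM 1..2\n")
        with pytest.raises(TopologyError, match="duplicate"):
            read_proteome(fasta, ann)

    def test_out_of_range_annotation_excluded_with_reason(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(">P1\nMAAC\n")
        ann = tmp_path / "a.tsv"
        ann.write_text("Entry\tTransmembrane\nP1\tTRANSMEM 2..99\n")
        result = read_proteome(fasta, ann)
        assert result.records == []
        assert result.excluded[0][0] == "P1"
        assert "exceeds" in result.excluded[0][1]

    def test_generator_round_trip_is_exact(self, tmp_path, small_proteome):
        sample = small_proteome[:25]
        write_proteome(sample, tmp_path / "p.fasta", tmp_path / "a.tsv")
        back = read_proteome(tmp_path / "p.fasta", tmp_path / "a.tsv")
        assert back.excluded == []
        by_acc = {r.accession: r for r in back.records}
        assert len(by_acc) == len(sample)
        for original in sample:
            rebuilt = by_acc[original.accession]
            assert rebuilt.sequence == original.sequence
            assert [
                (s.kind, s.start, s.end, s.orientation)
                for s in rebuilt.segments
            ] == [
                (s.kind, s.start, s.end, s.orientation)
                for s in original.segments
            ]
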