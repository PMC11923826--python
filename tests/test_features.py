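import math

import numpy as np
import pandas as pd
import pytest

from topopalm.features import (
    CYS_SCORE_WEIGHTS,
    FEATURE_NAMES,
    SiteIneligible,
    extract_windows,
    feature_registry_hash,
    featurize_proteome,
    featurize_site,
    hydropathy_block,
    interface_distance,
    locate_topology,
    property_block,
    window_cys_score,
)
from topopalm.topology import SegmentKind, TMOrientation

from .conftest import make_protein
from .oracles import scan_interface_oracle


class TestLocateTopology:
    @pytest.fixture()
    def segments(self, toy_protein):
        return toy_protein.segments

    @pytest.mark.parametrize(
        "position,dist_start,dist_end,rel",
        [(72, 0, 48, 0.0), (120, 48, 0, 1.0), (96, 24, 24, 0.5)],
    )
    def test_cytoplasmic_offsets(self, segments, position, dist_start,
                                 dist_end, rel):
        seg, ds, de, r = locate_topology(position, segments)
        assert seg.kind is SegmentKind.CYTOPLASMIC
        assert (ds, de) == (dist_start, dist_end)
        assert r == pytest.approx(rel)

    def test_gap_position_is_ineligible(self):
        protein = make_protein(
            "GAP1",
            "A" * 100,
            [
                (SegmentKind.CYTOPLASMIC, 1, 30),
                (SegmentKind.TRANSMEMBRANE, 41, 60),
            ],
        )
        with pytest.raises(SiteIneligible, match="gap"):
            locate_topology(35, protein.segments)


class TestInterfaceDistance:
    def _dist(self, protein, position):
        seg, *_ = locate_topology(position, protein.segments)
        return interface_distance(position, seg, protein)

    def test_last_residue_of_inward_tm_is_zero(self, toy_protein):
        # TM 51-71 is inward (extracellular predecessor)
        assert self._dist(toy_protein, 71) == 0

    def test_cytoplasmic_tail_counts_from_segment_start(self, toy_protein):
        assert self._dist(toy_protein, 75) == 3

    def test_internal_loop_takes_nearer_interface(self):
        protein = make_protein(
            "LOOP1",
            "A" * 140,
            [
                (SegmentKind.EXTRACELLULAR, 1, 20),
                (SegmentKind.TRANSMEMBRANE, 21, 40),
                (SegmentKind.CYTOPLASMIC, 41, 80),  # loop flanked by TMs
                (SegmentKind.TRANSMEMBRANE, 81, 100),
                (SegmentKind.EXTRACELLULAR, 101, 140),
            ],
        )
        # offsets 5 (from 41) and 11 (to 80) fall at position 46 ... 69
        assert self._dist(protein, 46) == 5
        assert self._dist(protein, 69) == 11
        assert self._dist(protein, 75) == 5  # nearer the downstream TM

    def test_outward_tm_counts_from_segment_start(self):
        protein = make_protein(
            "OUT1",
            "A" * 80,
            [
                (SegmentKind.CYTOPLASMIC, 1, 10),
                (SegmentKind.TRANSMEMBRANE, 11, 31),
                (SegmentKind.EXTRACELLULAR, 32, 80),
            ],
        )
        assert self._dist(protein, 11) == 0
        assert self._dist(protein, 20) == 9

    def test_agrees_with_scan_outward_oracle(self, small_proteome):
        checked = 0
        for protein in small_proteome:
            for position in protein.cys_positions():
                try:
                    seg, *_ = locate_topology(position, protein.segments)
                    if seg.kind in (SegmentKind.SIGNAL,
                                    SegmentKind.INTRAMEMBRANE):
                        continue
                    ours = interface_distance(position, seg, protein)
                except SiteIneligible:
                    continue
                expected = scan_interface_oracle(protein, position)
                if expected is None:
                    continue
                assert ours == expected, (protein.accession, position)
                checked += 1
        assert checked >= 500


class TestWindows:
    def test_interior_position_gives_two_pentamers(self):
        n, c = extract_windows("A" * 300, 100)
        assert len(n) == len(c) == 5

    def test_truncation_near_n_terminus(self):
        n, c = extract_windows("ABCDEFGHIJ", 3)
        assert (n, c) == ("AB", "DEFGH")

    def test_first_position_has_empty_n_window(self):
        n, c = extract_windows("ABCDEFGHIJ", 1)
        assert n == ""
        assert c == "BCDEF"

    def test_windows_never_contain_the_central_residue(self):
        seq = "AAAACAAAA"
        n, c = extract_windows(seq, 5)
        assert "C" not in n + c


class TestWindowCysScore:
    def test_no_cys_scores_zero(self):
        assert window_cys_score("AAAAA", "GGGGG") == 0.0

    def test_adjacent_cys_on_both_sides(self):
        assert window_cys_score("AAAAC", "CAAAA") == pytest.approx(2.0)

    def test_single_distal_cys(self):
        assert window_cys_score("CAAAA", "AAAAA") == pytest.approx(0.2)

    def test_weights_decay_with_distance(self):
        assert list(CYS_SCORE_WEIGHTS) == pytest.approx(
            [1.0, 0.8, 0.6, 0.4, 0.2]
        )


class TestHydropathyBlock:
    def test_ile_vs_arg_windows(self):
        mean_n, mean_c, total, gradient = hydropathy_block("IIIII", "RRRRR")
        assert mean_n == pytest.approx(4.5)
        assert mean_c == pytest.approx(-4.5)
        assert total == pytest.approx(0.0)
        assert gradient == pytest.approx(-9.0)

    def test_identical_windows_have_zero_gradient(self):
        *_, gradient = hydropathy_block("LMNPQ", "LMNPQ")
        assert gradient == pytest.approx(0.0)

    def test_mirror_site_negates_gradient(self, small_proteome):
        protein = small_proteome[0]
        seq = protein.sequence
        length = len(seq)
        checked = 0
        for position in protein.cys_positions():
            n_fwd, c_fwd = extract_windows(seq, position)
            n_rev, c_rev = extract_windows(seq[::-1], length - position + 1)
            *_, g_fwd = hydropathy_block(n_fwd, c_fwd)
            *_, g_rev = hydropathy_block(n_rev, c_rev)
            if math.isnan(g_fwd):
                continue
            assert g_rev == pytest.approx(-g_fwd)
            checked += 1
        assert checked > 0

    def test_empty_window_propagates_nan(self):
        mean_n, mean_c, total, gradient = hydropathy_block("", "LLLLL")
        assert math.isnan(mean_n) and math.isnan(total) and math.isnan(gradient)
        assert mean_c == pytest.approx(3.8)


class TestPropertyBlock:
    def test_basic_vs_acidic_windows(self):
        out = property_block("KKKKK", "EEEEE")
        assert out["charge_N"] == 5
        assert out["charge_C"] == -5
        assert out["charge_gradient"] == -10
        assert out["window_basic_count"] == 5

    def test_asparagine_count(self):
        out = property_block("ANAAA", "AAANA")
        assert out["window_asn_count"] == 2

    def test_all_glycine_windows_match_table_values(self):
        out = property_block("GGGGG", "GGGGG")
        assert out["polarity_N"] == pytest.approx(0.0)
        assert out["tmtend_C"] == pytest.approx(-0.19)
        assert out["aliphatic_N"] == 0.0


class TestFeaturizeSite:
    def test_roster_is_complete_and_ordered(self, toy_protein):
        row = featurize_site(toy_protein, 75)
        assert list(row) == list(FEATURE_NAMES)
        assert len(row) == 28
        assert row["interface_distance"] == 3
        assert row["topology_kind"] == 0  # cytoplasmic
        assert row["tm_orientation"] == 0  # not inside a TM

    def test_in_tm_site_records_orientation(self, toy_protein):
        row = featurize_site(toy_protein, 60)
        assert row["topology_kind"] == 2
        assert row["tm_orientation"] == 1  # inward

    def test_registry_hash_tracks_roster(self):
        assert feature_registry_hash() == feature_registry_hash(FEATURE_NAMES)
        assert feature_registry_hash() != feature_registry_hash(
            FEATURE_NAMES[::-1]
        )


class TestFeaturizeProteome:
    def test_signal_peptide_cys_is_excluded(self):
        seq = "MC" + "L" * 18 + "CA" * 20 + "C" + "A" * 59
        protein = make_protein(
            "SIG1",
            seq,
            [
                (SegmentKind.SIGNAL, 1, 20),
                (SegmentKind.EXTRACELLULAR, 21, 60),
                (SegmentKind.TRANSMEMBRANE, 61, 80),
                (SegmentKind.CYTOPLASMIC, 81, 120),
            ],
        )
        result = featurize_proteome([protein])
        reasons = dict(
            zip(result.excluded["position"], result.excluded["reason"])
        )
        assert reasons.get(2) == "site on a signal peptide"
        assert 2 not in set(result.features["position"])

    def test_intramembrane_cys_is_excluded(self):
        protein = make_protein(
            "IM1",
            "A" * 30 + "L" * 20 + "A" * 10 + "C" + "A" * 9 + "A" * 30,
            [
                (SegmentKind.CYTOPLASMIC, 1, 30),
                (SegmentKind.TRANSMEMBRANE, 31, 50),
                (SegmentKind.EXTRACELLULAR, 51, 60),
                (SegmentKind.INTRAMEMBRANE, 61, 70),
                (SegmentKind.EXTRACELLULAR, 71, 100),
            ],
        )
        result = featurize_proteome([protein])
        assert list(result.excluded["reason"]) == [
            "site in an intramembrane segment"
        ]

    def test_protein_without_cys_yields_no_rows(self):
        protein = make_protein(
            "NOC1",
            "A" * 60,
            [
                (SegmentKind.CYTOPLASMIC, 1, 20),
                (SegmentKind.TRANSMEMBRANE, 21, 40),
                (SegmentKind.EXTRACELLULAR, 41, 60),
            ],
        )
        result = featurize_proteome([protein])
        assert result.features.empty and result.excluded.empty

    def test_nonstandard_window_residue_is_flagged_not_faked(self):
        protein = make_protein(
            "NSR1",
            "AXACA" + "A" * 15 + "L" * 20 + "A" * 20,
            [
                (SegmentKind.CYTOPLASMIC, 1, 20),
                (SegmentKind.TRANSMEMBRANE, 21, 40),
                (SegmentKind.EXTRACELLULAR, 41, 60),
            ],
        )
        result = featurize_proteome([protein])
        assert result.features.empty
        assert "non-standard" in result.excluded.iloc[0]["reason"]

    def test_featurization_is_pure(self, small_proteome):
        first = featurize_proteome(small_proteome[:30]).features
        second = featurize_proteome(small_proteome[:30]).features
        pd.testing.assert_frame_equal(first, second)

    def test_offset_sum_invariants(self, small_features):
        table = small_features.features
        assert (
            table["dist_segment_start"] + table["dist_segment_end"]
            == table["segment_length"] - 1
        ).all()
        assert (
            table["dist_N_term"] + table["dist_C_term"]
            == table["protein_length"] - 1
        ).all()
        assert table["rel_position_in_segment"].between(0, 1).all()
        assert (table["interface_distance"] >= 0).all()
        # NaN marks terminus-truncated windows; the identity holds elsewhere
        assert np.allclose(
            table["kd_gradient"],
            table["kd_mean_C"] - table["kd_mean_N"],
            equal_nan=True,
        )
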