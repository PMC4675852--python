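"""Region derivation, feature scoring, the rule cascade, proteome mining,
and the hydropathy TM predictor."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tetmine.io import SequenceRecord, TopologyRecord
from tetmine.simulate import DECOY_RULES, GeneratorSpec, make_proteome
from tetmine.topology import (
    RuleConfig,
    classify,
    derive_regions,
    mine_proteome,
    predict_tm_hydropathy,
    score_features,
)

TMS_4 = ((11, 32), (41, 62), (81, 102), (171, 192))


def seq_of(n, pid="p1"):
    return SequenceRecord(id=pid, residues="A" * n)


class TestDeriveRegions:
    def test_canonical_alternation_inside(self):
        model = derive_regions(seq_of(220), TopologyRecord("p1", 220, TMS_4, "inside"))
        assert model.regions["EC1"] == (33, 40)
        assert model.regions["ICL"] == (63, 80)
        assert model.regions["EC2"] == (103, 170)
        assert model.regions["Ctail"] == (193, 220)
        assert model.orientation_ok

    def test_outside_n_terminus_flips_loop_sides(self):
        model = derive_regions(seq_of(220), TopologyRecord("p1", 220, TMS_4, "outside"))
        assert not model.orientation_ok
        # the TM2-TM3 loop is now the (only) extracellular loop
        assert model.regions["EC1"] == (63, 80)
        assert model.regions["ICL"] == (33, 40)

    def test_three_tm_labels_withheld(self):
        model = derive_regions(
            seq_of(150), TopologyRecord("p1", 150, TMS_4[:3], "inside")
        )
        assert model.n_tm == 3
        assert "EC1" not in model.regions
        assert "loop1" in model.regions

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            derive_regions(seq_of(220, "other"), TopologyRecord("p1", 220, TMS_4, "inside"))

    @given(
        st.integers(min_value=40, max_value=200),
        st.lists(st.integers(min_value=0, max_value=30), min_size=2, max_size=8),
        st.sampled_from(["inside", "outside"]),
    )
    def test_regions_tile_protein(self, length, gaps, side):
        """Concatenated region intervals reconstruct [1, length] exactly."""
        segs = []
        pos = 1 + gaps[0] % 10
        for g in gaps[1:]:
            end = pos + 5
            if end > length - 1:
                break
            segs.append((pos, end))
            pos = end + 2 + g
        if not segs:
            return
        model = derive_regions(
            seq_of(length), TopologyRecord("p1", length, tuple(segs), side)
        )
        covered = []
        for start, end in model.regions.values():
            covered.extend(range(start, end + 1))
        assert sorted(covered) == list(range(1, length + 1))

    def test_agrees_with_per_residue_walk_oracle(self):
        """On small proteins, labels match a walker that flips sides at
        every TM boundary."""
        cases = [
            (60, ((10, 25),), "inside"),
            (60, ((10, 25), (31, 45)), "inside"),
            (60, ((5, 20), (30, 44)), "outside"),
            (55, ((1, 15),), "outside"),
        ]
        for length, segs, side in cases:
            model = derive_regions(seq_of(length), TopologyRecord("p1", length, segs, side))
            # oracle: walk residues, flipping the side across each TM
            labels = {}
            cur = side
            for pos in range(1, length + 1):
                in_tm = any(s <= pos <= e for s, e in segs)
                if in_tm:
                    labels[pos] = "TM"
                else:
                    n_before = sum(1 for s, e in segs if e < pos)
                    flipped = cur if n_before % 2 == 0 else (
                        "outside" if cur == "inside" else "inside"
                    )
                    labels[pos] = flipped
            for name, (start, end) in model.regions.items():
                for pos in range(start, end + 1):
                    if name.startswith("TM"):
                        assert labels[pos] == "TM"
                    else:
                        n_tm_before = sum(1 for s, e in segs if e < pos)
                        expect = side if n_tm_before % 2 == 0 else (
                            "outside" if side == "inside" else "inside"
                        )
                        assert labels[pos] == expect


def build_protein(ec2_body, ec1_body="QQQQQQQQQQQQQC", ntail=15, ctail=20,
                  icl=12):
    """Assemble a 4-TM protein around the given loop contents."""
    tm = "L" * 22
    residues = (
        "S" * ntail + tm + ec1_body + tm + "T" * icl + tm + ec2_body + tm + "G" * ctail
    )
    pos = 1
    segs = []
    for part_len, is_tm in [
        (ntail, False), (22, True), (len(ec1_body), False), (22, True),
        (icl, False), (22, True), (len(ec2_body), False), (22, True),
        (ctail, False),
    ]:
        if is_tm:
            segs.append((pos, pos + part_len - 1))
        pos += part_len
    seq = SequenceRecord(id="p1", residues=residues)
    topo = TopologyRecord("p1", len(residues), tuple(segs), "inside")
    return seq, topo


class TestScoreFeatures:
    def test_long_signature_reported_with_position(self):
        ec2 = "N" * 30 + "SGCCKPP" + "Q" * 50
        seq, topo = build_protein(ec2)
        report = score_features(derive_regions(seq, topo), seq)
        assert report.signature == "SGCC[KR]PP"
        ec2_start = derive_regions(seq, topo).regions["EC2"][0]
        assert report.signature_position == ec2_start + 30

    def test_core_signature_without_flanks(self):
        ec2 = "N" * 30 + "GCCRP" + "Q" * 50
        seq, topo = build_protein(ec2)
        report = score_features(derive_regions(seq, topo), seq)
        assert report.signature == "GCC[KR]P"

    def test_sequon_excludes_proline_second_position(self):
        ec2 = "NPTNAS" + "Q" * 60
        seq, topo = build_protein(ec2)
        model = derive_regions(seq, topo)
        report = score_features(model, seq)
        ec2_start = model.regions["EC2"][0]
        # only the NAS sequon counts; N-P-T is excluded
        assert report.sequons == (ec2_start + 3,)

    def test_ec_cysteine_counts(self):
        ec2 = "C" * 9 + "Q" * 60
        seq, topo = build_protein(ec2)
        report = score_features(derive_regions(seq, topo), seq)
        assert report.ec2_cys == 9
        assert report.ec1_cys == 1


class TestClassify:
    def test_planted_tetraspanin_passes_all_rules(self, small_proteome):
        topo = {t.protein_id: t for t in small_proteome.topologies}
        for seq in small_proteome.sequences:
            if not seq.id.startswith("tet"):
                continue
            report = classify(score_features(derive_regions(seq, topo[seq.id]), seq))
            assert report.verdict == "tetraspanin"
            assert report.failed_rules == ()

    def test_missing_motif_fails_signature_rule(self):
        ec2 = "C" * 9 + "Q" * 60  # cysteines but no GCC[KR]P
        seq, topo = build_protein(ec2)
        report = classify(score_features(derive_regions(seq, topo), seq))
        assert report.verdict == "rejected"
        assert report.failed_rules == ("signature",)

    def test_smaller_ec2_fails_size_rule(self):
        ec2 = "SGCCKPPCCCCCCC"  # 14 aa, still 9 cys + motif
        seq, topo = build_protein(ec2, ec1_body="Q" * 39 + "C")
        report = classify(score_features(derive_regions(seq, topo), seq))
        assert report.failed_rules == ("ec2_longer_than_ec1",)

    def test_strict_mode_requires_long_form(self):
        ec2 = "N" * 10 + "GCCKP" + "C" * 7 + "Q" * 50
        seq, topo = build_protein(ec2)
        report = score_features(derive_regions(seq, topo), seq)
        assert classify(report).verdict == "tetraspanin"
        strict = classify(report, RuleConfig(strict_signature=True))
        assert "signature" in strict.failed_rules

    def test_relaxing_thresholds_never_shrinks_candidates(self, small_proteome):
        base = RuleConfig()
        relaxed_variants = [
            RuleConfig(cys_min=7),
            RuleConfig(tail_max=120),
            RuleConfig(require_signature=False),
            RuleConfig(require_ec2_longer=False),
            RuleConfig(require_four_tm=False),
        ]
        got = set(
            mine_proteome(small_proteome.sequences, small_proteome.topologies, base).candidates
        )
        for rules in relaxed_variants:
            relaxed = set(
                mine_proteome(small_proteome.sequences, small_proteome.topologies, rules).candidates
            )
            assert got <= relaxed


class TestMineProteome:
    def test_recovers_exactly_the_planted_positives(self, small_proteome):
        result = mine_proteome(small_proteome.sequences, small_proteome.topologies)
        truth = small_proteome.truth
        planted = sorted(truth[truth.is_tetraspanin].protein_id)
        assert result.candidates == planted
        assert result.funnel["total"] == len(small_proteome.sequences)
        assert result.funnel["passed"] == len(planted)

    def test_decoy_failure_lists_name_their_planted_rule(self, small_proteome):
        result = mine_proteome(small_proteome.sequences, small_proteome.topologies)
        for _, row in small_proteome.truth.iterrows():
            if row.is_tetraspanin:
                continue
            report = result.reports[row.protein_id]
            assert report.failed_rules == (DECOY_RULES[row.kind],)

    def test_empty_proteome(self):
        result = mine_proteome([], [])
        assert result.candidates == []
        assert result.funnel == {"total": 0, "with_tm": 0, "four_tm": 0, "passed": 0}

    def test_missing_topology_excluded_at_first_stage(self, small_proteome):
        result = mine_proteome(small_proteome.sequences, [])
        assert result.funnel["with_tm"] == 0
        assert result.candidates == []

    def test_keyword_track_intersection(self, small_proteome):
        keyword = {"tet001", "tet002", "nonexistent"}
        result = mine_proteome(
            small_proteome.sequences, small_proteome.topologies, keyword_ids=keyword
        )
        assert result.keyword_intersection == ["tet001", "tet002"]


class TestHydropathyPredictor:
    def test_poly_leucine_run_detected(self):
        seq = SequenceRecord(id="p", residues="D" * 30 + "L" * 25 + "D" * 30)
        topo = predict_tm_hydropathy(seq)
        assert len(topo.tm_segments) == 1
        start, end = topo.tm_segments[0]
        assert 31 <= start and end <= 55

    def test_hydrophilic_sequence_has_no_tm(self):
        seq = SequenceRecord(id="p", residues="D" * 100)
        assert predict_tm_hydropathy(seq).tm_segments == ()

    def test_short_sequence_gives_empty_segments(self):
        seq = SequenceRecord(id="p", residues="L" * 10)
        assert predict_tm_hydropathy(seq).tm_segments == ()

    def test_planted_tetraspanin_tms_recovered_near_truth(self, small_proteome):
        topo = {t.protein_id: t for t in small_proteome.topologies}
        for seq in small_proteome.sequences:
            if not seq.id.startswith("tet"):
                continue
            pred = predict_tm_hydropathy(seq)
            true_segs = topo[seq.id].tm_segments
            assert len(pred.tm_segments) == 4
            for (ps, pe), (ts, te) in zip(pred.tm_segments, true_segs):
                assert ts <= ps <= ts + 3
                assert te - 3 <= pe <= te
            assert pred.n_terminus_side == "inside"
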