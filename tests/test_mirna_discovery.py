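"""Homology search, precursor extraction and the six hairpin criteria."""

import pytest

from mirframe.io_formats import SequenceRecord, reverse_complement
from mirframe.mirna_discovery import (
    CRITERIA_NAMES,
    build_inventory,
    evaluate_criteria,
    extract_precursor,
    family_name,
    find_mature_matches,
    occurrence_evalue,
)
from mirframe.synthetic_data import SimulationConfig, make_transcriptome

from conftest import SYNTH_FLANK


def _tx(seq, tx_id="tx1"):
    return SequenceRecord(id=tx_id, sequence=seq, kind="transcript")


def _mat(seq, name="miR-156"):
    return SequenceRecord(id=name, sequence=seq, kind="mature_mirna")


MATURE = "UGACAGAAGAGAGUGAGCACA"  # 21 nt


class TestMatureMatching:
    def test_planted_exact_copy_found_once(self):
        data = make_transcriptome(
            SimulationConfig(seed=4, n_transcripts=3,
                             planted_precursors=(("miR-9", "all_pass"),))
        )
        truth = data["truth"].iloc[0]
        hits = [
            m
            for m in find_mature_matches(data["transcripts"], data["mature"])
            if m.mismatches == 0 and m.strand == "+"
        ]
        assert len(hits) == 1
        assert hits[0].transcript_id == truth["transcript_id"]
        assert (hits[0].start, hits[0].end) == (truth["start"], truth["end"])

    def test_no_shared_kmers_gives_empty(self):
        assert (
            find_mature_matches([_tx("A" * 100)], [_mat("G" * 21)]) == []
        )

    def test_five_mismatches_rejected_at_tier_four(self):
        swap = {"A": "C", "C": "A", "G": "U", "U": "G"}
        copy = list(MATURE)
        for pos in (0, 4, 8, 12, 16):
            copy[pos] = swap[MATURE[pos]]
        copy = "".join(copy)
        mm = sum(a != b for a, b in zip(copy, MATURE))
        assert mm == 5
        hits = find_mature_matches(
            [_tx("A" * 50 + copy + "A" * 50)], [_mat(MATURE)], max_mismatches=4
        )
        assert hits == []

    def test_reverse_complement_copy_reported_on_forward_coords(self):
        seq = "A" * 30 + reverse_complement(MATURE) + "A" * 30
        hits = find_mature_matches([_tx(seq)], [_mat(MATURE)])
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (30, 51)

    def test_short_mature_is_input_error(self):
        with pytest.raises(ValueError, match="shorter than 15"):
            find_mature_matches([_tx("ACGU" * 30)], [_mat("ACGUACGUACGU")])

    def test_evalue_filter_is_monotone(self):
        tx = [_tx("A" * 200 + MATURE + "A" * 200)]
        loose = find_mature_matches(tx, [_mat(MATURE)], evalue_cutoff=1e-3)
        tight = find_mature_matches(tx, [_mat(MATURE)], evalue_cutoff=1e-9)
        assert {(m.start, m.strand) for m in tight} <= {
            (m.start, m.strand) for m in loose
        }

    def test_evalue_formula(self):
        assert occurrence_evalue(1000, 100, 21) == pytest.approx(
            1000 * 100 * 4.0**-21
        )


class TestPrecursorExtraction:
    def test_window_arithmetic(self):
        tx = _tx("A" * 400)
        match = find_mature_matches(
            [_tx("A" * 200 + MATURE + "A" * 179)], [_mat(MATURE)]
        )[0]
        cand = extract_precursor(tx, match, flank=120)
        assert (cand.window_start, cand.window_end) == (80, 341)
        assert cand.mature_offset == 120

    def test_window_clipped_at_transcript_start(self):
        seq = MATURE + "A" * 100
        match = find_mature_matches([_tx(seq)], [_mat(MATURE)])[0]
        cand = extract_precursor(_tx(seq), match, flank=120)
        assert cand.window_start == 0
        assert cand.mature_offset == match.start

    def test_planted_precursor_contained_for_default_flank(self):
        data = make_transcriptome(SimulationConfig(seed=8, n_transcripts=3))
        truth = data["truth"].iloc[0]
        tx = {t.id: t for t in data["transcripts"]}[truth["transcript_id"]]
        match = [
            m
            for m in find_mature_matches(data["transcripts"], data["mature"])
            if m.strand == "+" and m.transcript_id == truth["transcript_id"]
        ][0]
        cand = extract_precursor(tx, match, flank=SYNTH_FLANK)
        assert cand.window_start <= truth["precursor_start"]
        assert cand.window_end >= truth["precursor_end"]


class TestCriteria:
    def test_accepted_iff_all_six_flags(self, planted_candidates):
        for cand in planted_candidates:
            assert cand.accepted == all(
                cand.criteria[name] for name in CRITERIA_NAMES
            )
            assert set(cand.criteria) == set(CRITERIA_NAMES)

    def test_mfe_threshold_boundary(self, planted_candidates):
        """The same fold flips mfe_ok when the bound moves past its MFE."""
        import copy as _copy

        cand = _copy.deepcopy(next(c for c in planted_candidates if c.accepted))
        relaxed = evaluate_criteria(cand, mfe_threshold=cand.fold.mfe)
        assert relaxed.criteria["mfe_ok"]
        strict = evaluate_criteria(_copy.deepcopy(cand),
                                   mfe_threshold=cand.fold.mfe - 0.1)
        assert not strict.criteria["mfe_ok"]

    def test_rejection_reasons_match_planted_profiles(
        self, planted_sim, planted_candidates
    ):
        _, data = planted_sim
        truth = data["truth"]
        for _, row in truth[truth["kind"] == "precursor"].iterrows():
            overlapping = [
                c
                for c in planted_candidates
                if c.match.transcript_id == row["transcript_id"]
                and c.match.start < row["end"]
                and row["start"] < c.match.end
                and c.match.strand == "+"
            ]
            assert overlapping, f"plant {row['family']} not recovered"
            for cand in overlapping:
                failing = [n for n in CRITERIA_NAMES if not cand.criteria[n]]
                if row["expected_failure"]:
                    assert failing == [row["expected_failure"]]
                else:
                    assert cand.accepted


class TestInventory:
    def test_family_name_collapsing(self):
        assert family_name("ath-miR156a") == "miR-156"
        assert family_name("miR-156b") == "miR-156"
        assert family_name("miR-f11908") == "miR-f11908"

    def test_variants_collapse_to_one_family(self, planted_candidates):
        accepted = [c for c in planted_candidates if c.accepted]
        inv = build_inventory(accepted, "JH")
        # both strand copies of the all_pass plant land in one family
        assert "miR-101" in inv.family_names
        assert all(len(cands) >= 1 for cands in inv.families.values())

    def test_empty_input_empty_inventory(self):
        inv = build_inventory([], "JH")
        assert inv.family_names == set()

    def test_fixture_inventories_reproduce_published_counts(self, fixture_tables):
        from mirframe.network_analysis import inventories_from_fixtures

        jh, jv = inventories_from_fixtures(fixture_tables)
        assert len(jh.family_names) == 11
        assert len(jv.family_names) == 13
        assert len(jh.family_names & jv.family_names) == 8
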