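"""Duplex expectation scoring, thresholding and inhibition-mode calls."""

import random

import pytest

from mirframe.io_formats import SequenceRecord, reverse_complement
from mirframe.target_prediction import (
    classify_mode,
    predict_targets,
    score_duplex,
    site_flanks,
)
from _oracles import brute_force_duplex

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def perfect_site(mirna: str) -> str:
    """Transcript subsequence perfectly complementary to the miRNA."""
    return reverse_complement(mirna)


def _tx(seq, tx_id="tx1"):
    return SequenceRecord(id=tx_id, sequence=seq, kind="transcript")


class TestScoreDuplex:
    MIRNA = "UGACAGAAGAGAGUGAGCACA"  # 21 nt

    def test_perfect_complement_scores_zero(self):
        states, expectation = score_duplex(self.MIRNA, perfect_site(self.MIRNA))
        assert expectation == 0.0
        assert all(s == "match" for s in states)

    @pytest.mark.parametrize(
        "position, expected",
        [(15, 0.5), (5, 1.0)],  # G:U wobble outside vs inside the core
    )
    def test_wobble_penalty_doubles_in_core(self, position, expected):
        mirna = self.MIRNA[: position - 1] + "G" + self.MIRNA[position:]
        site = list(perfect_site(mirna))
        site[len(mirna) - position] = "U"  # face the G with a U
        _, expectation = score_duplex(mirna, "".join(site))
        assert expectation == pytest.approx(expected)

    def test_core_mismatch_costs_two(self):
        site = list(perfect_site(self.MIRNA))
        pos = 10
        bad = {"A": "C", "C": "A", "G": "G", "U": "U"}[self.MIRNA[pos - 1]]
        site[len(self.MIRNA) - pos] = bad
        states, expectation = score_duplex(self.MIRNA, "".join(site))
        assert expectation == pytest.approx(2.0)
        assert states[pos - 1] == "mismatch"

    def test_positions_beyond_upsize_unscored(self):
        site = list(perfect_site(self.MIRNA))
        site[0] = {"A": "C", "C": "A", "G": "G", "U": "U"}[self.MIRNA[20]]
        _, expectation = score_duplex(self.MIRNA, "".join(site))
        assert expectation == 0.0  # position 21 > upsize 20

    def test_short_mirna_is_input_error(self):
        with pytest.raises(ValueError, match="shorter than 15"):
            score_duplex("ACGUACGUACGU", "ACGUACGUACGU")

    def test_matches_brute_force_on_short_duplexes(self):
        """Scanner equals exhaustive alignment search (<= 1 gap)."""
        rng = random.Random(17)
        for _ in range(150):
            mirna = "".join(rng.choice("ACGU") for _ in range(15))
            site = list(perfect_site(mirna))
            for _ in range(rng.randint(0, 3)):
                site[rng.randrange(len(site))] = rng.choice("ACGU")
            if rng.random() < 0.5:
                idx = rng.randrange(len(site))
                if rng.random() < 0.5 and len(site) > 14:
                    site.pop(idx)
                else:
                    site.insert(idx, rng.choice("ACGU"))
            site = "".join(site)
            if not 14 <= len(site) <= 16:
                continue
            _, mine = score_duplex(mirna, site)
            oracle = brute_force_duplex(mirna, site[::-1])
            assert mine == pytest.approx(oracle), (mirna, site)

    def test_expectation_zero_iff_all_match(self):
        rng = random.Random(23)
        for _ in range(30):
            mirna = "".join(rng.choice("ACGU") for _ in range(18))
            states, expectation = score_duplex(mirna, perfect_site(mirna))
            assert expectation == 0.0
            site = list(perfect_site(mirna))
            pos = len(mirna) - 10  # miRNA position facing site index 10
            # replace the face with a base that cannot pair that position
            site[10] = {"A": "G", "C": "A", "G": "G", "U": "C"}[mirna[pos - 1]]
            _, damaged = score_duplex(mirna, "".join(site))
            assert damaged > 0.0


class TestClassifyMode:
    def test_central_mismatch_calls_inhibition(self):
        states = ["match"] * 21
        states[9] = "mismatch"  # position 10
        assert classify_mode(states) == "translational_inhibition"

    def test_peripheral_mismatches_call_cleavage(self):
        states = ["match"] * 21
        states[0] = states[19] = "mismatch"
        assert classify_mode(states) == "cleavage"

    def test_central_wobble_does_not_trigger_inhibition(self):
        states = ["match"] * 21
        states[9] = "wobble"
        assert classify_mode(states) == "cleavage"
        assert classify_mode(states, wobble_counts=True) == "translational_inhibition"


class TestPredictTargets:
    MIRNA = "UGACAGAAGAGAGUGAGCACA"

    def _background(self, rng, n):
        return "".join(rng.choice("ACGU") for _ in range(n))

    def test_planted_perfect_site_recovered_at_zero(self):
        rng = random.Random(31)
        seq = self._background(rng, 150) + perfect_site(self.MIRNA) + self._background(rng, 150)
        hits = predict_targets({"miR-x": self.MIRNA}, [_tx(seq)])
        exact = [h for h in hits if h.expectation == 0.0]
        assert len(exact) == 1
        assert (exact[0].site_start, exact[0].site_end) == (150, 171)
        assert exact[0].mode == "cleavage"

    def test_sites_above_threshold_excluded(self):
        # 3.5 expectation: wobble at 15 (0.5) + mismatch at 16..; build via
        # three non-core mismatches (3.0) plus a non-core wobble (0.5)
        site = list(perfect_site(self.MIRNA))
        bad = {"A": "C", "C": "A", "G": "G", "U": "U"}
        for pos in (14, 16, 17):
            site[len(self.MIRNA) - pos] = bad[self.MIRNA[pos - 1]]
        mirna = self.MIRNA[: 15 - 1] + "G" + self.MIRNA[15:]
        site[len(mirna) - 15] = "U"
        seq = "A" * 60 + "".join(site) + "A" * 60
        _, expectation = score_duplex(mirna, "".join(site))
        assert expectation == pytest.approx(3.5)
        hits = predict_targets({"miR-x": mirna}, [_tx(seq)], max_expectation=3.0)
        assert all(h.expectation <= 3.0 for h in hits)
        assert not any(h.site_start == 60 and h.expectation == 3.5 for h in hits)

    def test_top_n_truncation(self):
        # 25 planted perfect sites, top_n 20 -> 20 kept
        rng = random.Random(37)
        blocks = []
        for _ in range(25):
            blocks.append(perfect_site(self.MIRNA))
            blocks.append(self._background(rng, 30))
        hits = predict_targets(
            {"miR-x": self.MIRNA}, [_tx("".join(blocks))], top_n=20
        )
        assert len([h for h in hits if h.expectation == 0.0]) == 20

    def test_deterministic_under_input_permutation(self):
        rng = random.Random(41)
        txs = [
            _tx(self._background(rng, 80) + perfect_site(self.MIRNA)
                + self._background(rng, 80), f"tx{i}")
            for i in range(3)
        ]
        forward = predict_targets({"miR-x": self.MIRNA}, txs)
        reverse = predict_targets({"miR-x": self.MIRNA}, txs[::-1])
        key = lambda h: (h.mirna_family, h.transcript_id, h.site_start, h.expectation)
        assert [key(h) for h in forward] == [key(h) for h in reverse]


class TestSiteFlanks:
    def test_default_flanks(self):
        tx = _tx("A" * 200)
        assert len(site_flanks(tx, (100, 121))) == 21 + 17 + 13

    def test_clipped_at_transcript_start(self):
        tx = _tx("A" * 50)
        assert len(site_flanks(tx, (0, 21))) == 21 + 13

    def test_flanked_region_contains_site(self):
        tx = _tx("ACGU" * 30)
        site = (40, 61)
        region = site_flanks(tx, site)
        assert tx.sequence[site[0] : site[1]] in region
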