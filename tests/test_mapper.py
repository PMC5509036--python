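"""Anchored alignment and classification rules, certified against the
exhaustive brute-force aligner."""

import numpy as np
import pytest

from mirtail.formats import CollapsedRead, HairpinRecord, MatureAnnotation, SpikeInSet
from mirtail.mapper import (
    MapConfig,
    align_anchored,
    brute_force_oracle,
    classify_library,
    validate_calls,
)

from conftest import TOY_HAIRPIN_SEQ, TOY_MATURE_SEQ


def random_instance(rng, cfg):
    """A random (read, hairpin, mature) triple with the read start inside
    the anchor window, carrying random mutations and/or terminal additions."""
    hp_len = int(rng.integers(60, 91))
    hp = HairpinRecord("h", "".join(rng.choice(list("ACGT"), size=hp_len)))
    m_start = int(rng.integers(4, hp_len - 30))
    mature = MatureAnnotation("m", "h", m_start, m_start + 22)
    offset = int(rng.integers(-cfg.anchor_window, cfg.anchor_window + 1))
    length = int(rng.integers(18, 25))
    start = max(0, m_start + offset)
    read = list(hp.sequence[start:start + length])
    # random substitutions (0-3) and/or a random terminal addition (0-2 nt)
    for _ in range(int(rng.integers(0, 4))):
        p = int(rng.integers(0, len(read)))
        read[p] = rng.choice(list("ACGT"))
    for _ in range(int(rng.integers(0, 3))):
        read.append(rng.choice(list("ACGT")))
    return "".join(read), hp, mature


class TestWorkedExamples:
    """Hand-checked calls on a let-7-like toy hairpin."""

    hp = HairpinRecord("hp-toy", TOY_HAIRPIN_SEQ)
    mature = MatureAnnotation("mir-toy", "hp-toy", 0, 22)
    cfg = MapConfig()

    def call(self, read):
        return align_anchored(read, self.hp, self.mature, self.cfg)

    def test_exact_mature_is_templated(self):
        c = self.call(TOY_MATURE_SEQ)
        assert (c.category, c.read_length, c.offset5) == ("TEMPLATED", 22, 0)

    def test_terminal_u_addition_is_nta(self):
        # hairpin position 22 is G; a terminal T cannot be templated
        assert TOY_HAIRPIN_SEQ[22] == "G"
        c = self.call(TOY_MATURE_SEQ + "T")
        assert (c.category, c.tail_seq, c.templated_prefix_len) == ("NTA", "T", 22)

    def test_internal_mismatch(self):
        read = TOY_MATURE_SEQ[:10] + "C" + TOY_MATURE_SEQ[11:]
        assert read[10] != TOY_MATURE_SEQ[10]
        c = self.call(read)
        assert c.category == "INTERNAL_MM"
        assert c.mismatch_positions_1based == (11,)

    def test_templated_extension_beats_nta(self):
        # the 23rd nt equals the hairpin base: a templated length-23 isoform,
        # never a tail — the critical extension/tail disambiguation
        c = self.call(TOY_MATURE_SEQ + TOY_HAIRPIN_SEQ[22])
        assert (c.category, c.read_length, c.tail_seq) == ("TEMPLATED", 23, "")

    def test_di_tail_called_with_two_mismatches(self):
        c = self.call(TOY_MATURE_SEQ + "TT")
        assert (c.category, c.tail_seq) == ("NTA", "TT")

    def test_three_terminal_mismatches_exceed_budget(self):
        # max_mismatches=2 caps NTA calling; a 3-nt nontemplated run is
        # unassignable, never a tail
        c = self.call(TOY_MATURE_SEQ + "TTT")
        assert c.category == "UNASSIGNED"

    def test_overhang_past_hairpin_end_is_nontemplated(self):
        hp = HairpinRecord("h", TOY_HAIRPIN_SEQ[:24])
        mature = MatureAnnotation("m", "h", 0, 22)
        read = TOY_HAIRPIN_SEQ[:24] + "A"  # one base past the hairpin end
        c = align_anchored(read, hp, mature, self.cfg)
        assert (c.category, c.tail_seq) == ("NTA", "A")

    def test_n_never_matches(self):
        read = TOY_MATURE_SEQ[:-1] + "N"
        c = self.call(read)
        assert c.category == "NTA"  # N at the terminus is a mismatch


class TestOracleAgreement:
    def test_agreement_on_random_instances(self, map_cfg):
        rng = np.random.default_rng(42)
        for _ in range(2000):
            read, hp, mature = random_instance(rng, map_cfg)
            fast = align_anchored(read, hp, mature, map_cfg)
            slow = brute_force_oracle(read, hp, mature, map_cfg, restrict_window=True)
            assert (
                fast.category, fast.offset5, fast.tail_seq,
                fast.mismatch_positions_1based, fast.templated_prefix_len,
            ) == (
                slow.category, slow.offset5, slow.tail_seq,
                slow.mismatch_positions_1based, slow.templated_prefix_len,
            )

    def test_divergence_outside_window_documented(self, map_cfg):
        # a read placed beyond the anchor window: the unrestricted oracle
        # finds it, the anchored aligner (by design) does not
        hp = HairpinRecord("h", "A" * 10 + TOY_MATURE_SEQ + "ACCTGGAC")
        mature = MatureAnnotation("m", "h", 0, 22)
        read = TOY_MATURE_SEQ
        assert align_anchored(read, hp, mature, map_cfg).category == "UNASSIGNED"
        assert (
            brute_force_oracle(read, hp, mature, map_cfg, restrict_window=False).category
            == "TEMPLATED"
        )

    def test_monotone_in_mismatch_budget(self):
        rng = np.random.default_rng(7)
        instances = [random_instance(rng, MapConfig()) for _ in range(300)]
        previous = None
        for budget in (0, 1, 2, 3):
            cfg = MapConfig(max_mismatches=budget)
            n_assigned = sum(
                align_anchored(r, h, m, cfg).category != "UNASSIGNED"
                for r, h, m in instances
            )
            assert previous is None or n_assigned >= previous
            previous = n_assigned


class TestClassifyLibrary:
    def _reference(self):
        hp = HairpinRecord("hp-toy", TOY_HAIRPIN_SEQ)
        mature = MatureAnnotation("mir-toy", "hp-toy", 0, 22)
        return {"hp-toy": hp}, [mature]

    def test_three_category_library(self, map_cfg):
        hairpins, anns = self._reference()
        reads = [
            CollapsedRead("a", TOY_MATURE_SEQ, 5),
            CollapsedRead("b", TOY_MATURE_SEQ + "T", 3),
            CollapsedRead("c", TOY_MATURE_SEQ[:10] + "C" + TOY_MATURE_SEQ[11:], 2),
        ]
        calls = classify_library(reads, hairpins, anns, SpikeInSet(), map_cfg)
        assert {c.category for c in calls} == {"TEMPLATED", "NTA", "INTERNAL_MM"}
        validate_calls(calls, hairpins, map_cfg, {r.read_id: r.sequence for r in reads})

    def test_multimapping_flagged(self, map_cfg):
        hairpins = {
            "h1": HairpinRecord("h1", TOY_HAIRPIN_SEQ),
            "h2": HairpinRecord("h2", "CC" + TOY_HAIRPIN_SEQ),
        }
        anns = [
            MatureAnnotation("m1", "h1", 0, 22),
            MatureAnnotation("m2", "h2", 2, 24),
        ]
        calls = classify_library(
            [CollapsedRead("r", TOY_MATURE_SEQ, 1)], hairpins, anns, SpikeInSet(), map_cfg
        )
        assert len(calls) == 2
        assert all(c.multimap_n == 2 for c in calls)

    def test_spike_interception(self, map_cfg):
        hairpins, anns = self._reference()
        spikes = SpikeInSet(records=[("sp1", "ACGTACGTACGTACGTACGTAC")])
        calls = classify_library(
            [CollapsedRead("r", "ACGTACGTACGTACGTACGTAC", 7)],
            hairpins, anns, spikes, map_cfg,
        )
        assert calls[0].category == "SPIKEIN"
        assert spikes.matched_count == 7

    def test_unmatched_read_gets_single_unassigned_call(self, map_cfg):
        hairpins, anns = self._reference()
        calls = classify_library(
            [CollapsedRead("r", "G" * 22, 1)], hairpins, anns, SpikeInSet(), map_cfg
        )
        assert [c.category for c in calls] == ["UNASSIGNED"]

    def test_duplicate_mature_ids_rejected(self, map_cfg):
        hairpins, anns = self._reference()
        with pytest.raises(Exception, match="duplicate"):
            classify_library([], hairpins, anns + anns, SpikeInSet(), map_cfg)
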