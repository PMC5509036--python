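"""Aggregation: spectra, tail composition, guide cutoff, normalization, fold."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirtail.formats import MatureAnnotation, SpikeInSet
from mirtail.mapper import MapConfig, ReadCall
from mirtail.stats import (
    GuideFilter,
    heatmap_matrix,
    isoform_spectrum,
    nta_profile,
    normalize,
    pooled_nta_profile,
    select_guides,
    spectra_frame,
    terminal_internal_fold,
)


def templated(mature="m1", length=22, count=1, multimap=1):
    return ReadCall(
        f"t{mature}{length}n{count}", count, "h1", mature, "TEMPLATED",
        read_length=length, templated_prefix_len=length, multimap_n=multimap,
    )


def nta(mature="m1", length=23, tail="T", count=1):
    k = len(tail)
    return ReadCall(
        f"n{mature}{length}{tail}{count}", count, "h1", mature, "NTA",
        read_length=length, templated_prefix_len=length - k, tail_seq=tail,
        mismatch_positions_1based=tuple(range(length - k + 1, length + 1)),
    )


def internal(mature="m1", pos=10, length=22, count=1):
    return ReadCall(
        f"i{mature}{pos}{count}", count, "h1", mature, "INTERNAL_MM",
        read_length=length, mismatch_positions_1based=(pos,),
    )


class TestIsoformSpectrum:
    def test_fraction_arithmetic(self, map_cfg):
        calls = (
            [templated(length=21, count=10)]
            + [templated(length=22, count=80)]
            + [templated(length=23, count=10)]
        )
        s = isoform_spectrum(calls, "m1", map_cfg)
        assert s.fractions[21] == pytest.approx(0.1)
        assert s.fractions[22] == pytest.approx(0.8)
        assert s.fractions[23] == pytest.approx(0.1)
        assert sum(v for v in s.fractions.values() if not math.isnan(v)) == pytest.approx(1.0)

    def test_single_length(self, map_cfg):
        s = isoform_spectrum([templated(length=22, count=4)], "m1", map_cfg)
        assert s.fractions[22] == 1.0

    def test_only_templated_counted(self, map_cfg):
        calls = [templated(length=22, count=10), nta(length=23, count=50)]
        s = isoform_spectrum(calls, "m1", map_cfg)
        assert s.total == 10

    def test_out_of_range_lengths_excluded(self, map_cfg):
        s = isoform_spectrum([templated(length=30, count=5)], "m1", map_cfg)
        assert s.total == 0


class TestNtaProfile:
    def test_percentage_arithmetic(self):
        calls = (
            [nta(tail="T", count=60), nta(tail="A", count=30),
             nta(tail="C", count=5), nta(tail="G", count=5)]
        )
        prof = nta_profile(calls, "m1")
        assert prof.percentages[(23, "U")] == pytest.approx(60)
        assert prof.percentages[(23, "A")] == pytest.approx(30)
        assert prof.percentages[(23, "C")] == pytest.approx(5)
        assert prof.percentages[(23, "G")] == pytest.approx(5)
        assert sum(prof.percentages[(23, nt)] for nt in "UACG") == pytest.approx(100)

    def test_zero_calls_give_nan(self):
        prof = nta_profile([], "m1")
        assert all(math.isnan(v) for v in prof.percentages.values())

    def test_di_tails_excluded_from_mono_profile(self):
        prof = nta_profile([nta(tail="TT", length=24, count=9)], "m1")
        assert sum(prof.counts.values()) == 0

    def test_pooled_sums_counts_before_percentages(self):
        calls = [nta(mature="m1", tail="T", count=10), nta(mature="m2", tail="A", count=30)]
        pooled = pooled_nta_profile(calls, ["m1", "m2"])
        assert pooled.percentages[(23, "U")] == pytest.approx(25)
        assert pooled.percentages[(23, "A")] == pytest.approx(75)


class TestSelectGuides:
    anns = [
        MatureAnnotation("m1", "h1", 4, 26),
        MatureAnnotation("m1*", "h1", 34, 56),
    ]

    def test_larger_arm_wins(self):
        calls = [templated("m1", count=500), templated("m1*", count=30)]
        assert select_guides(calls, self.anns, GuideFilter()) == {"m1"}

    def test_cutoff_is_strict_above_50(self):
        assert select_guides([templated("m1", count=50)], self.anns, GuideFilter()) == set()
        assert select_guides([templated("m1", count=51)], self.anns, GuideFilter()) == {"m1"}

    def test_tie_broken_toward_5p_arm(self):
        calls = [templated("m1", count=100), templated("m1*", count=100)]
        assert select_guides(calls, self.anns, GuideFilter()) == {"m1"}

    def test_unmapped_hairpin_yields_no_guide(self):
        assert select_guides([], self.anns, GuideFilter()) == set()


class TestNormalize:
    def test_per_million_scaling(self):
        spikes = SpikeInSet(records=[("s", "ACGT")], matched_count=2000)
        assert normalize({"m1": 50}, spikes, 0)["m1"] == pytest.approx(25_000)

    def test_fallback_identity_at_one_million(self):
        out = normalize({"m1": 50}, SpikeInSet(), 1_000_000)
        assert out["m1"] == pytest.approx(50)

    def test_nothing_to_normalize_by(self):
        with pytest.raises(ValueError, match="nothing to normalize"):
            normalize({"m1": 1}, SpikeInSet(), 0)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from(["a", "b", "c", "d"]),
            st.integers(min_value=1, max_value=10_000),
            min_size=2,
        ),
        st.integers(min_value=1, max_value=10_000_000),
    )
    def test_scale_invariance_of_fractions(self, counts, spike_total):
        spikes = SpikeInSet(records=[("s", "ACGT")], matched_count=spike_total)
        normed = normalize(counts, spikes, 0)
        total, ntotal = sum(counts.values()), sum(normed.values())
        for k in counts:
            assert normed[k] / ntotal == pytest.approx(counts[k] / total)


class TestFold:
    def test_fold_arithmetic(self):
        calls = [nta(length=23, count=700)] + [
            internal(pos=p, count=10) for p in range(1, 23)
        ]
        rep = terminal_internal_fold(calls, "m1", focal_position=23)
        assert rep.terminal_count == 700
        assert rep.internal_mean == pytest.approx(10)
        assert rep.fold == pytest.approx(70)

    def test_zero_internal_is_nan(self):
        rep = terminal_internal_fold([nta(length=23, count=5)], "m1")
        assert math.isnan(rep.fold)

    def test_positions_without_mismatches_count_in_mean(self):
        # 1 mismatch at one of 22 internal positions -> mean 1/22
        rep = terminal_internal_fold([nta(length=23, count=22), internal(pos=5)], "m1")
        assert rep.internal_mean == pytest.approx(1 / 22)
        assert rep.fold == pytest.approx(484)

    def test_multi_mismatch_internal_calls_excluded(self):
        c = internal(pos=5)
        c.mismatch_positions_1based = (5, 9)
        rep = terminal_internal_fold([nta(length=23, count=10), c], "m1")
        assert rep.internal_mean == pytest.approx(0)
        assert math.isnan(rep.fold)


class TestHeatmapMatrix:
    def test_rows_sum_to_one_per_sample(self, map_cfg):
        spectra = [
            isoform_spectrum([templated("m1", 21, 2), templated("m1", 22, 8)], "m1", map_cfg),
            isoform_spectrum([templated("m2", 22, 5)], "m2", map_cfg),
        ]
        m = heatmap_matrix({"s1": spectra})
        assert m.shape == (2, 7)
        assert m.loc["m1"].sum() == pytest.approx(1.0)
        assert m.index[0] == "m1"  # larger total first

    def test_missing_sample_cells_are_nan(self, map_cfg):
        s1 = isoform_spectrum([templated("m1", 22, 9)], "m1", map_cfg)
        s2 = isoform_spectrum([templated("m2", 22, 5)], "m2", map_cfg)
        m = heatmap_matrix({"a": [s1], "b": [s2]})
        assert math.isnan(m.loc["m1", "b|len22"])
        assert m.loc["m1", "a|len22"] == pytest.approx(1.0)


def test_unique_only_drops_multimapped(map_cfg):
    calls = [templated("m1", 22, 10, multimap=2), templated("m1", 22, 5)]
    assert isoform_spectrum(calls, "m1", map_cfg).total == 15
    assert isoform_spectrum(calls, "m1", map_cfg, unique_only=True).total == 5
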