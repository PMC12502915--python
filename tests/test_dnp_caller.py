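"""Read grouping, indel filtering, dinucleotide counting, likelihoods
and genotype assignment."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnpcaller.dnp_caller import (
    DNPCounts,
    ReadObservation,
    assign_genotype,
    call_dnp,
    call_from_columns,
    count_dinucleotides,
    filter_reads,
    genotype_likelihoods,
    group_reads,
)
from dnpcaller.pileup_engine import DELETION, DNPSite, PileupColumn, PileupEntry

SITE = DNPSite("chr22", 100, 101, "AC", "GT")

LOG10_HALF = math.log10(0.5)


def columns(entries_by_pos):
    return [
        PileupColumn("chr22", pos, "A", entries)
        for pos, entries in sorted(entries_by_pos.items())
    ]


def obs(dinuc=None, q1=30, q2=30, indel=False, rid="r", base1=None, base2=None):
    if dinuc is not None:
        base1, base2 = dinuc[0], dinuc[1]
    return ReadObservation(
        read_id=rid, base1=base1, base2=base2, qual1=q1, qual2=q2, indel_any=indel
    )


class TestGroupReads:
    def test_full_span_read(self):
        cols = columns(
            {
                99: [PileupEntry("r1", "A", 30)],
                100: [PileupEntry("r1", "A", 30)],
                101: [PileupEntry("r1", "C", 31)],
                102: [PileupEntry("r1", "G", 30)],
            }
        )
        (ob,) = group_reads(cols, SITE)
        assert ob.covers_both
        assert (ob.base1, ob.base2, ob.qual1, ob.qual2) == ("A", "C", 30, 31)
        assert not ob.indel_any

    def test_read_covering_only_pos1_does_not_cover_both(self):
        cols = columns({100: [PileupEntry("r2", "A", 30)]})
        (ob,) = group_reads(cols, SITE)
        assert not ob.covers_both and ob.base1 == "A" and ob.base2 is None

    def test_disagreeing_overlapping_mates_drop_the_fragment(self):
        cols = columns(
            {
                100: [PileupEntry("r3", "A", 30), PileupEntry("r3", "G", 35)],
                101: [PileupEntry("r3", "C", 30)],
            }
        )
        assert group_reads(cols, SITE) == []

    def test_agreeing_overlapping_mates_merge_at_higher_quality(self):
        cols = columns(
            {
                100: [PileupEntry("r4", "A", 20), PileupEntry("r4", "A", 35)],
                101: [PileupEntry("r4", "C", 30)],
            }
        )
        (ob,) = group_reads(cols, SITE)
        assert ob.covers_both and ob.qual1 == 35

    def test_indel_flag_on_any_window_position_marks_the_read(self):
        cols = columns(
            {
                99: [PileupEntry("r5", "T", 30, indel_after=True)],
                100: [PileupEntry("r5", "A", 30)],
                101: [PileupEntry("r5", "C", 30)],
            }
        )
        (ob,) = group_reads(cols, SITE)
        assert ob.indel_any and ob.covers_both

    def test_deletion_at_dnp_position_leaves_base_unset(self):
        cols = columns(
            {
                100: [PileupEntry("r6", DELETION, 0, is_deletion=True)],
                101: [PileupEntry("r6", "C", 30)],
            }
        )
        (ob,) = group_reads(cols, SITE)
        assert not ob.covers_both and ob.indel_any

    def test_empty_input_gives_empty_output(self):
        assert group_reads(columns({100: [], 101: []}), SITE) == []


class TestFilterReads:
    def test_indel_read_discarded_and_counted(self):
        retained, n_disc, total = filter_reads(
            [obs("AC"), obs("AC", indel=True), obs(base1="A")]
        )
        assert [o.dinucleotide for o in retained] == ["AC"]
        assert n_disc == 1
        assert total == 2  # the pos1-only read is silently dropped

    def test_clean_full_span_read_retained(self):
        retained, n_disc, total = filter_reads([obs("GT")])
        assert len(retained) == 1 and n_disc == 0 and total == 1

    def test_flank_only_indel_still_discards(self):
        # indel seen on the upstream flank, bases fine at both DNP positions
        retained, n_disc, total = filter_reads([obs("AC", indel=True)])
        assert retained == [] and n_disc == 1 and total == 1


class TestCountDinucleotides:
    def test_mixed_tally(self):
        reads = [obs("AC")] * 3 + [obs("GT")] * 2 + [obs("AT")]
        counts = count_dinucleotides(reads, SITE)
        assert (counts.n_ref, counts.n_alt, counts.n_other) == (3, 2, 1)
        assert counts.combined == {"AC": 3, "GT": 2, "AT": 1}

    def test_all_reference(self):
        counts = count_dinucleotides([obs("AC")] * 8, SITE)
        assert (counts.n_ref, counts.n_alt, counts.n_other) == (8, 0, 0)

    def test_trans_adjacent_snps_all_land_in_other(self):
        # ref AA, alt GG in trans: reads carry GA and AG, never ref or alt
        site = DNPSite("chr22", 100, 101, "AA", "GG")
        reads = [obs("GA")] * 5 + [obs("AG")] * 5
        counts = count_dinucleotides(reads, site)
        assert (counts.n_ref, counts.n_alt, counts.n_other) == (0, 0, 10)

    def test_n_containing_dinucleotide_is_other(self):
        counts = count_dinucleotides([obs("AN")], SITE)
        assert counts.n_other == 1 and counts.combined == {"AN": 1}

    @given(
        n_ref=st.integers(0, 30),
        n_alt=st.integers(0, 30),
        n_other=st.integers(0, 30),
        n_indel=st.integers(0, 10),
    )
    @settings(derandomize=True, max_examples=100)
    def test_conservation_identities(self, n_ref, n_alt, n_other, n_indel):
        observations = (
            [obs("AC", rid=f"a{i}") for i in range(n_ref)]
            + [obs("GT", rid=f"b{i}") for i in range(n_alt)]
            + [obs("CC", rid=f"c{i}") for i in range(n_other)]
            + [obs("AC", rid=f"d{i}", indel=True) for i in range(n_indel)]
        )
        retained, n_disc, total = filter_reads(observations)
        counts = count_dinucleotides(retained, SITE, n_disc, total)
        assert counts.n_ref + counts.n_alt + counts.n_other == len(retained)
        assert sum(counts.combined.values()) == len(retained)
        assert len(retained) + counts.reads_discarded_for_indels == counts.total_considered
        assert 0.0 <= counts.ratio_discarded <= 1.0


class TestGenotypeLikelihoods:
    def test_single_reference_read_at_phred30(self):
        gl0, gl1, gl2 = genotype_likelihoods([obs("AC")], SITE)
        assert gl0 == pytest.approx(math.log10(0.999), abs=1e-12)
        assert gl1 == pytest.approx(math.log10(0.5), abs=1e-12)
        assert gl2 == pytest.approx(-3.0, abs=1e-12)

    def test_mean_quality_is_arithmetic_on_phred_scale(self):
        # q1=20, q2=40 -> mean 30 -> same as a q30/q30 read
        a = genotype_likelihoods([obs("AC", q1=20, q2=40)], SITE)
        b = genotype_likelihoods([obs("AC", q1=30, q2=30)], SITE)
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_informative_reads_gives_zero_triplet(self):
        assert genotype_likelihoods([], SITE) == (0.0, 0.0, 0.0)
        assert genotype_likelihoods([obs("CC")], SITE) == (0.0, 0.0, 0.0)

    @given(
        n_ref=st.integers(0, 20),
        n_alt=st.integers(0, 20),
        quals=st.lists(st.integers(2, 41), min_size=1, max_size=10),
    )
    @settings(derandomize=True, max_examples=100)
    def test_het_likelihood_closed_form(self, n_ref, n_alt, quals):
        """gl1 = m * log10(1/2) regardless of mix or qualities."""
        reads = [
            obs("AC", q1=quals[i % len(quals)], q2=quals[(i + 1) % len(quals)], rid=f"a{i}")
            for i in range(n_ref)
        ] + [
            obs("GT", q1=quals[i % len(quals)], q2=quals[(i + 1) % len(quals)], rid=f"b{i}")
            for i in range(n_alt)
        ]
        _, gl1, _ = genotype_likelihoods(reads, SITE)
        assert gl1 == pytest.approx((n_ref + n_alt) * LOG10_HALF, abs=1e-9)

    @given(st.lists(st.sampled_from(["AC", "GT"]), min_size=0, max_size=20))
    @settings(derandomize=True, max_examples=50)
    def test_appending_a_ref_read_increases_gl0_minus_gl2(self, dinucs):
        reads = [obs(d, rid=f"r{i}") for i, d in enumerate(dinucs)]
        gl0, _, gl2 = genotype_likelihoods(reads, SITE)
        gl0b, _, gl2b = genotype_likelihoods(reads + [obs("AC", rid="extra")], SITE)
        assert (gl0b - gl2b) > (gl0 - gl2)


class TestAssignGenotype:
    def test_other_ratio_just_above_threshold_blocks_the_call(self):
        counts = DNPCounts(n_ref=5, n_alt=4, n_other=1)
        call = assign_genotype(counts, (-1.0, -2.0, -9.0))
        assert call.gt == "NA" and call.na_reason == "other_ratio_exceeded"
        assert call.other_ratio == pytest.approx(1 / 9)

    def test_other_ratio_exactly_at_threshold_allows_the_call(self):
        reads = [obs("AC", rid=f"r{i}") for i in range(10)]
        counts = count_dinucleotides(reads + [obs("CC", rid="x")], SITE)
        gls = genotype_likelihoods(reads, SITE)
        call = assign_genotype(counts, gls)
        assert call.other_ratio == pytest.approx(0.1)
        assert call.gt == "0/0"

    def test_no_informative_reads_is_na(self):
        counts = DNPCounts(n_ref=0, n_alt=0, n_other=7)
        assert assign_genotype(counts, (0.0, 0.0, 0.0)).gt == "NA"

    def test_likelihood_tie_refuses_to_guess(self):
        counts = DNPCounts(n_ref=1, n_alt=1, n_other=0)
        call = assign_genotype(counts, (-1.0, -1.0, -5.0))
        assert call.gt == "NA" and call.na_reason == "likelihood_tie"

    @pytest.mark.parametrize(
        "n_ref, n_alt, expected",
        [(10, 0, "0/0"), (5, 5, "0/1"), (0, 10, "1/1")],
    )
    def test_argmax_maps_to_genotype(self, n_ref, n_alt, expected):
        reads = [obs("AC", rid=f"a{i}") for i in range(n_ref)] + [
            obs("GT", rid=f"b{i}") for i in range(n_alt)
        ]
        counts = count_dinucleotides(reads, SITE)
        call = assign_genotype(counts, genotype_likelihoods(reads, SITE))
        assert call.gt == expected


class TestCallDnp:
    def test_het_dnp_fixture_called_heterozygous(self, world, make_bam):
        bam, _, dnp = make_bam("het_dnp", coverage=20, base_error_rate=0.0)
        rec = call_dnp(bam, world["reference"], dnp)
        assert rec.call.gt == "0/1"
        assert rec.counts.n_other == 0

    def test_trans_adjacent_snps_refused_via_other_reads(self, world, make_bam):
        bam, _, dnp = make_bam("adjacent_snp_trans", coverage=20, base_error_rate=0.0)
        rec = call_dnp(bam, world["reference"], dnp)
        assert rec.call.gt == "NA"
        assert rec.counts.n_ref == 0 and rec.counts.n_alt == 0
        assert rec.counts.n_other == 20

    def test_hom_ref_with_planted_indels_counts_discards(self, world, make_bam):
        bam, truth, dnp = make_bam(
            "indel_contaminated", coverage=25, base_error_rate=0.0, indel_rate=0.4, seed=9
        )
        rec = call_dnp(bam, world["reference"], dnp)
        assert rec.call.gt == "0/0"
        assert rec.counts.reads_discarded_for_indels == len(truth.planted_indel_reads)
        assert rec.counts.total_considered == 25

    def test_zero_coverage_site_is_na_with_zero_counts(self, world, make_bam):
        bam, _, _ = make_bam("hom_ref", site_index=0, coverage=5)
        other = world["sites"][4]
        rec = call_dnp(bam, world["reference"], other)
        assert rec.call.gt == "NA"
        assert rec.counts.n_retained == 0
        assert (rec.call.gl0, rec.call.gl1, rec.call.gl2) == (0.0, 0.0, 0.0)

    def test_call_from_columns_is_deterministic(self, world, make_bam):
        from dnpcaller.pileup_engine import pileup_window

        bam, _, dnp = make_bam("het_dnp", coverage=15, base_error_rate=0.01, seed=2)
        cols = pileup_window(bam, world["reference"], dnp)
        a = call_from_columns(cols, dnp)
        b = call_from_columns(cols, dnp)
        assert a == b
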