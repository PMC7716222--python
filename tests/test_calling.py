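import numpy as np
import pytest

from mitohap.calling import (
    AlignedRead,
    CallParams,
    PileupColumn,
    build_pileup,
    call_column,
    call_profile,
    numt_screen,
    quality_mask,
    read_pileup_tsv,
    read_sam,
    trim_reads,
    write_pileup_tsv,
)
from mitohap.nomenclature import format_variant
from mitohap.simulate import (
    SimConfig,
    NumtConfig,
    simulate_pileup,
    simulate_population,
    simulate_reads,
    write_sam,
)

PARAMS = CallParams()


def make_read(start=100, length=60, strand="+", paired=False, quals=None, bases=None):
    bases = bases or "A" * length
    quals = tuple(quals) if quals is not None else tuple([40] * len(bases))
    return AlignedRead(
        read_id="r", start=start, strand=strand, bases=bases,
        qualities=quals, paired=paired,
    )


class TestTrimming:
    def test_single_end_length_60_keeps_40(self):
        out = trim_reads([make_read(length=60)], PARAMS)
        assert len(out) == 1 and len(out[0]) == 40
        assert out[0].start == 120  # 20 trimmed off the 5' (left) end

    def test_single_end_length_59_dropped(self):
        assert trim_reads([make_read(length=59)], PARAMS) == []

    def test_paired_150_becomes_110(self):
        out = trim_reads([make_read(length=150, paired=True)], PARAMS)
        assert len(out[0]) == 110

    def test_reverse_strand_trims_high_coordinates(self):
        out = trim_reads([make_read(length=60, strand="-")], PARAMS)
        # the 5' end of a reverse read is its highest reference position
        assert out[0].start == 100 and len(out[0]) == 40


class TestQualityMask:
    def test_all_high_quality_untouched(self):
        r = make_read(length=50)
        assert quality_mask(r, PARAMS).bases == r.bases

    def test_low_quality_base_masks_neighborhood(self):
        quals = [40] * 50
        quals[25] = 10
        out = quality_mask(make_read(length=50, quals=quals), PARAMS)
        masked = [i for i, b in enumerate(out.bases) if b == "N"]
        assert masked == list(range(20, 31))  # the base and 5 on each side

    def test_quality_exactly_30_not_masked(self):
        out = quality_mask(make_read(length=50, quals=[30] * 50), PARAMS)
        assert "N" not in out.bases


class TestBuildPileup:
    def test_two_reads_give_depth_two(self, reference):
        reads = [make_read(start=100, length=51), make_read(start=100, length=51)]
        pile = build_pileup(reads, reference)
        assert pile.depth[99:150].tolist() == [2] * 51
        assert pile.depth[98] == 0 and pile.depth[150] == 0

    def test_circular_wrap(self, reference):
        read = make_read(start=16560, length=20)
        pile = build_pileup([read], reference)
        assert pile.depth[16559] == 1 and pile.depth[0] == 1 and pile.depth[9] == 1

    def test_empty_read_list(self, reference):
        assert build_pileup([], reference).depth.sum() == 0

    def test_overlong_read_rejected(self, reference):
        with pytest.raises(ValueError):
            build_pileup([make_read(length=2 * 16569 + 1)], reference)


def column(pos, ref_base, alleles):
    """alleles: dict base -> (fwd, rev)."""
    counts = np.zeros((5, 2), dtype=np.int64)
    order = "ACGT-"
    for b, (f, r) in alleles.items():
        counts[order.index(b)] = (f, r)
    return PileupColumn(position=pos, counts=counts)


class TestCallColumn:
    def test_php_at_five_percent(self):
        col = column(16093, "C", {"C": (475, 475), "T": (25, 25)})
        call = call_column(col, "C", PARAMS)
        assert call.status == "php"
        assert call.variant.call == "Y"
        assert call.variant.major_base == "C"
        assert call.variant.major_frequency == pytest.approx(0.95)

    def test_depth_99_is_no_call(self):
        col = column(100, "C", {"C": (50, 49)})
        assert call_column(col, "C", PARAMS).status == "no_call"

    def test_below_threshold_minor_is_reference(self):
        col = column(100, "C", {"C": (476, 475), "T": (25, 24)})
        assert call_column(col, "C", PARAMS).status == "reference"

    def test_strand_imbalanced_minor_discarded(self):
        # 50 A all on one strand fail the 1% opposite-strand rule; the
        # remaining fixed G call is a substitution against ref A
        col = column(100, "A", {"G": (475, 475), "A": (50, 0)})
        call = call_column(col, "A", PARAMS)
        assert call.status == "variant"
        assert format_variant(call.variant) == "A100G"

    def test_more_than_two_alleles_is_mixture_suspect(self):
        col = column(100, "A", {"A": (400, 400), "G": (60, 60), "T": (40, 40)})
        call = call_column(col, "A", PARAMS)
        assert call.status == "mixture_suspect" and call.variant is None

    def test_equal_counts_tie_keeps_both_major_by_base_order(self):
        col = column(100, "A", {"C": (250, 250), "G": (250, 250)})
        call = call_column(col, "A", PARAMS)
        assert call.status == "php"
        assert call.variant.call == "S" and call.variant.major_base == "C"

    def test_deletion_allele_competes(self):
        col = column(100, "A", {"-": (500, 500)})
        call = call_column(col, "A", PARAMS)
        assert call.variant.kind == "deletion"


class TestCallProfile:
    def test_noiseless_recovery(self, reference):
        cfg = SimConfig(seed=42, n_individuals=20, base_error_rate=0.0,
                        php_individual_rate=0.0, length_het_region_rates=(),
                        depth_mean=500)
        _, truth = simulate_population(cfg, reference)
        rng = np.random.default_rng(1)
        for sample in truth.samples[:5]:
            pile = simulate_pileup(sample, reference, cfg, rng)
            profile, _ = call_profile(pile, reference, sample_id="x")
            assert {format_variant(v) for v in profile.variants} == {
                format_variant(v) for v in sample.profile.variants
            }

    def test_php_recovered_at_ten_percent(self, reference):
        cfg = SimConfig(seed=7, n_individuals=1, base_error_rate=0.0,
                        php_individual_rate=0.0, length_het_region_rates=(),
                        depth_mean=1000)
        _, truth = simulate_population(cfg, reference)
        sample = truth.samples[0]
        ref = reference.base(16093)
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        import dataclasses
        sample = dataclasses.replace(sample, phps=((16093, ref, alt, 0.10),))
        pile = simulate_pileup(sample, reference, cfg, np.random.default_rng(2))
        profile, _ = call_profile(pile, reference)
        hit = [v for v in profile.variants if v.position == 16093]
        assert hit and hit[0].is_php

    def test_coverage_gap_excluded_from_range(self, reference):
        cfg = SimConfig(seed=9, n_individuals=1, base_error_rate=0.0,
                        php_individual_rate=0.0, length_het_region_rates=(),
                        depth_mean=400)
        _, truth = simulate_population(cfg, reference)
        pile = simulate_pileup(truth.samples[0], reference, cfg,
                               np.random.default_rng(3))
        pile.counts[7999:8100] = 0  # nps 8000-8100
        profile, metrics = call_profile(pile, reference)
        assert not any(a <= 8050 <= b for a, b in profile.range)
        assert 3107 not in [p for iv in profile.range for p in iv]

    def test_metrics_ordering(self, reference):
        cfg = SimConfig(seed=13, n_individuals=1, depth_mean=600,
                        length_het_region_rates=())
        _, truth = simulate_population(cfg, reference)
        pile = simulate_pileup(truth.samples[0], reference, cfg,
                               np.random.default_rng(4))
        _, metrics = call_profile(pile, reference)
        assert (
            metrics.average_major_base_frequency_excl_het
            >= metrics.average_major_base_frequency
        )

    def test_zero_coverage_errors(self, reference):
        from mitohap.calling import Pileup

        with pytest.raises(ValueError):
            call_profile(Pileup(reference), reference)


class TestNumtScreen:
    @pytest.fixture()
    def numt_setup(self, reference):
        cfg = SimConfig(seed=17, n_individuals=1, base_error_rate=0.002,
                        php_individual_rate=0.0, length_het_region_rates=(),
                        depth_mean=1000, numt=NumtConfig(fraction=0.03, n_diff_sites=4))
        _, truth = simulate_population(cfg, reference)
        sample = truth.samples[0]
        pile = simulate_pileup(sample, reference, cfg, np.random.default_rng(5))
        return cfg, sample, pile

    def test_spike_in_screened_but_not_in_profile(self, reference, numt_setup):
        _, sample, pile = numt_setup
        profile, _ = call_profile(pile, reference)
        hits = numt_screen(pile, reference)
        hit_positions = {h.position for h in hits}
        truth_positions = {p for p, _, _ in sample.numt_sites}
        assert truth_positions & hit_positions
        assert all(h.in_numt_interval for h in hits if h.position in truth_positions)
        assert not truth_positions & {v.position for v in profile.variants}

    def test_clean_simulation_screens_empty(self, reference):
        cfg = SimConfig(seed=19, n_individuals=1, base_error_rate=0.0,
                        php_individual_rate=0.0, length_het_region_rates=(),
                        depth_mean=800)
        _, truth = simulate_population(cfg, reference)
        pile = simulate_pileup(truth.samples[0], reference, cfg,
                               np.random.default_rng(6))
        assert numt_screen(pile, reference) == []

    def test_six_percent_allele_is_php_not_screened(self, reference):
        cfg = SimConfig(seed=23, n_individuals=1, base_error_rate=0.0,
                        php_individual_rate=0.0, length_het_region_rates=(),
                        depth_mean=1000)
        _, truth = simulate_population(cfg, reference)
        import dataclasses
        ref = reference.base(7000)
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        sample = dataclasses.replace(truth.samples[0], phps=((7000, ref, alt, 0.06),))
        pile = simulate_pileup(sample, reference, cfg, np.random.default_rng(8))
        profile, _ = call_profile(pile, reference)
        assert any(v.position == 7000 and v.is_php for v in profile.variants)
        assert 7000 not in {h.position for h in numt_screen(pile, reference)}


class TestIO:
    def test_pileup_tsv_round_trip(self, reference, tmp_path):
        cfg = SimConfig(seed=29, n_individuals=1, depth_mean=200,
                        length_het_region_rates=())
        _, truth = simulate_population(cfg, reference)
        pile = simulate_pileup(truth.samples[0], reference, cfg,
                               np.random.default_rng(9))
        path = tmp_path / "pileup.tsv"
        write_pileup_tsv(pile, path)
        back = read_pileup_tsv(path, reference)
        assert np.array_equal(back.counts, pile.counts)

    def test_sam_round_trip_preserves_calls(self, reference, tmp_path):
        cfg = SimConfig(seed=31, n_individuals=1, base_error_rate=0.0,
                        php_individual_rate=0.0, length_het_region_rates=(),
                        depth_mean=300, read_length=120)
        _, truth = simulate_population(cfg, reference)
        reads = simulate_reads(truth.samples[0], reference, cfg,
                               np.random.default_rng(10), interval=(500, 2500))
        path = tmp_path / "reads.sam"
        write_sam(reads, reference, path)
        back = read_sam(path, reference)
        pile_a = build_pileup(reads, reference)
        pile_b = build_pileup(back, reference)
        assert np.array_equal(pile_a.counts, pile_b.counts)
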