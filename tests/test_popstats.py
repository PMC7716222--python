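import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitohap.nomenclature import MitoProfile, parse_variant, php_variant
from mitohap.popstats import (
    ComparisonOptions,
    HaplotypeCounts,
    PopulationDataset,
    ancestry_proportions,
    assign_ancestry,
    empirical_rmp,
    haplotype_diversity,
    haplotype_key,
    k2p_distance,
    k2p_matrix,
    observed_rmp,
    pairwise_phist,
    pcoa,
    php_characterize,
    round_half_up,
    summary_statistics,
    tabulate,
    SaturationError,
)
from mitohap.simulate import SimConfig, simulate_population

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def sub(reference, pos):
    ref = reference.base(pos)
    return parse_variant(f"{ref}{pos}{TRANSITION[ref]}")


class TestHaplotypeKey:
    def test_ignored_insertion_does_not_differentiate(self, reference):
        a = MitoProfile(sample_id="a", variants=(sub(reference, 263),
                                                 parse_variant("315.1C")))
        b = MitoProfile(sample_id="b", variants=(sub(reference, 263),))
        assert haplotype_key(a) == haplotype_key(b)

    def test_php_mode_controls_merging(self, reference):
        ref = reference.base(16093)
        php = php_variant(16093, ref, (ref, TRANSITION[ref]))
        a = MitoProfile(sample_id="a", variants=(sub(reference, 263), php))
        b = MitoProfile(sample_id="b", variants=(sub(reference, 263),))
        assert haplotype_key(a, ComparisonOptions(php_mode="ignored")) == \
            haplotype_key(b, ComparisonOptions(php_mode="ignored"))
        assert haplotype_key(a) != haplotype_key(b)

    def test_non_ignored_insertion_differentiates(self, reference):
        a = MitoProfile(sample_id="a", variants=(sub(reference, 263),
                                                 parse_variant("291.1A")))
        b = MitoProfile(sample_id="b", variants=(sub(reference, 263),))
        assert haplotype_key(a) != haplotype_key(b)

    def test_control_region_range_drops_cds_variants(self, reference):
        a = MitoProfile(sample_id="a", variants=(sub(reference, 263),
                                                 sub(reference, 7028)))
        b = MitoProfile(sample_id="b", variants=(sub(reference, 263),))
        opts = ComparisonOptions(range="control_region")
        assert haplotype_key(a, opts) == haplotype_key(b, opts)


partitions = st.lists(st.integers(1, 12), min_size=2, max_size=40)


class TestRmpAndDiversity:
    @pytest.mark.parametrize(
        "groups,expected",
        [
            ([1] * 112, (0.89, 0.00, 1.0)),
            ([2, 2] + [1] * 108, (0.92, 0.03, 0.9997)),
            ([2] * 4 + [1] * 163, (0.61, 0.03, 0.9997)),
            ([4, 2, 2, 2, 2] + [1] * 97, (1.09, 0.17, 0.9983)),
        ],
    )
    def test_reported_compositions(self, groups, expected):
        s = summary_statistics(HaplotypeCounts(n=sum(groups), groups=tuple(groups)))
        assert (s["observed_rmp_pct"], s["empirical_rmp_pct"],
                s["haplotype_diversity"]) == expected

    def test_degenerate_cases(self):
        allsame = HaplotypeCounts(n=7, groups=(7,))
        assert observed_rmp(allsame) == 1.0
        assert empirical_rmp(allsame) == 1.0
        assert haplotype_diversity(allsame) == 0.0

    @given(partitions)
    @settings(max_examples=300, deadline=None)
    def test_identities_exact(self, groups):
        counts = HaplotypeCounts(n=sum(groups), groups=tuple(groups))
        n = counts.n
        obs = observed_rmp(counts, exact=True)
        emp = empirical_rmp(counts, exact=True)
        div = haplotype_diversity(counts, exact=True)
        assert emp == (n * obs - 1) / Fraction(n - 1)
        assert div == Fraction(n, n - 1) * (1 - obs)
        assert emp <= obs
        assert obs >= Fraction(1, n)
        assert (obs == Fraction(1, n)) == (counts.unique == counts.distinct == n)

    def test_small_n_guard(self):
        counts = HaplotypeCounts(n=1, groups=(1,))
        with pytest.raises(ValueError):
            empirical_rmp(counts)

    def test_round_half_up_display(self):
        assert round_half_up(0.005, 2) == 0.01
        assert round_half_up(0.8928571, 2) == 0.89


class TestTabulate:
    def test_all_distinct(self, reference):
        profiles = [MitoProfile(sample_id=f"s{i}", variants=(sub(reference, 1000 + i),))
                    for i in range(10)]
        counts = tabulate(profiles)
        assert (counts.n, counts.distinct, counts.unique) == (10, 10, 10)

    def test_pairs(self, reference):
        v1, v2 = sub(reference, 1000), sub(reference, 2000)
        profiles = [MitoProfile(sample_id=f"s{i}", variants=(v,))
                    for i, v in enumerate([v1, v1, v2, v2])]
        assert tabulate(profiles).groups == (2, 2)

    def test_identical_triplet(self, reference):
        v = sub(reference, 1500)
        profiles = [MitoProfile(sample_id=f"s{i}", variants=(v,)) for i in range(3)]
        assert tabulate(profiles).groups == (3,)


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGT" * 25, "ACGT" * 25) == 0.0

    def test_pure_transition_closed_form(self):
        a = "A" * 100
        b = "G" + "A" * 99
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.98), abs=1e-10)

    def test_mixed_closed_form(self):
        # P = 0.1, Q = 0.05 over 100 sites
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        expected = -0.5 * math.log(0.75 * math.sqrt(0.9))
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_first_order_agreement_at_low_divergence(self):
        a = "A" * 10000
        b = "G" * 6 + "C" * 4 + "A" * 9990  # P + Q = 0.001
        assert k2p_distance(a, b) == pytest.approx(0.001, abs=1e-4)

    def test_ambiguous_sites_skipped(self):
        assert k2p_distance("ANCG", "AYCG") == 0.0

    def test_saturation_errors(self):
        with pytest.raises(SaturationError):
            k2p_distance("A" * 10, "G" * 10)

    def test_matrix_matches_scalar(self, reference):
        cfg = SimConfig(seed=301, n_individuals=4, php_individual_rate=0.0,
                        length_het_region_rates=())
        profiles, _ = simulate_population(cfg, reference)
        from mitohap.popstats import substitution_sequence

        D = k2p_matrix(profiles, reference)
        s0 = substitution_sequence(profiles[0], reference)
        s1 = substitution_sequence(profiles[1], reference)
        assert D[0, 1] == pytest.approx(k2p_distance(s0, s1), abs=1e-12)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)


class TestPhiST:
    @pytest.fixture()
    def pool(self, reference):
        cfg = SimConfig(seed=303, n_individuals=12, php_individual_rate=0.0,
                        length_het_region_rates=())
        profiles, _ = simulate_population(cfg, reference)
        return profiles

    def test_identical_populations_show_no_differentiation(self, reference, pool):
        a = PopulationDataset("a", tuple(pool[:6]))
        b = PopulationDataset(
            "b",
            tuple(MitoProfile(sample_id=p.sample_id + "x", variants=p.variants)
                  for p in pool[:6]),
        )
        res = pairwise_phist(a, b, reference, n_permutations=200, seed=1)
        assert res.phi_st <= 1e-9
        assert res.p_value > 0.05

    def test_fixed_disjoint_populations_phist_one(self, reference):
        va, vb = sub(reference, 1000), sub(reference, 2000)
        a = PopulationDataset("a", tuple(
            MitoProfile(sample_id=f"a{i}", variants=(va,)) for i in range(4)))
        b = PopulationDataset("b", tuple(
            MitoProfile(sample_id=f"b{i}", variants=(vb,)) for i in range(4)))
        res = pairwise_phist(a, b, reference, n_permutations=100, seed=2)
        assert res.phi_st == pytest.approx(1.0)

    def test_symmetry_and_seed_reproducibility(self, reference, pool):
        a = PopulationDataset("a", tuple(pool[:6]))
        b = PopulationDataset("b", tuple(pool[6:]))
        r1 = pairwise_phist(a, b, reference, n_permutations=300, seed=9)
        r2 = pairwise_phist(b, a, reference, n_permutations=300, seed=9)
        assert r1.phi_st == pytest.approx(r2.phi_st, abs=1e-12)
        r3 = pairwise_phist(a, b, reference, n_permutations=300, seed=9)
        assert r1.p_value == r3.p_value

    def test_too_small_population_rejected(self, reference, pool):
        a = PopulationDataset("a", tuple(pool[:1]))
        b = PopulationDataset("b", tuple(pool[1:4]))
        with pytest.raises(ValueError):
            pairwise_phist(a, b, reference)


class TestPCoA:
    def test_collinear_points_single_axis(self):
        D = np.array([[0.0, 1, 3], [1, 0, 2], [3, 2, 0]])
        res = pcoa(D)
        assert res.explained[0] == pytest.approx(1.0)

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(9, 3))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(D)
        got = np.sqrt(((res.coordinates[:, None, :] -
                        res.coordinates[None, :, :]) ** 2).sum(-1))
        assert np.abs(got - D).max() < 1e-9

    def test_identical_points_all_zero(self):
        res = pcoa(np.zeros((4, 4)))
        assert res.coordinates.shape[1] == 0
        assert np.allclose(res.eigenvalues, 0.0)

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 1], [2, 0]])
        with pytest.raises(ValueError):
            pcoa(D)

    def test_explained_fractions_non_increasing(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(8, 4))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(D)
        assert np.all(np.diff(res.explained) <= 1e-12)

    def test_against_independent_implementation(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ours = pcoa(D)
        theirs = skbio_ord.pcoa(D)
        assert np.allclose(
            np.sort(ours.eigenvalues)[::-1][:2],
            np.sort(np.asarray(theirs.eigvals))[::-1][:2],
            atol=1e-9,
        )


class TestPhpCharacterize:
    def test_classification(self, reference):
        v1 = php_variant(16192, reference.base(16192),
                         ("C", "T"), major_base="C", major_frequency=0.9)
        v2 = php_variant(16265, reference.base(16265), ("A", "C"),
                         major_base="A", major_frequency=0.93)
        v3 = php_variant(7028, reference.base(7028), ("A", "G"),
                         major_base="A", major_frequency=0.8)
        profiles = [
            MitoProfile(sample_id="a", variants=(v1, v2)),
            MitoProfile(sample_id="b", variants=(v3,)),
            MitoProfile(sample_id="c"),
        ]
        summary = php_characterize(profiles)
        by_pos = {r.position: r for r in summary.records}
        assert by_pos[16192].is_transition and by_pos[16192].region == "CR"
        assert not by_pos[16265].is_transition
        assert by_pos[7028].region == "CDS" and by_pos[7028].transition_class == "R"
        assert summary.individuals_with_php == 2
        assert summary.php_count_histogram == {2: 1, 1: 1, 0: 1}

    def test_folded_vf(self, reference):
        ref = reference.base(5000)
        alt = TRANSITION[ref]
        dominant_variant = php_variant(5000, ref, (ref, alt), major_base=alt,
                                       major_frequency=0.93)
        summary = php_characterize(
            [MitoProfile(sample_id="a", variants=(dominant_variant,))]
        )
        assert summary.records[0].folded_vf == pytest.approx(0.07)


class TestAncestry:
    @pytest.mark.parametrize(
        "haplogroup,continent",
        [
            ("L2a1", "African"),
            ("B2", "Native American"),
            ("B4", "Asian"),
            ("H1", "European"),
            ("HV0", "European"),
            ("A2w", "Native American"),
            ("Q99", "unassigned"),
        ],
    )
    def test_longest_prefix_assignment(self, haplogroup, continent):
        assert assign_ancestry(haplogroup) == continent

    def test_proportions(self, reference):
        profiles = [
            MitoProfile(sample_id="a", haplogroup="H1"),
            MitoProfile(sample_id="b", haplogroup="L2a1"),
            MitoProfile(sample_id="c", haplogroup="B2"),
            MitoProfile(sample_id="d", haplogroup="B2"),
        ]
        continents, haplogroups = ancestry_proportions(profiles)
        assert continents == {
            "African": 0.25, "European": 0.25, "Native American": 0.5
        }
        assert haplogroups["B2"] == 0.5
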