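"""Meiosis, population structure, segregation filtering and trial simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from biparpred import simulate as sim
from biparpred._rng import child_rng
from biparpred.simulate import SimulationError


def _two_marker_map(chrom, distance_cm):
    return sim.GeneticMap(
        chromosome=np.array(chrom),
        marker_id=("m1", "m2"),
        position_cm=np.array([0.0, distance_cm]) if chrom[0] == chrom[1]
        else np.array([0.0, 0.0]),
    )


def _recombinant_fraction(gmap, n_gametes, seed=0):
    hap = np.array([[0, 0], [1, 1]], dtype=np.int8)
    rng = np.random.default_rng(seed)
    gametes = np.array([sim.simulate_gamete(hap, gmap, rng) for _ in range(n_gametes)])
    return np.mean(gametes[:, 0] != gametes[:, 1])


class TestGameteHaldane:
    def test_zero_distance_never_recombines(self):
        gmap = _two_marker_map([1, 1], 0.0)
        assert _recombinant_fraction(gmap, 500) == 0.0

    def test_different_chromosomes_assort_independently(self):
        gmap = _two_marker_map([1, 2], 0.0)
        frac = _recombinant_fraction(gmap, 20000)
        se = np.sqrt(0.25 / 20000)
        assert abs(frac - 0.5) < 3 * se

    def test_fifty_cm_matches_haldane_closed_form(self):
        # r = (1 - e^{-2*50/100}) / 2 = (1 - e^{-1}) / 2
        expected = (1 - np.exp(-1)) / 2
        gmap = _two_marker_map([1, 1], 50.0)
        frac = _recombinant_fraction(gmap, 10000)
        se = np.sqrt(expected * (1 - expected) / 10000)
        assert abs(frac - expected) < 3 * se

    def test_map_genotype_mismatch_raises(self, small_map):
        with pytest.raises(SimulationError):
            sim.simulate_gamete(np.zeros((2, 3)), small_map, np.random.default_rng(0))


class TestPopulation:
    def test_monomorphic_cross_raises(self, small_map):
        n = small_map.n_markers
        ped = sim.FounderPair("A", "B", np.ones(n, np.int8), np.ones(n, np.int8))
        with pytest.raises(SimulationError):
            sim.simulate_population(ped, "F2", 10, small_map, np.random.default_rng(0))

    def test_too_few_families_raises(self, small_map):
        n = small_map.n_markers
        ped = sim.FounderPair("A", "B", np.zeros(n, np.int8), np.ones(n, np.int8))
        with pytest.raises(SimulationError):
            sim.simulate_population(ped, "F2", 1, small_map, np.random.default_rng(0))

    def test_f2_unlinked_marker_fits_1_2_1(self):
        gmap = sim.GeneticMap(np.array([1]), ("m1",), np.array([0.0]))
        ped = sim.FounderPair("A", "B", np.array([0], np.int8), np.array([1], np.int8))
        pop = sim.simulate_population(ped, "F2", 10000, gmap, np.random.default_rng(5))
        col = pop.genotypes[:, 0]
        counts = [(col == c).sum() for c in (1, 0, -1)]
        stat, p = stats.chisquare(counts, f_exp=[2500, 5000, 2500])
        assert p > 0.01

    def test_bc1_codes_and_ratio(self, small_map):
        n = small_map.n_markers
        ped = sim.FounderPair("A", "B", np.zeros(n, np.int8), np.ones(n, np.int8))
        pop = sim.simulate_population(ped, "BC1", 2000, small_map, np.random.default_rng(6))
        assert set(np.unique(pop.genotypes)) <= {0, 1}
        frac_hom = (pop.genotypes == 1).mean()
        assert abs(frac_hom - 0.5) < 0.02

    def test_codes_within_alphabet_and_allele_freq_half(self, f2_population):
        g = f2_population.genotypes
        assert set(np.unique(g)) <= {-1, 0, 1}
        # parent-A allele frequency per marker ~ 0.5 overall
        freq_a = (g.mean() / 2) + 0.5
        assert abs(freq_a - 0.5) < 0.05

    def test_study_sizing_matches_metadata_by_construction(self):
        pop = sim.simulate_study_population(1, n_families=165, n_snps=201, master_seed=0)
        assert pop.n_families == 165
        assert pop.n_markers == 201
        assert 126 <= pop.n_families <= 278 and 162 <= pop.n_markers <= 283

    def test_seed_contract_bit_identical(self, small_map):
        n = small_map.n_markers
        ped = sim.FounderPair("A", "B", np.zeros(n, np.int8), np.ones(n, np.int8))
        pops = [
            sim.simulate_population(ped, "F2", 30, small_map, child_rng(42, "pop"), "P")
            for _ in range(2)
        ]
        np.testing.assert_array_equal(pops[0].genotypes, pops[1].genotypes)


def _population_with_counts(counts_by_marker):
    """Hand-built F2 population whose marker columns have given class counts."""
    cols = []
    for c_plus, c_zero, c_minus in counts_by_marker:
        cols.append([1] * c_plus + [0] * c_zero + [-1] * c_minus)
    geno = np.array(cols).T
    n_fam, n_mark = geno.shape
    gmap = sim.GeneticMap(
        np.arange(1, n_mark + 1), tuple(f"m{j}" for j in range(n_mark)),
        np.zeros(n_mark),
    )
    ped = sim.FounderPair(
        "A", "B", np.zeros(n_mark, np.int8), np.ones(n_mark, np.int8)
    )
    return sim.BiparentalPopulation(
        population_id="hand", pedigree=ped, generation="F2", genotypes=geno,
        polymorphic_marker_ids=tuple(f"m{j}" for j in range(n_mark)),
        genetic_map=gmap,
    )


class TestSegregationFilter:
    def test_exact_fit_retained(self):
        pop = _population_with_counts([(25, 50, 25)])
        assert sim.segregation_filter(pop, alpha=0.05).n_markers == 1

    def test_total_distortion_dropped_unless_alpha_zero(self):
        pop = _population_with_counts([(100, 0, 0), (25, 50, 25)])
        filtered = sim.segregation_filter(pop, alpha=0.05)
        assert filtered.polymorphic_marker_ids == ("m1",)
        both = sim.segregation_filter(pop, alpha=0.0)
        assert both.n_markers == 2

    def test_hand_chisquare_statistic_two(self):
        # counts (30, 50, 20) vs 1:2:1 -> chi2 = 25/25 + 0 + 25/25 = 2.0,
        # p = exp(-1) ~ 0.3679 on 2 df
        pop = _population_with_counts([(30, 50, 20)])
        p_hand = float(stats.chi2.sf(2.0, df=2))
        assert sim.segregation_filter(pop, alpha=p_hand - 1e-9).n_markers == 1
        with pytest.raises(SimulationError):
            sim.segregation_filter(pop, alpha=p_hand + 1e-9)

    def test_all_markers_dropped_raises(self):
        pop = _population_with_counts([(100, 0, 0)])
        with pytest.raises(SimulationError):
            sim.segregation_filter(pop, alpha=0.05)


class TestCalibrateVariances:
    def test_noiseless_target(self):
        assert sim.calibrate_variances(1.0, 4, 2) == (0.0, 0.0)

    def test_hand_inversion(self):
        # h2 = 0.5, e = r = 2, sg2 = 1, no GxE: 1/(1 + se2/4) = 0.5 -> se2 = 4
        sge2, se2 = sim.calibrate_variances(0.5, 2, 2, sigma_g2=1.0, ge_to_e_ratio=0.0)
        assert sge2 == 0.0
        assert se2 == pytest.approx(4.0)

    def test_invalid_target_raises(self):
        for bad in (0.0, -0.1, 1.2):
            with pytest.raises(ValueError):
                sim.calibrate_variances(bad, 4, 2)

    @given(
        h2=st.floats(0.01, 1.0),
        e=st.integers(1, 8),
        r=st.integers(1, 4),
        sg2=st.floats(0.1, 10.0),
        rho=st.floats(0.0, 3.0),
    )
    def test_round_trip_reproduces_target(self, h2, e, r, sg2, rho):
        sge2, se2 = sim.calibrate_variances(h2, e, r, sg2, rho)
        realized = sg2 / (sg2 + sge2 / e + se2 / (e * r))
        assert realized == pytest.approx(h2, abs=1e-10)


class TestSimulateTrials:
    def test_noise_free_records_equal_genetic_value(self, f2_population):
        rng = np.random.default_rng(0)
        arch = sim.random_trait_architecture(
            f2_population, "PH_WW", 1.0, rng, n_qtl=10, e=2, r=2, mu=100.0
        )
        trials = sim.simulate_trials(f2_population, arch, rng)
        g = sim.genetic_values(f2_population, arch)
        by_fam = trials.groupby("family_id", sort=False)["value"]
        assert by_fam.nunique().eq(1).all()
        np.testing.assert_allclose(
            by_fam.first().loc[list(f2_population.family_ids)].to_numpy(),
            100.0 + g,
        )

    def test_realized_genetic_variance_exact(self, f2_population):
        rng = np.random.default_rng(1)
        arch = sim.random_trait_architecture(
            f2_population, "GY_WW", 0.4, rng, sigma_g2=2.5
        )
        g = sim.genetic_values(f2_population, arch)
        assert g.var(ddof=1) == pytest.approx(2.5, rel=1e-12)

    def test_balanced_design_complete(self, balanced_trials):
        trials, arch = balanced_trials
        counts = trials.groupby(["family_id", "environment_id", "replicate_id"]).size()
        assert (counts == 1).all()
        assert len(counts) == 60 * arch.n_environments * arch.n_replicates

    def test_zero_genetic_variance_family_mean_variance(self, f2_population):
        # var of family means -> sge2/e + se2/(e r) when sg2 = 0
        e, r = 4, 2
        arch = sim.TraitArchitecture(
            trait_env="GY_WW", qtl_marker_ids=(), additive_effects=np.array([]),
            sigma_g2=0.0, sigma_ge2=1.0, sigma_e2=2.0, n_environments=e, n_replicates=r,
        )
        vars_ = []
        for s in range(40):
            trials = sim.simulate_trials(f2_population, arch, np.random.default_rng(s))
            vars_.append(trials.groupby("family_id")["value"].mean().var(ddof=1))
        expected = 1.0 / e + 2.0 / (e * r)
        assert np.mean(vars_) == pytest.approx(expected, rel=0.1)


class TestHalfsibSet:
    def test_full_sib_configuration_rejected(self, small_map):
        with pytest.raises(SimulationError):
            sim.simulate_halfsib_set(
                "S", ("A", "A"), (20, 20), small_map, np.random.default_rng(0)
            )

    def test_common_markers_in_study_range(self):
        gmap = sim.default_map(markers_per_chromosome=45)
        counts = []
        for s in range(5):
            _, _, common = sim.simulate_halfsib_set(
                "S", ("A", "B"), (50, 50), gmap, np.random.default_rng(s)
            )
            counts.append(len(common))
        assert all(44 <= c <= 100 for c in counts)

    def test_common_set_is_joint_polymorphism_of_panels(self, small_map):
        pop1, pop2, common = sim.simulate_halfsib_set(
            "S", ("A", "B"), (20, 20), small_map, np.random.default_rng(3),
            panel_size=10_000,  # no panel thinning: common = joint polymorphism
        )
        joint = set(pop1.polymorphic_marker_ids) & set(pop2.polymorphic_marker_ids)
        assert set(common) == joint
        # +1 codes the shared parent's allele in both populations
        assert pop1.pedigree.parent_a_id == pop2.pedigree.parent_a_id == "S"
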