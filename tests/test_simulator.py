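"""Unit tests for the life-cycle simulator phases and whole runs."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from myxolife.simulator import (
    ConfigurationError,
    ExtinctionError,
    SimConfig,
    TraitPopulation,
    assign_interactions,
    bottleneck_phase,
    classify_strategies,
    germination_phase,
    growth_phase,
    init_population,
    relative_metrics,
    resolve_cc,
    resolve_ce,
    resolve_ee,
    run_simulation,
    sporulation_phase,
    sweep,
)


def small_config(**kw):
    base = dict(n_max=1000, n_cycles=3, readout_cycles=(3,), seed=7)
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("beta", 0.0),
            ("beta", 1.5),
            ("gamma", -0.1),
            ("epsilon", 1.2),
            ("n_sharing", 0.5),
            ("n_max", 1),
            ("coop_threshold", 0.0),
            ("mutation_halfwidth", -0.01),
            ("germination_mode", "telepathic"),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            small_config(**{field: value})

    def test_defaults_valid(self):
        SimConfig().validate()


class TestInitPopulation:
    def test_population_size_matches_capacity(self, rng):
        pop = init_population(small_config(n_max=12345), rng)
        assert len(pop) == 12345

    def test_zero_sd_collapses_to_mean(self, rng):
        pop = init_population(small_config(init_sd=0.0, init_mean=0.37), rng)
        assert np.all(pop.s == 0.37)
        assert np.all(pop.g == 0.37)

    def test_matches_truncated_normal(self, rng):
        """Sample mean and KS distance agree with the truncated normal."""
        cfg = small_config(n_max=100_000)
        pop = init_population(cfg, rng)
        a = (0 - cfg.init_mean) / cfg.init_sd
        b = (1 - cfg.init_mean) / cfg.init_sd
        dist = stats.truncnorm(a, b, loc=cfg.init_mean, scale=cfg.init_sd)
        assert abs(pop.s.mean() - dist.mean()) < 0.01
        ks = stats.kstest(pop.s, dist.cdf)
        # 1% critical value of the KS statistic ~ 1.63 / sqrt(n)
        assert ks.statistic < 1.63 / np.sqrt(len(pop))

    def test_bounds(self, rng):
        pop = init_population(small_config(n_max=50_000), rng)
        assert pop.in_bounds()


class TestClassify:
    def test_threshold_is_inclusive(self):
        pop = TraitPopulation(np.array([0.5]), np.array([0.5]))
        split = classify_strategies(pop, 0.5)
        assert split.cooperators.tolist() == [0]
        assert split.p_c == 1.0

    def test_all_cooperators(self):
        pop = TraitPopulation(np.ones(10), np.ones(10))
        split = classify_strategies(pop, 0.5)
        assert split.p_c == 1.0 and split.p_e == 0.0

    def test_direct_count(self):
        pop = TraitPopulation(
            np.array([0.1, 0.49, 0.5, 0.9]), np.full(4, 0.5)
        )
        split = classify_strategies(pop, 0.5)
        assert split.p_c == 0.5
        assert split.p_c + split.p_e == 1.0

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            classify_strategies(TraitPopulation.empty())


class TestAssignInteractions:
    def test_no_exploiters_means_all_cc(self, rng):
        pop = TraitPopulation(np.full(100, 0.8), np.full(100, 0.5))
        split = classify_strategies(pop)
        a = assign_interactions(pop, split, rng)
        assert len(a.cc_pairs) == 50
        assert len(a.ce_pairs) == 0 and len(a.ee_pairs) == 0

    def test_odd_population_leaves_one_unpaired(self, rng):
        pop = TraitPopulation(
            np.array([0.8, 0.8, 0.8, 0.2, 0.2]), np.full(5, 0.5)
        )
        split = classify_strategies(pop)
        a = assign_interactions(pop, split, rng)
        n_pairs = len(a.cc_pairs) + len(a.ce_pairs) + len(a.ee_pairs)
        assert n_pairs == 2
        assert len(a.unpaired) == 1

    def test_each_cell_in_at_most_one_pair(self, rng):
        pop = TraitPopulation(rng.random(1001), rng.random(1001))
        split = classify_strategies(pop)
        a = assign_interactions(pop, split, rng)
        used = np.concatenate(
            [a.cc_pairs.ravel(), a.ce_pairs.ravel(), a.ee_pairs.ravel(),
             a.unpaired]
        )
        assert len(used) == len(pop)
        assert len(np.unique(used)) == len(pop)
        # C-E pairs really are one cooperator plus one exploiter
        if len(a.ce_pairs):
            assert np.all(pop.s[a.ce_pairs[:, 0]] >= 0.5)
            assert np.all(pop.s[a.ce_pairs[:, 1]] < 0.5)

    def test_ce_fraction_matches_random_pairing(self, rng_factory):
        """At p_c = p_e = 0.5 the C-E pair fraction is ~0.5."""
        n = 100_000
        fractions = []
        for seed in range(100):
            rng = rng_factory(seed)
            s = np.where(rng.random(n) < 0.5, 0.8, 0.2)
            pop = TraitPopulation(s, np.full(n, 0.5))
            split = classify_strategies(pop)
            a = assign_interactions(pop, split, rng)
            fractions.append(len(a.ce_pairs) / (n // 2))
        se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert abs(np.mean(fractions) - 0.5) < 3 * max(se, 1e-4)


class TestResolveCC:
    def test_full_ability_no_cost(self, rng):
        pop = TraitPopulation(np.array([1.0, 1.0]), np.array([0.5, 0.5]))
        kept, K = resolve_cc(pop, np.array([0, 1]), 1.0, rng)
        assert K == pytest.approx(1.0)
        assert sorted(kept.tolist()) == [0, 1]

    def test_payoff_hand_arithmetic(self, rng):
        pop = TraitPopulation(np.array([0.8, 0.6]), np.array([0.5, 0.5]))
        _, K = resolve_cc(pop, np.array([0, 1]), 0.65, rng)
        assert K == pytest.approx(0.455)

    def test_total_cost_yields_no_spores(self, rng):
        pop = TraitPopulation(np.array([0.9, 0.7]), np.array([0.5, 0.5]))
        kept, K = resolve_cc(pop, np.array([0, 1]), 0.0, rng)
        assert K == 0.0 and len(kept) == 0

    def test_non_cooperator_rejected(self, rng):
        pop = TraitPopulation(np.array([0.3]), np.array([0.5]))
        with pytest.raises(ValueError, match="consistency"):
            resolve_cc(pop, np.array([0]), 1.0, rng)


class TestResolveCE:
    def test_transfer_hand_arithmetic(self):
        pop = TraitPopulation(
            np.array([0.8, 0.6, 0.4, 0.2]), np.full(4, 0.5)
        )
        out = resolve_ce(pop, np.array([0, 1]), np.array([2, 3]), 50.0)
        assert out.D == pytest.approx(0.4)
        assert out.s_expl == pytest.approx([0.408, 0.208])
        assert out.s_coop == pytest.approx([0.792, 0.592])
        assert out.expl_retained.sum() == 0
        assert out.coop_retained.sum() == 2
        assert out.L == pytest.approx(1.384)
        assert out.M == 0.0

    def test_total_expropriation_at_n_one(self):
        """n = 1: exploiters take everything the cooperators produced."""
        pop = TraitPopulation(
            np.array([0.8, 0.6, 0.4, 0.2]), np.full(4, 0.5)
        )
        out = resolve_ce(pop, np.array([0, 1]), np.array([2, 3]), 1.0)
        assert out.s_expl == pytest.approx([0.8, 0.6])
        assert out.expl_retained.all()
        assert not out.coop_retained.any()
        assert out.M == pytest.approx(1.4)
        assert out.L == 0.0

    def test_large_n_sharing_no_transfer(self):
        pop = TraitPopulation(
            np.array([0.9, 0.1]), np.full(2, 0.5)
        )
        out = resolve_ce(pop, np.array([0]), np.array([1]), 1e12)
        assert out.s_coop == pytest.approx([0.9], abs=1e-9)
        assert out.M == 0.0
        assert out.coop_retained.all()

    def test_ability_conserved_without_clipping(self):
        pop = TraitPopulation(
            np.array([0.8, 0.6, 0.4, 0.2]), np.full(4, 0.5)
        )
        out = resolve_ce(pop, np.array([0, 1]), np.array([2, 3]), 5.0)
        before = pop.s.sum()
        after = out.s_coop.sum() + out.s_expl.sum()
        assert not out.clipped
        assert after == pytest.approx(before)

    def test_one_sided_ce_set_rejected(self):
        pop = TraitPopulation(np.array([0.8]), np.array([0.5]))
        with pytest.raises(ValueError, match="consistency"):
            resolve_ce(pop, np.array([0]), np.array([], dtype=int), 50.0)


class TestResolveEE:
    def test_never_any_spores(self):
        for pairs in (np.empty((0, 2), int), np.arange(2000).reshape(-1, 2)):
            kept, N = resolve_ee(pairs)
            assert len(kept) == 0 and N == 0.0


class TestSporulationPhase:
    def test_cycle_one_full_ability_sporulates_everyone(self, rng):
        pop = TraitPopulation(np.ones(500), np.full(500, 0.5))
        spores, summary = sporulation_phase(pop, small_config(), 1, rng)
        assert len(spores) == 500
        assert summary.m == summary.p == summary.q == 0

    def test_expected_spore_count_all_cooperators(self, rng_factory):
        """p_e = 0, gamma = 1: expected spores = sum of paired abilities."""
        counts, expected = [], []
        for seed in range(40):
            rng = rng_factory(seed)
            s = rng.uniform(0.5, 1.0, 2000)
            pop = TraitPopulation(s, np.full(2000, 0.5))
            cfg = small_config(gamma=1.0)
            spores, _ = sporulation_phase(pop, cfg, 2, rng)
            counts.append(len(spores))
            expected.append(s.sum())  # all cells are paired (even N)
        diff = np.mean(counts) - np.mean(expected)
        se = np.std(np.array(counts) - np.array(expected), ddof=1)
        se /= np.sqrt(len(counts))
        assert abs(diff) < 3 * se + 1e-9

    def test_empty_population_signals_extinction(self, rng):
        with pytest.raises(ExtinctionError):
            sporulation_phase(TraitPopulation.empty(), small_config(), 2, rng)

    def test_summary_proportions_sum_to_one(self, rng):
        pop = TraitPopulation(rng.random(1000), rng.random(1000))
        _, summary = sporulation_phase(pop, small_config(), 2, rng)
        assert summary.p_c + summary.p_e == pytest.approx(1.0)
        assert summary.N == 0.0


class TestGerminationPhase:
    def test_zero_epsilon_retains_nothing(self, rng):
        spores = TraitPopulation(np.full(100, 0.7), np.full(100, 0.9))
        out = germination_phase(spores, 0.0, "communal", rng)
        assert len(out) == 0

    def test_full_epsilon_full_ability_retains_all(self, rng):
        spores = TraitPopulation(np.full(100, 0.7), np.ones(100))
        out = germination_phase(spores, 1.0, "communal", rng)
        assert len(out) == 100

    def test_communal_rate_matches_binomial(self, rng_factory):
        """epsilon=0.8, mean g=0.5: germinated fraction ~0.40."""
        n = 100_000
        fracs = []
        for seed in range(100):
            rng = rng_factory(seed)
            spores = TraitPopulation(np.full(n, 0.7), np.full(n, 0.5))
            fracs.append(
                len(germination_phase(spores, 0.8, "communal", rng)) / n
            )
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.40) < 3 * se

    def test_mixed_mode_weights_individual_ability(self, rng):
        # epsilon=0 in mixed mode reduces to pure individual ability
        spores = TraitPopulation(
            np.full(2, 0.7), np.array([1.0, 0.0])
        )
        out = germination_phase(spores, 0.0, "mixed", rng)
        assert np.all(out.g == 1.0)

    def test_empty_pool_signals_extinction(self, rng):
        with pytest.raises(ExtinctionError):
            germination_phase(TraitPopulation.empty(), 0.5, "communal", rng)


class TestBottleneckPhase:
    def test_identity_at_beta_one(self, rng):
        pop = TraitPopulation(rng.random(100), rng.random(100))
        out = bottleneck_phase(pop, 1.0, rng)
        assert sorted(out.s.tolist()) == sorted(pop.s.tolist())

    def test_exact_count(self, rng):
        pop = TraitPopulation(rng.random(10_000), rng.random(10_000))
        assert len(bottleneck_phase(pop, 0.01, rng)) == 100

    def test_floor_of_one_survivor(self, rng):
        pop = TraitPopulation(rng.random(10), rng.random(10))
        assert len(bottleneck_phase(pop, 0.001, rng)) == 1

    def test_trait_blind_sampling_is_unbiased(self, rng_factory):
        source = np.random.default_rng(0).random(2000)
        pop = TraitPopulation(source, source.copy())
        means = []
        for seed in range(200):
            out = bottleneck_phase(pop, 0.15, rng_factory(seed))
            means.append(out.s.mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - source.mean()) < 3 * se


class TestGrowthPhase:
    def test_without_mutation_daughters_copy_parents(self, rng):
        values = np.array([0.11, 0.52, 0.93])
        pop = TraitPopulation(values, values[::-1].copy())
        cfg = small_config(n_max=48, mutation_prob=0.0)
        out = growth_phase(pop, cfg, rng)
        assert len(out) == 48
        assert set(np.round(out.s, 12)) <= set(np.round(values, 12))

    def test_reaches_carrying_capacity_exactly(self, rng):
        pop = TraitPopulation(np.full(100, 0.5), np.full(100, 0.5))
        out = growth_phase(pop, SimConfig(n_max=1_000_000, seed=0), rng)
        assert len(out) == 1_000_000

    def test_lethal_mutations_keep_bounds(self, rng):
        # cells at the boundary: any outward step is lethal, so all
        # survivors stay inside [0, 1]
        pop = TraitPopulation(np.full(64, 0.05), np.full(64, 0.95))
        cfg = small_config(n_max=4096, mutation_halfwidth=0.2)
        out = growth_phase(pop, cfg, rng)
        assert out.in_bounds()

    def test_empty_input_signals_extinction(self, rng):
        with pytest.raises(ExtinctionError):
            growth_phase(TraitPopulation.empty(), small_config(), rng)


class TestRelativeMetrics:
    def test_equal_rates_give_zero(self):
        m = relative_metrics((0.3, 0.2), (0.3, 0.2))
        assert m.rel_spore_productivity == 0.0
        assert m.rel_germination_efficiency == 0.0

    def test_log10_identities(self):
        m = relative_metrics((1.0, 0.05), (0.1, 0.1))
        assert m.rel_spore_productivity == pytest.approx(1.0)
        assert m.rel_germination_efficiency == pytest.approx(
            np.log10(0.5), abs=1e-12
        )

    def test_zero_rate_floored_and_flagged(self):
        m = relative_metrics((0.0, 0.1), (0.5, 0.1))
        assert m.spore_floored and not m.germ_floored
        assert np.isfinite(m.rel_spore_productivity)

    def test_nonpositive_ancestral_rejected(self):
        with pytest.raises(ValueError):
            relative_metrics((0.5, 0.5), (0.0, 0.5))


class TestRunSimulation:
    def test_zero_cycles_is_self_comparison(self):
        res = run_simulation(small_config(n_cycles=0))
        assert res.metrics[0].rel_spore_productivity == 0.0
        assert res.metrics[0].rel_germination_efficiency == 0.0

    def test_fixed_seed_is_bit_identical(self):
        cfg = small_config(n_max=2000, n_cycles=4, readout_cycles=(4,),
                           seed=42)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert a.metrics[4] == b.metrics[4]
        assert a.pc_series == b.pc_series
        assert np.array_equal(a.final_population.s, b.final_population.s)
        assert np.array_equal(a.final_population.g, b.final_population.g)
        assert a.trajectory_frame().equals(b.trajectory_frame())

    def test_trait_bounds_hold_every_cycle(self):
        res = run_simulation(small_config(n_max=2000, n_cycles=5,
                                          readout_cycles=(5,), seed=3))
        assert res.final_population.in_bounds()
        for rec in res.records:
            assert 0 <= rec.spor_rate <= 1
            assert 0 <= rec.germ_rate <= 1
            assert rec.n_spores <= rec.n_start
            assert rec.n_after_bottleneck <= rec.n_germinated

    def test_extinction_is_flagged_not_raised(self):
        # epsilon 0 kills every spore in cycle 1
        res = run_simulation(small_config(epsilon_first_cycle=0.0))
        assert res.extinct and res.extinct_cycle == 1


class TestSweep:
    def test_single_point_matches_single_run(self):
        cfg = small_config(n_max=1000, n_cycles=2, readout_cycles=(2,),
                           seed=5)
        sw = sweep(cfg, [0.9], [0.7], replicates=1)
        seed = sw.seeds[(0.9, 0.7, 0)]
        solo = run_simulation(
            dataclasses.replace(cfg, gamma=0.9, epsilon=0.7, seed=seed)
        )
        row = sw.table.iloc[0]
        assert row["rel_spore_productivity"] == pytest.approx(
            solo.metrics[2].rel_spore_productivity
        )

    def test_grid_shape_and_determinism(self):
        cfg = small_config(n_max=500, n_cycles=2, readout_cycles=(2,),
                           seed=9)
        sw1 = sweep(cfg, [0.7, 0.9], [0.5, 0.8], replicates=2)
        sw2 = sweep(cfg, [0.7, 0.9], [0.5, 0.8], replicates=2)
        assert len(sw1.table) == 8
        assert sw1.table.equals(sw2.table)
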