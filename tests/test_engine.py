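"""Generation loop: initialization, stepping, determinism, replicates."""

import math

import numpy as np
import pytest

from armevo.combat import make_male
from armevo.config import SimParams, derive_replicate_seed
from armevo.engine import (
    Female,
    Population,
    init_population,
    run_replicates,
    run_simulation,
    step_generation,
)


def monomorphic_population(params, g0, rng):
    """Population in which every individual carries genotype g0 exactly."""
    pop = Population(males=[], females=[])
    for _ in range(params.n_males):
        body = rng.uniform(params.body_min, params.body_max)
        pop.males.append(
            make_male(pop.next_id, body, g0, params.allometric_slope,
                      params.initial_condition)
        )
        pop.next_id += 1
    for _ in range(params.n_females):
        pop.females.append(Female(id=pop.next_id, genotype=g0))
        pop.next_id += 1
    return pop


class TestInitPopulation:
    def test_counts_bodies_conditions(self, rng):
        params = SimParams()
        pop = init_population(params, rng)
        assert len(pop.males) == 100 and len(pop.females) == 100
        for m in pop.males:
            assert 150.0 <= m.body <= 250.0
            assert m.condition == 100.0
            assert 0.0 <= m.genotype < 0.01
            assert m.armament == pytest.approx(m.body**1.35 * m.genotype)
        for f in pop.females:
            assert 0.0 <= f.genotype < 0.01

    def test_founder_mean_ratio_near_half_scale(self):
        # mean of U(0, 0.01) is 0.005; average over many founders
        genotypes = []
        for seed in range(20):
            pop = init_population(SimParams(), np.random.default_rng(seed))
            genotypes.extend(m.genotype for m in pop.males)
        genotypes = np.array(genotypes)
        se = 0.01 / math.sqrt(12 * genotypes.size)
        assert abs(genotypes.mean() - 0.005) < 3 * se


class TestStepGeneration:
    def test_no_deaths_means_no_fights(self, rng):
        params = SimParams(natural_death_rate=0.0)
        pop = init_population(params, rng)
        before = [(m.id, m.genotype, m.condition) for m in pop.males]
        _, stats = step_generation(pop, params, rng)
        after = [(m.id, m.genotype, m.condition) for m in pop.males]
        assert before == after
        assert stats.n_fights == 0 and stats.n_default_wins == 0
        assert stats.n_deaths_natural == 0

    def test_pool_sizes_conserved_over_many_generations(self, rng):
        params = SimParams()
        pop = init_population(params, rng)
        for _ in range(300):
            _, _ = step_generation(pop, params, rng)
            assert len(pop.males) == params.n_males
            assert len(pop.females) == params.n_females
            assert all(f.alive for f in pop.females)

    def test_neutral_control_keeps_ratio_exactly_constant(self, rng):
        # dyadic genotype so per-generation means incur no rounding at all
        g0 = 0.0078125
        params = SimParams(mutation_prob=0.0)
        pop = monomorphic_population(params, g0, rng)
        for _ in range(300):
            _, stats = step_generation(pop, params, rng)
            assert stats.mean_ratio == g0

    def test_death_counts_are_consistent(self, rng):
        params = SimParams()
        pop = init_population(params, rng)
        for _ in range(50):
            _, s = step_generation(pop, params, rng)
            for count in (s.n_deaths_natural, s.n_deaths_armament,
                          s.n_deaths_combat, s.n_fights, s.n_default_wins):
                assert count >= 0
            # each slot emptied by the sweep is refilled by one offspring
            total_dead = s.n_deaths_natural + s.n_deaths_armament + s.n_deaths_combat
            assert s.n_fights + s.n_default_wins == total_dead


class TestRunSimulation:
    def test_fixed_seed_reproduces_trajectory_exactly(self):
        params = SimParams(n_generations=200)
        t1 = run_simulation(params, 77)
        t2 = run_simulation(params, 77)
        assert t1.stats == t2.stats
        assert not t1.collapsed

    def test_single_generation_boundary(self):
        t = run_simulation(SimParams(n_generations=1), 3)
        assert len(t.stats) == 1 and t.stats[0].generation == 1

    def test_total_natural_death_collapses_gracefully(self):
        t = run_simulation(SimParams(n_generations=50, natural_death_rate=1.0), 5)
        assert t.collapsed
        assert len(t.stats) < 50

    def test_genotypes_never_negative_under_heavy_mutation(self, rng):
        params = SimParams(mutation_prob=0.5, mutation_delta=1.5, n_generations=100)
        t = run_simulation(params, 11)
        assert all(s.mean_ratio >= 0.0 for s in t.stats)

    def test_assortative_pairing_mode_runs(self):
        params = SimParams(n_generations=50, pairing="rank_assortative")
        t = run_simulation(params, 13)
        assert len(t.stats) == 50


class TestRunReplicates:
    def test_single_replicate_equals_single_run(self):
        params = SimParams(n_generations=100, n_replicates=1, master_seed=9)
        summary = run_replicates(params)
        single = run_simulation(params, derive_replicate_seed(9, 0))
        assert np.all(summary.mean_ratio_sd == 0.0)
        assert np.allclose(
            summary.mean_ratio_mean, [s.mean_ratio for s in single.stats]
        )
        assert np.allclose(
            summary.mean_armament_mean, [s.mean_armament for s in single.stats]
        )

    def test_replicates_have_distinct_seeds_and_finite_spread(self):
        params = SimParams(n_generations=200, n_replicates=4, master_seed=21)
        summary = run_replicates(params)
        assert len(set(summary.seeds)) == 4
        assert np.all(np.isfinite(summary.mean_ratio_sd))
        # independent runs diverge: spread is positive late in the run
        assert summary.mean_ratio_sd[-1] > 0.0

    def test_summary_dataframe_schema(self):
        params = SimParams(n_generations=20, n_replicates=2, master_seed=5)
        df = run_replicates(params).to_dataframe()
        assert set(df["stat"]) == {"mean", "sd"}
        assert list(df.columns) == ["stat", "generation", "mean_armament", "mean_ratio"]
        assert len(df) == 2 * 20
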