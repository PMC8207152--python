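"""Generation loop: mortality, contests, mating, replacement, statistics.

Each generation proceeds in a fixed order:

1. **Mortality sweep** over all adults.  Males killed in the previous
   generation's fights (condition exhausted) are removed first; every
   surviving adult then faces the natural death rate d, and males
   additionally face armament-ratio mortality.  Newborns of the current
   generation do not exist yet and are therefore never swept in their birth
   generation.
2. **Deficit**: the number of empty slots in the male and female pools.
3. **Contests and mating**: one contest per empty slot.  Two distinct
   living males are drawn (uniformly at random by default), the contest is
   resolved, and the winner mates a living female drawn uniformly at random
   (with replacement across contests).  Each mating yields one offspring
   genotype via blended inheritance plus mutation.
4. **Replacement**: offspring refill the male pool first, then the female
   pool, restoring exactly n_males and n_females.  Male offspring receive a
   fresh truncated-normal body size and full condition.
5. **Statistics** over the post-replacement living males.

Surviving males keep their depleted condition across generations: energy is
never replenished, so a male's fighting ability decays over his lifetime of
contests.  A run is fully determined by (params, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .combat import Male, make_male, resolve_fight
from .config import SimParams, derive_replicate_seed
from .genetics import inherit, init_founder_genotype, mutate
from .mortality import MortalityCurve

__all__ = [
    "Female",
    "Population",
    "GenerationStats",
    "Trajectory",
    "SummaryTrajectory",
    "PopulationCollapse",
    "init_population",
    "step_generation",
    "run_simulation",
    "run_replicates",
]


class PopulationCollapse(RuntimeError):
    """Raised when fewer than two living males (or no living female) remain
    while offspring are still needed; the run ends with a truncated trajectory."""


@dataclass(slots=True)
class Female:
    """A female individual: carries a genotype but expresses no armament."""

    id: int
    genotype: float
    alive: bool = True


@dataclass(slots=True)
class Population:
    males: list[Male]
    females: list[Female]
    generation: int = 0
    next_id: int = 0


@dataclass(frozen=True, slots=True)
class GenerationStats:
    """Per-generation summary over living males, plus event counts."""

    generation: int
    mean_armament: float
    mean_ratio: float
    n_fights: int
    n_default_wins: int
    n_deaths_natural: int
    n_deaths_armament: int
    n_deaths_combat: int


@dataclass(frozen=True)
class Trajectory:
    """A single run: parameters, seed, and per-generation statistics.

    ``collapsed`` flags a run that ended early because the male pool could
    no longer sustain contests; its stats are truncated but valid.
    """

    params: SimParams
    seed: int
    stats: tuple[GenerationStats, ...]
    collapsed: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.stats])


@dataclass(frozen=True)
class SummaryTrajectory:
    """Across-replicate per-generation mean and sd of the two trait summaries."""

    params: SimParams
    seeds: tuple[int, ...]
    generation: np.ndarray
    mean_armament_mean: np.ndarray
    mean_armament_sd: np.ndarray
    mean_ratio_mean: np.ndarray
    mean_ratio_sd: np.ndarray
    collapsed: tuple[bool, ...]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for stat, arm, ratio in (
            ("mean", self.mean_armament_mean, self.mean_ratio_mean),
            ("sd", self.mean_armament_sd, self.mean_ratio_sd),
        ):
            rows.append(
                pd.DataFrame(
                    {
                        "stat": stat,
                        "generation": self.generation,
                        "mean_armament": arm,
                        "mean_ratio": ratio,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _draw_body(params: SimParams, rng: np.random.Generator) -> float:
    """Truncated-normal body size by rejection."""
    while True:
        b = rng.normal(params.body_mean, params.body_sd)
        if params.body_min <= b <= params.body_max:
            return b


def init_population(params: SimParams, rng: np.random.Generator) -> Population:
    """Founders: full condition, uniform tiny genotypes, truncated-normal bodies."""
    pop = Population(males=[], females=[])
    k = params.allometric_slope
    for _ in range(params.n_males):
        pop.males.append(
            make_male(
                id=pop.next_id,
                body=_draw_body(params, rng),
                genotype=init_founder_genotype(rng, params.founder_trait_scale),
                k=k,
                condition=params.initial_condition,
            )
        )
        pop.next_id += 1
    for _ in range(params.n_females):
        pop.females.append(
            Female(id=pop.next_id, genotype=init_founder_genotype(rng, params.founder_trait_scale))
        )
        pop.next_id += 1
    return pop


def _record_stats(
    pop: Population,
    n_fights: int,
    n_default: int,
    n_nat: int,
    n_arm: int,
    n_combat: int,
) -> GenerationStats:
    arm_sum = 0.0
    g_sum = 0.0
    n = 0
    for m in pop.males:
        if m.alive:
            arm_sum += m.armament
            g_sum += m.genotype
            n += 1
    mean_arm = arm_sum / n if n else float("nan")
    mean_ratio = g_sum / n if n else float("nan")
    return GenerationStats(
        generation=pop.generation,
        mean_armament=mean_arm,
        mean_ratio=mean_ratio,
        n_fights=n_fights,
        n_default_wins=n_default,
        n_deaths_natural=n_nat,
        n_deaths_armament=n_arm,
        n_deaths_combat=n_combat,
    )


def step_generation(
    pop: Population, params: SimParams, rng: np.random.Generator
) -> tuple[Population, GenerationStats]:
    """Advance the population by one generation in place; returns (pop, stats).

    Raises :class:`PopulationCollapse` if a contest is needed but fewer than
    two living males (or no living female) remain.
    """
    pop.generation += 1
    curve = MortalityCurve(params.mortality_alpha, params.mortality_beta)
    d = params.natural_death_rate
    k = params.allometric_slope

    # --- (1) mortality sweep -------------------------------------------------
    n_combat = n_nat = n_arm = 0
    dead_male_slots: list[int] = []
    dead_female_slots: list[int] = []

    males = pop.males
    u_m = rng.random(len(males))
    for i, m in enumerate(males):
        if not m.alive:
            # fell in last generation's fights; remove and replace now
            n_combat += 1
            dead_male_slots.append(i)
            continue
        u = u_m[i]
        if u < d:
            n_nat += 1
            m.alive = False
            dead_male_slots.append(i)
            continue
        g = m.genotype
        if g > 1.0:
            mrate = min(((g - 1.0) / (curve.beta - 1.0)) ** curve.alpha, 1.0)
            if u < d + (1.0 - d) * mrate:
                n_arm += 1
                m.alive = False
                dead_male_slots.append(i)

    females = pop.females
    u_f = rng.random(len(females))
    for i, f in enumerate(females):
        if u_f[i] < d:
            n_nat += 1
            f.alive = False
            dead_female_slots.append(i)

    # --- (2) replacement deficit --------------------------------------------
    deficit_m = len(dead_male_slots)
    deficit_f = len(dead_female_slots)
    deficit = deficit_m + deficit_f

    living_m = [i for i, m in enumerate(males) if m.alive]
    living_f = [i for i, f in enumerate(females) if f.alive]

    # --- (3) contests and matings -------------------------------------------
    n_fights = n_default = 0
    offspring: list[float] = []
    mp, md = params.mutation_prob, params.mutation_delta
    assortative = params.pairing == "rank_assortative"
    for _ in range(deficit):
        if len(living_m) < 2 or not living_f:
            raise PopulationCollapse(
                f"generation {pop.generation}: "
                f"{len(living_m)} living males, {len(living_f)} living females"
            )
        if assortative:
            order = sorted(living_m, key=lambda i: males[i].armament)
            pos = int(rng.integers(len(order) - 1))
            i1, i2 = order[pos], order[pos + 1]
        else:
            n_liv = len(living_m)
            p1 = int(rng.integers(n_liv))
            p2 = int(rng.integers(n_liv - 1))
            if p2 >= p1:
                p2 += 1
            i1, i2 = living_m[p1], living_m[p2]
        m1, m2 = males[i1], males[i2]
        out = resolve_fight(m1, m2, params, rng)
        if out.physical_fight:
            n_fights += 1
        else:
            n_default += 1
        # males whose condition hit zero leave the contest pool immediately;
        # their slots are refilled in the next generation's sweep
        for idx in (i1, i2):
            if not males[idx].alive:
                living_m.remove(idx)
        winner = m1 if out.winner_id == m1.id else m2
        mate = females[living_f[int(rng.integers(len(living_f)))]]
        child = mutate(inherit(winner.genotype, mate.genotype, rng), mp, md, rng)
        offspring.append(child)

    # --- (4) replacement: refill the male pool first -------------------------
    for j, slot in enumerate(dead_male_slots):
        males[slot] = make_male(
            id=pop.next_id,
            body=_draw_body(params, rng),
            genotype=offspring[j],
            k=k,
            condition=params.initial_condition,
        )
        pop.next_id += 1
    for j, slot in enumerate(dead_female_slots):
        females[slot] = Female(id=pop.next_id, genotype=offspring[deficit_m + j])
        pop.next_id += 1

    # --- (5) statistics -------------------------------------------------------
    stats = _record_stats(pop, n_fights, n_default, n_nat, n_arm, n_combat)
    return pop, stats


def run_simulation(params: SimParams, seed: int) -> Trajectory:
    """Run one simulation of ``params.n_generations`` generations from ``seed``."""
    rng = np.random.default_rng(seed)
    pop = init_population(params, rng)
    stats: list[GenerationStats] = []
    collapsed = False
    for _ in range(params.n_generations):
        try:
            _, s = step_generation(pop, params, rng)
        except PopulationCollapse:
            collapsed = True
            break
        stats.append(s)
    return Trajectory(params=params, seed=seed, stats=tuple(stats), collapsed=collapsed)


def run_replicates(params: SimParams) -> SummaryTrajectory:
    """Run ``params.n_replicates`` independent simulations and aggregate.

    Replicate seeds derive deterministically from ``params.master_seed``.
    Aggregation covers the generations present in every replicate (shorter,
    collapsed runs truncate the summary to the common length).
    """
    seeds = tuple(
        derive_replicate_seed(params.master_seed, i) for i in range(params.n_replicates)
    )
    trajectories = [run_simulation(params, s) for s in seeds]
    n_common = min(len(t.stats) for t in trajectories)
    arm = np.array(
        [[s.mean_armament for s in t.stats[:n_common]] for t in trajectories]
    )
    ratio = np.array(
        [[s.mean_ratio for s in t.stats[:n_common]] for t in trajectories]
    )
    return SummaryTrajectory(
        params=params,
        seeds=seeds,
        generation=np.arange(1, n_common + 1),
        mean_armament_mean=arm.mean(axis=0),
        mean_armament_sd=arm.std(axis=0, ddof=0),
        mean_ratio_mean=ratio.mean(axis=0),
        mean_ratio_sd=ratio.std(axis=0, ddof=0),
        collapsed=tuple(t.collapsed for t in trajectories),
    )
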