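# Methods

## Model overview

`armevo` simulates a closed population with discrete, overlapping-survivor
generations: a fixed pool of `n_males` males and `n_females` females in
which only the slots vacated by death are refilled each generation. The
male phenotype has three components — a heritable armament-ratio genotype
`g ≥ 0`, a non-heritable body size `b`, and a depletable physical condition
`c ∈ [0, 100]` — combined into an expressed armament `a = b^k g` and a
per-fight fighting ability `f = a · b^k · c/100`. Females carry (and
transmit) the genotype but express no armament and face no armament
mortality.

The model isolates intrasexual selection: females exert no mate choice, all
mating opportunities flow through contest victories, and energy spent in
fights is never recovered. Armament exaggeration is opposed only by the
armament-ratio mortality trade-off and by the loss of condition in fights.

## Generation cycle

Each generation executes, in order:

1. **Mortality sweep.** Males who exhausted their condition in the previous
   generation's fights are removed first (their slots were occupied by the
   corpse until now; see *Bookkeeping* below). Every surviving adult then
   faces the natural death rate `d`; males additionally face armament
   mortality `m(g)`. The two hazards are composed independently (survival
   probability `(1−d)(1−m)`), the minimal assumption when neither hazard is
   stated to preempt the other.
2. **Deficit.** The number of empty slots across both pools.
3. **Contests and matings.** One contest per empty slot: two distinct
   living males are drawn uniformly at random (a male may fight repeatedly
   within a generation — consistent with condition depleting over fights),
   the contest is resolved by the threshold-retreat rule and, if needed, a
   physical fight, and the winner mates a living female drawn uniformly at
   random with replacement (a female may bear several offspring per
   generation). Each mating yields one offspring genotype
   `mutate(inherit(g_sire, g_dam))`. A male whose condition reaches zero
   mid-generation leaves the contest pool immediately. The winner of the
   fight in which he spent his last condition still mates: the mating is
   the prize of the victory already won.
4. **Replacement.** Offspring refill the male pool first, then the female
   pool, restoring the exact pool sizes. Male offspring draw a fresh body
   size from the truncated normal and start at full condition. Newborns
   are exempt from mortality in their birth generation by construction
   (the sweep precedes the births).
5. **Statistics** (mean armament size and mean armament ratio) over the
   living males after replacement.

**Bookkeeping.** Males killed in the fight phase stay in the male pool,
flagged dead and excluded from fighting, mating and statistics, until the
next generation's sweep replaces them. This keeps the pool sizes exactly
constant at every observation point while preserving the rule that each
generation replaces the individuals who died in the previous one; the only
alternative (refilling mid-generation) would make the number of matings
depend on the order in which fights happen to kill.

**Collapse.** If a contest is needed but fewer than two living males (or
no living female) remain, the run ends gracefully with a truncated,
flagged trajectory rather than an error — at the default death rate this
requires pathological parameter choices, but sweeps may reach them.

## Parameters

| field | meaning | default | notes |
|---|---|---|---|
| `n_males`, `n_females` | fixed pool sizes | 100, 100 | population regulation is absolute |
| `n_generations` | generations per run | 100,000 | presets use 5,000 at reduced scale |
| `natural_death_rate` | background death probability / generation | 0.31 | applies to both sexes, adults only |
| `allometric_slope` | exponent `k` in `a = b^k g` | 1.35 | `k > 1` = positive allometry |
| `body_mean`, `body_sd` | body-size distribution | 200, 15 | truncated normal, rejection-sampled |
| `body_min`, `body_max` | truncation bounds | 150, 250 | ~99.9% acceptance at defaults |
| `cost_winner`, `cost_loser` | condition lost in a physical fight (W, L) | 5, 10 | `L > W` enforced; flat, body-independent |
| `r_thres` | retreat threshold on the armament ratio of a pair | 1.5 | `≥ 1`; at exactly 1 every contest settles by default |
| `mortality_alpha` | convexity exponent α of the mortality curve | 10 | large α = mortality rises late |
| `mortality_beta` | ratio β at which mortality reaches 1 | 10 | curve clamped to 1 beyond β |
| `mutation_prob` | per-offspring mutation probability M | 1e-5 | |
| `mutation_delta` | half-width δ of the relative mutation | 0.1 | multiplicative kernel, see below |
| `founder_trait_scale` | founder genotypes ~ U(0, scale) | 0.01 | founders are essentially unarmed |
| `initial_condition` | condition at birth | 100 | 0 means dead |
| `pairing` | contest pairing policy | `uniform` | `rank_assortative` pairs armament-rank neighbours (sensitivity mode) |
| `n_replicates`, `master_seed` | replication | 20, 0 | per-replicate seeds derived deterministically |

Costs are flat condition units regardless of body size: the observation
that small fighters injure each other less is treated as commentary, not a
formula, keeping the cost structure identical across the body-size range.

The `/100` normalizer in the fighting-ability product is fixed at 100 (the
nominal full condition), not tied to `initial_condition`, so changing the
starting condition rescales ability rather than silently redefining it.

## Design choices where the design was open

* **Blend weight per conception.** `P1` is redrawn uniformly at every
  conception. A fixed global `P1` would make inheritance a deterministic
  linear map, collapse all trait variance in a few generations, and remove
  the stated source of armament differences between same-sized males.
* **Mutation kernel.** The mutation probability is specified by the model;
  the kernel is not. A multiplicative perturbation `g → g(1+ε)`,
  `ε ~ U(−δ, δ)`, keeps the trait nonnegative and scale-free (the same
  relative effect whether the population ratio is 0.005 or 5), which an
  additive kernel with a fixed step cannot do across four orders of
  magnitude.
* **Founder genotypes** are drawn per individual from `U(0, 0.01)`; the
  initial parental contributions are specified only as `0.01·rand`, and a
  per-individual draw is the reading that produces standing variance for
  selection to act on.
* **Body size is redrawn** for each male offspring rather than inherited:
  the model specifies the male body-size distribution but no body-size
  heritability, so body size acts as environmental noise in contests.
* **Fight outcomes are deterministic** given abilities (the
  better-equipped male wins); exact ties — equal abilities, or equal
  armaments when `r_thres = 1` puts the pair in the default branch — are
  broken by a fair coin flip from the run's seeded stream.
* **Number of contests = replacement deficit.** With both pool sizes held
  fixed and one offspring per mating, the only consistent reading is one
  contest/mating per death to be replaced.
* **Sex assignment of offspring** refills the male pool first, then the
  female pool, deterministically; coin-flip sexes would violate the fixed
  pool sizes the model states.

## Seeding and determinism

A run is a pure function of `(params, seed)`. Replicate seeds derive from
the master seed by hashing it to a 31-bit base (`numpy.random.SeedSequence`)
and adding the replicate index modulo 2³¹ — injective in the index by
construction, and decorrelated by the generator's own seed scrambling.
Sweep cells derive an independent 31-bit master seed from the base master
seed and the cell index, so sweep results are independent of cell execution
order. All outputs (trajectory CSV at full float precision, YAML manifest
with the parameter snapshot and every derived seed) suffice to regenerate a
run bit-for-bit.

## Numerical choices

* The mortality polynomial is clamped to 1 above β; probabilities never
  exceed 1.
* Condition is clamped at 0; zero condition marks death.
* Blending of exactly equal parental genotypes returns the shared value
  exactly (no floating-point drift), so a monomorphic, mutation-free
  population is a true fixed point of the dynamics.
* Truncated-normal body sizes use rejection sampling — exact, and at the
  default bounds (±3.3σ) the acceptance rate is ≈ 99.9%.
* A zero armament facing a positive one yields an infinite pair ratio (the
  unarmed male always retreats); two zero armaments are a perfect tie
  (ratio 1).

## What the simulation does and does not emulate

The generator's defaults describe a deer-like system: bodies ~ N(200, 15),
positive allometry `k = 1.35`, a 31% annual background death rate, and
founders with negligible weapons. Real systems differ in ways the model
deliberately omits: female choice, resource re-acquisition between fights,
body-size heritability, multi-male contests, assessment error, and
age-structured mortality. Conclusions from these simulations concern the
isolated logic of contest-driven selection under a mortality trade-off, not
any particular taxon.

One structural property matters for interpreting time scales: blending
inheritance is a convex combination, so no offspring can exceed the range
of its parents' genotypes. Selection on founder variance therefore drives
the mean armament ratio only toward the top of the founder range (≈ 0.01),
after which further exaggeration requires new mutations, which arrive at a
rate of roughly `M ×` (deficit ≈ 63 offspring/generation) ≈ 6×10⁻⁴ per
generation at the default `M = 10⁻⁵`. At the reduced experiment scale
(5,000 generations) this mutational input is negligible: the scaled
parameter contrasts probe the selection-on-standing-variance phase, in
which the mean ratio sits near the blending plateau and far below the
`a_rt > 1` region where the mortality curve and its convexity act at all.
The acceptance script's computed contrasts reflect this: the armament
*size* ordering across allometric slopes is large and robust (the explicit
`b^k` leverage), while the final armament-*ratio* differences between
slopes, and between mortality convexities, are within replicate noise at
that scale. Probing the mortality-regulated regime requires either far
longer horizons with a richer mutation supply or founders seeded near
`a_rt ≈ 1`; both are parameter choices away (`founder_trait_scale`,
`mutation_prob`), not code changes.

## Reduced problem sizes

Preset experiments default to 5,000 generations and 5 replicates — enough
to resolve the founder-variance selection phase and the contest/mortality
bookkeeping at desk-run times — with the full published scale (100,000
generations; 10 or 20 replicates depending on the preset) behind
`scale="full"`.
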