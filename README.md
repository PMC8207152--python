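# armevo

An individual-based simulator of the evolution of exaggerated male
**armaments** — weapons used in male–male contests, such as deer antlers or
fiddler-crab chelae — through intrasexual selection, for theoretical
evolutionary ecologists studying when sexual selection escalates weapon size
and when natural selection reins it in.

## Model

A population of `n1` males and `n2` females is held at fixed size across
discrete generations. Each male carries a heritable scalar genotype
`g = P1·x + P2·y` (blended from his parents' genotypes with a random weight
`P1 ~ U(0,1)`, `P2 = 1 − P1`) and a body size `b ~ N(μ, σ²)` truncated to
`[b_min, b_max]`. His armament is expressed allometrically:

    a = b^k · g,         so the armament ratio  a / b^k = g,

where `k` is the allometric slope (`k > 1`: disproportionate weapon growth
with body size). Males compete pairwise for matings:

* if the larger-to-smaller armament ratio of the pair reaches a threshold
  `r_thres ≥ 1`, the smaller-armed male retreats and the larger wins **by
  default**, at no cost;
* otherwise a physical fight occurs, won by the male with the greater
  fighting ability `f = a · b^k · c/100`, where `c` is his depletable
  physical condition (100 at birth, 0 = dead). The winner loses `W`
  condition units, the loser `L > W`; condition is never replenished.

Each contest winner mates a randomly drawn female; one offspring (blended
genotype, mutated with probability `M` by a multiplicative factor
`1 + U(−δ, δ)`) fills one slot left by death. Deaths arise from a natural
death rate `d` and, for males, from an armament-ratio mortality trade-off

    m(a_rt) = 0                       for a_rt ≤ 1,
    m(a_rt) = ((a_rt−1)/(β−1))^α      for a_rt > 1 (clamped at 1),

which is zero while the weapon is smaller than the body term, reaches
certainty at ratio `β`, and rises the more slowly the larger the convexity
exponent `α`. See `docs/methods.md` for assumptions, parameter defaults and
numerical details.

## Worked example

```python
from armevo import SimParams, run_replicates

params = SimParams(n_generations=2000, n_replicates=3, master_seed=7)
s = run_replicates(params)
print(f"final mean armament ratio: {s.mean_ratio_mean[-1]:.5f} +/- {s.mean_ratio_sd[-1]:.5f}")
print(f"final mean armament size:  {s.mean_armament_mean[-1]:.2f}")
print(f"founder-generation ratio:  {s.mean_ratio_mean[0]:.5f}")
```

prints

```
final mean armament ratio: 0.00680 +/- 0.00039
final mean armament size:  8.80
founder-generation ratio:  0.00528
```

Founders start with armament ratios uniform on [0, 0.01) (mean 0.005, here
0.00528 in generation 1). Over 2,000 generations contest winners are
enriched for large armaments, so the mean ratio climbs toward the upper end
of the founder range (0.00680 ± 0.00039 across three replicates); the mean
armament *size* of 8.80 reflects the additional `b^k ≈ 200^1.35` body-size
leverage. Because inheritance blends parental values, sustained growth
beyond the founder range requires new mutations, which at the default
mutation probability (10⁻⁵ per offspring) arrive rarely — see
`docs/methods.md` for what this implies at different time scales.

The same run from a shell:

```bash
armevo run --generations 2000 --replicates 3 --seed 7 --out out/
armevo sweep --preset fig2 --scale reduced --seed 1 --out out/   # k ∈ {1, 1.25, 1.35}
armevo presets                                                   # list all preset grids
```

Preset sweeps (`fig2`, `fig5`, `fig6`, `fig9`, `fig12`) vary the allometric
slope, the contest costs, the retreat threshold and the mortality convexity
over the published grids, at a reduced scale by default (5,000 generations,
5 replicates) or at full scale (100,000 generations) with `--scale full`.

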