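"""Trait genetics: founder draws, blended inheritance, mutation, allometry.

The heritable trait is a single nonnegative scalar genotype g.  A male with
body size b expresses an armament of size a = b**k * g, where k is the
allometric slope; the armament ratio a / b**k therefore equals g itself, so
the genotype can be read directly as the armament-to-body-power ratio.

Inheritance is blending: an offspring receives P1*x + (1-P1)*y, where x and y
are the paternal and maternal genotypes and P1 is drawn uniformly on [0, 1]
anew at each conception.  The offspring trait then mutates with a small
probability, by a multiplicative perturbation g * (1 + eps) with eps uniform
on [-delta, +delta]; multiplicative mutation keeps the trait scale-free and
nonnegative.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "init_founder_genotype",
    "inherit",
    "mutate",
    "armament_size",
    "armament_ratio",
]


def init_founder_genotype(rng: np.random.Generator, scale: float = 0.01) -> float:
    """Draw a founder genotype uniformly from [0, scale).

    Founders start with tiny armament ratios (default scale 0.01), so any
    exaggeration observed later is evolved, not seeded.
    """
    if scale <= 0:
        raise ValueError(f"founder trait scale must be > 0, got {scale}")
    return scale * rng.random()


def inherit(x: float, y: float, rng: np.random.Generator) -> float:
    """Blend parental genotypes: P1*x + (1-P1)*y with P1 ~ U[0, 1).

    The result always lies in the closed interval spanned by the parents.
    Equal parents are returned exactly (no floating-point drift), which keeps
    a monomorphic population monomorphic in the absence of mutation.
    """
    p1 = rng.random()
    if x == y:
        return x
    return p1 * x + (1.0 - p1) * y


def mutate(
    g: float,
    mutation_prob: float,
    mutation_delta: float,
    rng: np.random.Generator,
) -> float:
    """With probability ``mutation_prob``, perturb g to g*(1+eps), eps ~ U[-delta, delta].

    The result is clamped at zero; a genotype can never become negative.
    """
    if not 0.0 <= mutation_prob <= 1.0:
        raise ValueError(f"mutation_prob must lie in [0, 1], got {mutation_prob}")
    if mutation_delta < 0.0:
        raise ValueError(f"mutation_delta must be >= 0, got {mutation_delta}")
    if mutation_prob > 0.0 and rng.random() < mutation_prob:
        eps = rng.uniform(-mutation_delta, mutation_delta)
        return max(0.0, g * (1.0 + eps))
    return g


def armament_size(body: float, k: float, g: float) -> float:
    """Expressed armament size a = body**k * g."""
    if body <= 0:
        raise ValueError(f"body size must be > 0, got {body}")
    return body**k * g


def armament_ratio(armament: float, body: float, k: float) -> float:
    """Armament ratio a / body**k; exact inverse of :func:`armament_size`."""
    if body <= 0:
        raise ValueError(f"body size must be > 0, got {body}")
    return armament / body**k
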