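"""Pairwise contest resolution between males.

Contests follow a two-stage assessment rule.  First the armament sizes of
the rivals are compared: if the ratio of the larger to the smaller armament
is at least the retreat threshold ``r_thres``, the smaller-armed male backs
down and the larger-armed male wins *by default*, with no physical fight and
no cost to either side.  Otherwise a physical fight occurs and the male with
the greater fighting ability wins, where

    fighting ability = armament * body**k * condition / 100.

A physical fight injures both contestants: the winner's condition drops by
W and the loser's by L (L > W), clamped at zero.  A male whose condition
reaches zero dies.  Exact ability ties (and exact armament ties inside the
default branch) are broken by a fair coin flip from the caller's RNG stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import SimParams
from .genetics import armament_size

__all__ = [
    "Male",
    "make_male",
    "FightOutcome",
    "pair_ratio",
    "default_winner",
    "fighting_ability",
    "resolve_fight",
]


@dataclass(slots=True)
class Male:
    """A male individual.

    ``armament`` is cached at construction from (body, genotype, slope) and
    never changes afterwards: body size and genotype are fixed at birth, so
    the expressed armament is too.  Only ``condition`` and ``alive`` mutate,
    through fight costs and death.
    """

    id: int
    body: float
    genotype: float
    armament: float
    condition: float
    alive: bool = True


def make_male(
    id: int,
    body: float,
    genotype: float,
    k: float,
    condition: float = 100.0,
) -> Male:
    """Construct a male with armament expressed from body size and genotype."""
    return Male(
        id=id,
        body=body,
        genotype=genotype,
        armament=armament_size(body, k, genotype),
        condition=condition,
    )


@dataclass(frozen=True, slots=True)
class FightOutcome:
    """Result of one contest.

    ``physical_fight`` is False when the contest was settled by default
    (retreat), in which case both applied costs are zero.  ``ratio`` is the
    larger-to-smaller armament ratio of the pair (inf when exactly one
    armament is zero).
    """

    winner_id: int
    loser_id: int
    physical_fight: bool
    ratio: float
    cost_applied_winner: float
    cost_applied_loser: float


def pair_ratio(a1: float, a2: float) -> float:
    """Larger armament divided by the smaller.

    Exactly one zero armament gives +inf (the zero-armed male always
    retreats); two zero armaments are a perfect tie, defined as ratio 1.
    """
    if a1 < 0 or a2 < 0:
        raise ValueError(f"armament sizes must be >= 0, got {a1}, {a2}")
    lo, hi = (a1, a2) if a1 <= a2 else (a2, a1)
    if hi == 0.0:
        return 1.0
    if lo == 0.0:
        return math.inf
    return hi / lo


def default_winner(
    m1: Male,
    m2: Male,
    r_thres: float,
    rng: Optional[np.random.Generator] = None,
) -> Optional[int]:
    """Id of the male who wins by default, or None if a physical fight is needed.

    When the pair ratio reaches ``r_thres``, the male with the larger
    armament wins without fighting.  An exact armament tie can enter this
    branch only when r_thres == 1; it is broken by a coin flip from ``rng``.
    """
    r = pair_ratio(m1.armament, m2.armament)
    if r < r_thres:
        return None
    if m1.armament > m2.armament:
        return m1.id
    if m2.armament > m1.armament:
        return m2.id
    if rng is None:
        raise ValueError("exact armament tie in the default branch requires an rng")
    return m1.id if rng.random() < 0.5 else m2.id


def fighting_ability(armament: float, body: float, k: float, condition: float) -> float:
    """Fighting ability: armament * body**k * condition / 100.

    The /100 normalizer makes full condition (100) contribute a factor of 1.
    """
    if condition < 0:
        raise ValueError(f"condition must be >= 0, got {condition}")
    return armament * body**k * condition / 100.0


def resolve_fight(
    m1: Male,
    m2: Male,
    params: SimParams,
    rng: np.random.Generator,
) -> FightOutcome:
    """Resolve one contest between two living males, mutating their condition.

    Applies the default-winner rule first; on a physical fight the greater
    fighting ability wins, costs W/L are deducted (clamped at zero) and a
    male whose condition reaches zero is marked dead.  Genotype, body size
    and armament are never modified.
    """
    if not (m1.alive and m2.alive):
        raise ValueError("resolve_fight called with a dead participant")
    if m1.condition <= 0 or m2.condition <= 0:
        raise ValueError("resolve_fight called with a zero-condition participant")
    if m1.id == m2.id:
        raise ValueError("a male cannot fight himself")

    ratio = pair_ratio(m1.armament, m2.armament)
    dw = default_winner(m1, m2, params.r_thres, rng)
    if dw is not None:
        loser = m2.id if dw == m1.id else m1.id
        return FightOutcome(
            winner_id=dw,
            loser_id=loser,
            physical_fight=False,
            ratio=ratio,
            cost_applied_winner=0.0,
            cost_applied_loser=0.0,
        )

    k = params.allometric_slope
    f1 = fighting_ability(m1.armament, m1.body, k, m1.condition)
    f2 = fighting_ability(m2.armament, m2.body, k, m2.condition)
    if f1 > f2:
        winner, loser = m1, m2
    elif f2 > f1:
        winner, loser = m2, m1
    else:
        winner, loser = (m1, m2) if rng.random() < 0.5 else (m2, m1)

    winner.condition = max(0.0, winner.condition - params.cost_winner)
    loser.condition = max(0.0, loser.condition - params.cost_loser)
    if winner.condition <= 0.0:
        winner.alive = False
    if loser.condition <= 0.0:
        loser.alive = False

    return FightOutcome(
        winner_id=winner.id,
        loser_id=loser.id,
        physical_fight=True,
        ratio=ratio,
        cost_applied_winner=params.cost_winner,
        cost_applied_loser=params.cost_loser,
    )
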