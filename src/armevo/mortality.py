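"""Armament-ratio mortality curve and per-generation survival sampling.

Natural selection penalizes armaments larger than the body: a male whose
armament ratio a_rt exceeds 1 (armament bigger than the allometric body
term) suffers an extra death probability

    m(a_rt) = 0                                   for a_rt <= 1
    m(a_rt) = ((a_rt - 1) / (beta - 1))**alpha    for a_rt > 1, clamped to 1

so mortality is zero up to ratio 1, reaches certainty at ratio beta, and the
exponent alpha sets the convexity: large alpha means mortality stays near
zero over most of (1, beta) and rises abruptly near beta, which is the
regime in which exaggerated armaments can evolve.

Natural death (rate d, independent of armaments) and armament mortality are
composed as independent hazards within a generation: survival probability
(1 - d) * (1 - m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MortalityCurve", "armament_mortality", "survives_generation"]


@dataclass(frozen=True, slots=True)
class MortalityCurve:
    """Armament-ratio mortality curve parameters.

    ``beta`` is the ratio at which mortality reaches 1; ``alpha`` the
    convexity exponent.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta <= 1:
            raise ValueError(f"beta must be > 1, got {self.beta}")


def armament_mortality(a_rt, curve: MortalityCurve):
    """Death probability m(a_rt) from the armament ratio; scalar or ndarray.

    Zero for a_rt <= 1, ((a_rt-1)/(beta-1))**alpha above, clamped to 1 for
    ratios beyond beta (the raw polynomial exceeds 1 there).
    """
    a = np.asarray(a_rt, dtype=float)
    if np.any(a < 0):
        raise ValueError("armament ratio must be >= 0")
    excess = np.clip(a - 1.0, 0.0, None)
    m = np.minimum((excess / (curve.beta - 1.0)) ** curve.alpha, 1.0)
    if np.isscalar(a_rt) or np.ndim(a_rt) == 0:
        return float(m)
    return m


def survives_generation(
    individual_ratio: float,
    curve: MortalityCurve,
    d: float,
    rng: np.random.Generator,
) -> bool:
    """Sample one generation of survival under natural + armament hazards.

    Survival probability is (1-d)*(1-m(a_rt)).  Individuals without an
    armament (females) should be passed ratio 0 and then face only d.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"natural death rate must lie in [0, 1], got {d}")
    m = armament_mortality(individual_ratio, curve)
    return rng.random() < (1.0 - d) * (1.0 - m)
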