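"""Simulation parameters: definition, validation, YAML loading and replicate seeding.

The full parameter set of the model lives in a single frozen dataclass,
:class:`SimParams`.  Defaults are the baseline study conditions: 100 males and
100 females, natural death rate 0.31 per generation, allometric slope 1.35,
body size ~ N(200, 15) truncated to [150, 250], contest costs W=5 / L=10,
retreat threshold 1.5, and a mortality curve with alpha=10, beta=10.

Config files are flat YAML mappings whose keys match the SimParams field
names.  Unknown keys are a hard error so that a typo in a parameter name can
never silently run the default instead.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = [
    "SimParams",
    "ParamError",
    "load_params",
    "params_to_dict",
    "save_params",
    "derive_replicate_seed",
]

PAIRING_MODES = ("uniform", "rank_assortative")


class ParamError(ValueError):
    """A parameter failed validation; the message names the offending field."""


@dataclass(frozen=True)
class SimParams:
    """Complete parameter set for one simulation experiment.

    Attributes
    ----------
    n_males, n_females
        Fixed numbers of males and females maintained every generation.
    n_generations
        Number of discrete generations to iterate.
    natural_death_rate
        Per-generation probability of death unrelated to armaments (d).
    allometric_slope
        Exponent k linking body size to armament size, a = b**k * g.
    body_mean, body_sd, body_min, body_max
        Truncated-normal body size distribution (rejection sampling).
    cost_winner, cost_loser
        Condition units lost in a physical fight (W and L, with L > W).
    r_thres
        Armament-size ratio at or above which the smaller-armed male
        retreats and the larger wins by default (>= 1).
    mortality_alpha, mortality_beta
        Shape exponent and saturation ratio of the armament-ratio mortality
        curve; mortality reaches 1 at ratio beta.
    mutation_prob
        Per-offspring probability that the inherited trait mutates (M).
    mutation_delta
        Half-width of the relative (multiplicative) mutation perturbation.
    founder_trait_scale
        Founder genotypes are drawn uniformly from [0, founder_trait_scale).
    initial_condition
        Physical condition at birth; 0 means dead.
    pairing
        Fight pairing policy: "uniform" (default) draws contestants uniformly
        at random; "rank_assortative" pairs neighbours in armament rank.
    n_replicates, master_seed
        Replicate count and the seed from which per-replicate seeds derive.
    """

    n_males: int = 100
    n_females: int = 100
    n_generations: int = 100_000
    natural_death_rate: float = 0.31
    allometric_slope: float = 1.35
    body_mean: float = 200.0
    body_sd: float = 15.0
    body_min: float = 150.0
    body_max: float = 250.0
    cost_winner: float = 5.0
    cost_loser: float = 10.0
    r_thres: float = 1.5
    mortality_alpha: float = 10.0
    mortality_beta: float = 10.0
    mutation_prob: float = 0.00001
    mutation_delta: float = 0.1
    founder_trait_scale: float = 0.01
    initial_condition: float = 100.0
    pairing: str = "uniform"
    n_replicates: int = 20
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_males", "n_females", "n_generations", "n_replicates"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 1:
                raise ParamError(f"{name} must be an integer >= 1, got {v!r}")
        if not isinstance(self.master_seed, (int, np.integer)) or isinstance(self.master_seed, bool):
            raise ParamError(f"master_seed must be an integer, got {self.master_seed!r}")
        if not 0.0 <= self.natural_death_rate <= 1.0:
            raise ParamError(
                f"natural_death_rate must lie in [0, 1], got {self.natural_death_rate}"
            )
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ParamError(f"mutation_prob must lie in [0, 1], got {self.mutation_prob}")
        if self.mutation_delta < 0.0:
            raise ParamError(f"mutation_delta must be >= 0, got {self.mutation_delta}")
        if self.founder_trait_scale <= 0.0:
            raise ParamError(
                f"founder_trait_scale must be > 0, got {self.founder_trait_scale}"
            )
        if self.initial_condition <= 0.0:
            raise ParamError(
                f"initial_condition must be > 0, got {self.initial_condition}"
            )
        if not self.body_min <= self.body_mean <= self.body_max:
            raise ParamError(
                "body_min <= body_mean <= body_max required, got "
                f"body_min={self.body_min}, body_mean={self.body_mean}, "
                f"body_max={self.body_max}"
            )
        if self.body_min <= 0.0:
            raise ParamError(f"body_min must be > 0, got {self.body_min}")
        if self.body_sd <= 0.0:
            raise ParamError(f"body_sd must be > 0, got {self.body_sd}")
        if self.cost_winner < 0.0:
            raise ParamError(f"cost_winner must be >= 0, got {self.cost_winner}")
        if not self.cost_loser > self.cost_winner:
            raise ParamError(
                "cost_loser must exceed cost_winner (loser is injured more), got "
                f"cost_winner={self.cost_winner}, cost_loser={self.cost_loser}"
            )
        if self.r_thres < 1.0:
            raise ParamError(f"r_thres must be >= 1, got {self.r_thres}")
        if self.mortality_alpha <= 0.0:
            raise ParamError(f"mortality_alpha must be > 0, got {self.mortality_alpha}")
        if self.mortality_beta <= 1.0:
            raise ParamError(f"mortality_beta must be > 1, got {self.mortality_beta}")
        if self.pairing not in PAIRING_MODES:
            raise ParamError(
                f"pairing must be one of {PAIRING_MODES}, got {self.pairing!r}"
            )

    def replace(self, **changes: Any) -> "SimParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


_FIELD_NAMES = frozenset(f.name for f in dataclasses.fields(SimParams))


def load_params(source: str | Path | Mapping[str, Any] | None = None) -> SimParams:
    """Build a validated :class:`SimParams` from a YAML file or a mapping.

    Absent keys take their defaults; unknown keys raise :class:`ParamError`.
    An empty document (or ``None``) yields the full default parameter set.
    """
    if source is None:
        doc: Mapping[str, Any] = {}
    elif isinstance(source, Mapping):
        doc = source
    else:
        text = Path(source).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ParamError(
                f"config document must be a flat key-value mapping, got {type(loaded).__name__}"
            )
        doc = loaded
    unknown = sorted(set(doc) - _FIELD_NAMES)
    if unknown:
        raise ParamError(f"unknown config keys: {', '.join(unknown)}")
    return SimParams(**dict(doc))


def params_to_dict(params: SimParams) -> dict[str, Any]:
    """Flat plain-python dict of all parameter fields (YAML-serializable)."""
    return dataclasses.asdict(params)


def save_params(params: SimParams, path: str | Path) -> None:
    """Write the parameter set as a flat YAML document."""
    Path(path).write_text(
        yaml.safe_dump(params_to_dict(params), sort_keys=False, default_flow_style=False)
    )


def derive_replicate_seed(master_seed: int, replicate_index: int) -> int:
    """Deterministic per-replicate seed derived from the master seed.

    The master seed is hashed to a 31-bit base via ``numpy.random.SeedSequence``
    and the replicate index added modulo 2**31, so for a fixed master seed the
    mapping is injective over any range of 2**31 consecutive indices.  The
    returned integer is fed to ``numpy.random.default_rng`` which scrambles it
    again, so consecutive derived seeds yield statistically independent streams.
    """
    if replicate_index < 0:
        raise ValueError(f"replicate_index must be >= 0, got {replicate_index}")
    base = int(np.random.SeedSequence(master_seed).generate_state(1)[0]) >> 1
    return (base + replicate_index) % (1 << 31)
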