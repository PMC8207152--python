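"""Named parameter sweeps replicating the published simulation experiments.

Each preset fixes the baseline parameter set and varies one knob (or one
linked group of knobs) over the grid used in the corresponding figure of the
study this simulator reproduces:

* ``fig2``  — allometric slope k in {1, 1.25, 1.35}
* ``fig5``  — loser cost L in {10, 15, 20, 25, 30} at fixed W = 5
* ``fig6``  — linked contest costs (W, L) in {(5,10), (10,20), (15,30)}
* ``fig9``  — retreat threshold r_thres in {1.5, 2.75, 4}
* ``fig12`` — mortality convexity alpha in {1, 2, 10} at beta = 10

Presets default to a reduced scale (5,000 generations, 5 replicates) that
runs on a desktop in minutes; ``scale="full"`` restores the published scale
(100,000 generations; 20 replicates for fig2/fig6/fig9, 10 for fig5/fig12).
Only the generation count and replicate count differ between scales.

Sweep results are returned as a tidy long-format table, one row per
(cell, statistic, generation), suitable for direct CSV export or plotting.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import SimParams
from .engine import run_replicates

__all__ = [
    "SweepSpec",
    "PRESET_NAMES",
    "get_preset",
    "run_sweep",
    "final_ratio_ordering",
]

# a varied key is either one SimParams field name, or a tuple of field names
# varied jointly (value lists then hold tuples of the same arity)
VariedMap = Mapping[str | tuple[str, ...], Sequence[Any]]

REDUCED_GENERATIONS = 5_000
REDUCED_REPLICATES = 5
FULL_GENERATIONS = 100_000


@dataclass(frozen=True)
class SweepSpec:
    """A Cartesian parameter sweep around a base parameter set."""

    base: SimParams
    varied: VariedMap
    label: str = "sweep"

    def __post_init__(self) -> None:
        if not self.varied:
            raise ValueError("a sweep must vary at least one parameter")
        valid = {f.name for f in dataclasses.fields(SimParams)}
        for key, values in self.varied.items():
            names = key if isinstance(key, tuple) else (key,)
            for name in names:
                if name not in valid:
                    raise ValueError(f"unknown swept parameter: {name!r}")
            if len(values) == 0:
                raise ValueError(f"empty value list for swept parameter {key!r}")
            if isinstance(key, tuple):
                for v in values:
                    if len(v) != len(key):
                        raise ValueError(
                            f"joint values for {key!r} must have arity {len(key)}"
                        )

    @property
    def param_columns(self) -> list[str]:
        cols: list[str] = []
        for key in self.varied:
            cols.extend(key if isinstance(key, tuple) else (key,))
        return cols

    def cells(self) -> list[dict[str, Any]]:
        """Cartesian product of the varied entries, as field->value dicts."""
        keys = list(self.varied)
        out = []
        for combo in itertools.product(*(self.varied[k] for k in keys)):
            cell: dict[str, Any] = {}
            for key, value in zip(keys, combo):
                if isinstance(key, tuple):
                    cell.update(dict(zip(key, value)))
                else:
                    cell[key] = value
            out.append(cell)
        return out


def _preset_specs(base: SimParams) -> dict[str, tuple[SweepSpec, int]]:
    """Preset table: label -> (spec, full-scale replicate count)."""
    return {
        "fig2": (
            SweepSpec(base, {"allometric_slope": [1.0, 1.25, 1.35]}, "fig2"),
            20,
        ),
        "fig5": (
            SweepSpec(
                base.replace(cost_winner=5.0),
                {"cost_loser": [10.0, 15.0, 20.0, 25.0, 30.0]},
                "fig5",
            ),
            10,
        ),
        "fig6": (
            SweepSpec(
                base,
                {
                    ("cost_winner", "cost_loser"): [
                        (5.0, 10.0),
                        (10.0, 20.0),
                        (15.0, 30.0),
                    ]
                },
                "fig6",
            ),
            20,
        ),
        "fig9": (
            SweepSpec(base, {"r_thres": [1.5, 2.75, 4.0]}, "fig9"),
            20,
        ),
        "fig12": (
            SweepSpec(base, {"mortality_alpha": [1.0, 2.0, 10.0]}, "fig12"),
            10,
        ),
    }


PRESET_NAMES = ("fig2", "fig5", "fig6", "fig9", "fig12")


def get_preset(
    name: str,
    scale: str = "reduced",
    base: SimParams | None = None,
    master_seed: int | None = None,
) -> SweepSpec:
    """Return a named preset sweep at the requested scale.

    ``scale`` is "reduced" (5,000 generations, 5 replicates) or "full"
    (100,000 generations at the published replicate count).  ``base``
    overrides the baseline parameter set; only n_generations and
    n_replicates are forced by the scale.
    """
    if scale not in ("reduced", "full"):
        raise ValueError(f"scale must be 'reduced' or 'full', got {scale!r}")
    base = base if base is not None else SimParams()
    if master_seed is not None:
        base = base.replace(master_seed=master_seed)
    table = _preset_specs(base)
    if name not in table:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(table)}")
    spec, full_reps = table[name]
    if scale == "full":
        scaled = spec.base.replace(n_generations=FULL_GENERATIONS, n_replicates=full_reps)
    else:
        scaled = spec.base.replace(
            n_generations=REDUCED_GENERATIONS, n_replicates=REDUCED_REPLICATES
        )
    return SweepSpec(scaled, spec.varied, spec.label)


def _cell_master_seed(master_seed: int, cell_index: int) -> int:
    """Independent 31-bit master seed for one sweep cell."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(cell_index,))
    return int(ss.generate_state(1)[0]) >> 1


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run every cell of the sweep and return a tidy long-format table.

    Columns: run_label, one column per swept parameter, stat ("mean"/"sd"
    across replicates), generation, mean_armament, mean_ratio.  Each cell's
    replicate seeds derive from the base master seed and the cell index, so
    results do not depend on execution order.
    """
    frames = []
    for cell_index, cell in enumerate(spec.cells()):
        params = spec.base.replace(
            **cell, master_seed=_cell_master_seed(spec.base.master_seed, cell_index)
        )
        summary = run_replicates(params)
        df = summary.to_dataframe()
        df.insert(0, "run_label", spec.label)
        for pos, (name, value) in enumerate(cell.items(), start=1):
            df.insert(pos, name, value)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def final_ratio_ordering(
    table: pd.DataFrame, param: str
) -> list[tuple[Any, float]]:
    """Rank swept values of ``param`` by final mean armament ratio.

    Takes the across-replicate mean trajectory rows, restricts to the last
    recorded generation, averages ``mean_ratio`` over any other swept
    dimensions, and returns (value, final_ratio) pairs sorted ascending by
    the final ratio.
    """
    if param not in table.columns:
        raise ValueError(f"parameter {param!r} not present in the sweep table")
    means = table[table["stat"] == "mean"]
    last_gen = means["generation"].max()
    final = means[means["generation"] == last_gen]
    grouped = final.groupby(param)["mean_ratio"].mean()
    return sorted(((v, float(r)) for v, r in grouped.items()), key=lambda t: t[1])
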