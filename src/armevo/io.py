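"""Serialization: trajectory CSV, run manifest (YAML), and run logs.

Trajectories are written as plain CSV with full float precision (shortest
round-trip representation), so a parsed-and-rewritten file is byte-identical
and every value survives the round trip exactly.  The manifest is a flat
YAML document holding everything needed to regenerate the outputs: the
complete parameter snapshot, the master seed, the derived per-replicate
seeds, collapse flags, and the artifact version.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from . import __version__
from .config import SimParams, params_to_dict
from .engine import SummaryTrajectory, Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "build_manifest",
    "write_manifest",
    "write_log",
]

AnyTrajectory = Union[Trajectory, SummaryTrajectory]


def write_trajectory(traj: AnyTrajectory | pd.DataFrame, destination: str | Path) -> Path:
    """Write a trajectory (single-run or replicate summary) as CSV.

    One row per generation for a single run; one row per generation and
    statistic (mean/sd) for a replicate summary.  Column order is stable.
    """
    df = traj if isinstance(traj, pd.DataFrame) else traj.to_dataframe()
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(destination, index=False)
    return destination


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV with exact float round-tripping."""
    return pd.read_csv(path, float_precision="round_trip")


def build_manifest(
    traj: AnyTrajectory,
    *,
    label: str = "run",
    extra: dict | None = None,
) -> dict:
    """Assemble the reproducibility manifest for a run or replicate summary."""
    manifest: dict = {
        "artifact": "armevo",
        "version": __version__,
        "label": label,
        "params": params_to_dict(traj.params),
    }
    if isinstance(traj, Trajectory):
        manifest.update(
            seed=traj.seed,
            start_generation=traj.stats[0].generation if traj.stats else None,
            end_generation=traj.stats[-1].generation if traj.stats else None,
            collapsed=traj.collapsed,
        )
    else:
        manifest.update(
            master_seed=traj.params.master_seed,
            replicate_seeds=list(traj.seeds),
            start_generation=int(traj.generation[0]) if len(traj.generation) else None,
            end_generation=int(traj.generation[-1]) if len(traj.generation) else None,
            collapsed=list(traj.collapsed),
        )
    if extra:
        manifest.update(extra)
    return manifest


def write_manifest(manifest: dict, destination: str | Path) -> Path:
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    destination.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return destination


def write_log(
    traj: AnyTrajectory,
    destination: str | Path,
    every: int = 100,
) -> Path:
    """Write a throttled per-generation text log (every ``every``-th generation)."""
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    if isinstance(traj, Trajectory):
        lines.append(f"single run, seed={traj.seed}, generations={len(traj.stats)}")
        for s in traj.stats:
            if s.generation % every == 0 or s.generation == 1:
                lines.append(
                    f"gen {s.generation}: mean_armament={s.mean_armament:.6g} "
                    f"mean_ratio={s.mean_ratio:.6g} fights={s.n_fights} "
                    f"default_wins={s.n_default_wins}"
                )
        if traj.collapsed:
            lines.append("run collapsed before completing all generations")
    else:
        lines.append(
            f"replicate summary, {len(traj.seeds)} replicates, "
            f"generations={len(traj.generation)}"
        )
        for i, g in enumerate(traj.generation):
            if g % every == 0 or g == 1:
                lines.append(
                    f"gen {int(g)}: mean_ratio={traj.mean_ratio_mean[i]:.6g} "
                    f"sd={traj.mean_ratio_sd[i]:.6g}"
                )
        if any(traj.collapsed):
            lines.append(f"collapsed replicates: {list(traj.collapsed)}")
    destination.write_text("\n".join(lines) + "\n")
    return destination
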