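"""Canonical plain-text storage for trajectories and ensembles.

One gzip-compressed columnar text file holds the sparse per-generation
species counts (``run_id, generation, species_id, count``) and a JSON
sidecar records the model parameters, seeds and run flags, so any stored
ensemble can be reloaded bit-identically.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Ensemble, ModelParams, Trajectory

__all__ = ["save_ensemble", "load_ensemble", "save_trajectory", "load_trajectory"]

_COLUMNS = ["run_id", "generation", "species_id", "count"]


def _traj_frame(traj: Trajectory, run_id: int) -> pd.DataFrame:
    gens, species = np.nonzero(traj.counts)
    return pd.DataFrame(
        {
            "run_id": run_id,
            "generation": gens,
            "species_id": species,
            "count": traj.counts[gens, species],
        }
    )


def save_ensemble(ensemble: Ensemble, path: str | Path) -> Path:
    """Write an ensemble to ``<path>`` (csv.gz) plus ``<path>.meta.json``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [_traj_frame(m, r) for r, m in enumerate(ensemble.members)]
    table = pd.concat(frames, ignore_index=True)
    with gzip.open(path, "wt", newline="") as fh:
        table.to_csv(fh, index=False)
    meta = {
        "params": {
            k: getattr(ensemble.params, k)
            for k in ("L", "theta", "p_kill", "p_mut", "k", "mu", "n0",
                      "n0_species")
        },
        "run_seeds": [m.params.seed for m in ensemble.members],
        "interaction_seeds": [m.interaction_seed for m in ensemble.members],
        "terminated_early": [bool(m.terminated_early) for m in ensemble.members],
        "n_generations": [int(m.n_generations) for m in ensemble.members],
        "meta": {k: v for k, v in ensemble.meta.items()},
    }
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=1))
    return path


def load_ensemble(path: str | Path) -> Ensemble:
    """Reload an ensemble written by :func:`save_ensemble`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    with gzip.open(path, "rt") as fh:
        table = pd.read_csv(fh)
    if list(table.columns) != _COLUMNS:
        raise ValueError(f"unexpected columns {list(table.columns)}")
    base = ModelParams(**meta["params"])
    M = base.n_species
    members = []
    for r, seed in enumerate(meta["run_seeds"]):
        sub = table[table.run_id == r]
        n_gen = meta["n_generations"][r]
        counts = np.zeros((n_gen + 1, M), dtype=np.int32)
        counts[sub.generation.to_numpy(), sub.species_id.to_numpy()] = (
            sub["count"].to_numpy()
        )
        members.append(
            Trajectory(
                params=base.replace(seed=seed),
                counts=counts,
                terminated_early=meta["terminated_early"][r],
                interaction_seed=meta["interaction_seeds"][r],
            )
        )
    return Ensemble(members=members, meta=meta.get("meta", {}))


def save_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Store a single run (an ensemble of one)."""
    return save_ensemble(Ensemble(members=[traj]), path)


def load_trajectory(path: str | Path) -> Trajectory:
    return load_ensemble(path).members[0]
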