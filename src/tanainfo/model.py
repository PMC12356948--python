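"""Domain types for the Tangled Nature (TaNa) co-evolution model.

Species are binary pangenomes of length ``L`` (integer ids in ``[0, 2**L)``).
A run tracks the per-species population count after every generation, where a
generation is ``N(t) / p_kill`` elementary birth/death timesteps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "InteractionMatrix",
    "EcosystemState",
    "Trajectory",
    "Ensemble",
    "ExtinctionError",
]


class ExtinctionError(RuntimeError):
    """Raised when the total population of the ecosystem reaches zero."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the Tangled Nature model.

    Attributes
    ----------
    L
        Pangenome length in bits; the species space has ``2**L`` members.
    theta
        Coupling probability: each directed off-diagonal interaction is
        permitted independently with this probability.
    p_kill
        Per-timestep probability that the uniformly chosen individual dies.
    p_mut
        Per-bit mutation probability applied to each offspring genome.
    k
        Dimensionless scaling of the interaction strength.
    mu
        Inverse carrying capacity; the fitness penalty per individual.
    n0
        Initial total population.
    n0_species
        Number of distinct species the initial population is spread over.
    seed
        Integer RNG seed for the run.
    """

    L: int = 10
    theta: float = 0.25
    p_kill: float = 0.2
    p_mut: float = 0.01
    k: float = 33.0
    mu: float = 1.0 / 143.0
    n0: int = 500
    n0_species: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        for name in ("theta", "p_kill", "p_mut"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if not 1 <= self.n0_species <= 2**self.L:
            raise ValueError("n0_species must be in [1, 2**L]")

    @property
    def n_species(self) -> int:
        return 2**self.L

    def replace(self, **kw) -> "ModelParams":
        from dataclasses import replace

        return replace(self, **kw)


@dataclass(frozen=True)
class InteractionMatrix:
    """Random interaction web ``J`` between all ``M = 2**L`` species.

    Off-diagonal entries are Uniform(-1, 1) where the coupling mask permits
    an interaction (probability ``theta`` per directed entry) and zero
    elsewhere; the diagonal is zero.  ``neutral_flag`` marks the control
    variant in which every permitted interaction has one constant weight.
    """

    weights: np.ndarray
    neutral_flag: bool = False

    def __post_init__(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if np.any(np.diagonal(w) != 0.0):
            raise ValueError("diagonal of the interaction matrix must be zero")
        if np.nanmax(np.abs(w)) > 1.0 + 1e-12:
            raise ValueError("interaction weights must lie in [-1, 1]")

    @property
    def n_species(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class EcosystemState:
    """Populations of all existing species at one generation."""

    populations: Mapping[int, int]
    generation: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.populations.values()):
            raise ValueError("species counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.populations.values()))

    def count(self, species: int) -> int:
        return int(self.populations.get(species, 0))


@dataclass
class Trajectory:
    """One TaNa run: per-generation species counts plus provenance.

    ``counts`` has shape ``(n_recorded, M)``; row ``g`` is the population
    vector after generation ``g`` (row 0 is the initial condition).
    """

    params: ModelParams
    counts: np.ndarray
    terminated_early: bool = False
    interaction_seed: int | None = None
    timesteps_per_generation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.counts.ndim != 2 or self.counts.shape[0] < 1:
            raise ValueError("counts must be a non-empty (generations, M) array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_generations(self) -> int:
        """Number of completed generations (excludes the initial row)."""
        return self.counts.shape[0] - 1

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1).astype(np.int64)

    def states(self) -> Iterator[EcosystemState]:
        for g in range(self.counts.shape[0]):
            row = self.counts[g]
            occ = np.nonzero(row)[0]
            yield EcosystemState(
                populations={int(s): int(row[s]) for s in occ}, generation=g
            )


@dataclass
class Ensemble:
    """Aligned trajectories of independent runs at identical parameters.

    Members share every ``ModelParams`` field except ``seed``.  ``horizon``
    is the common number of generations available across retained members.
    """

    members: list[Trajectory]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must contain at least one trajectory")
        ref = self.members[0].params.replace(seed=0)
        for m in self.members:
            if m.params.replace(seed=0) != ref:
                raise ValueError("ensemble members must share all parameters but seed")

    @property
    def params(self) -> ModelParams:
        return self.members[0].params

    @property
    def n_runs(self) -> int:
        return len(self.members)

    @property
    def horizon(self) -> int:
        return min(m.n_generations for m in self.members)

    def surviving(self) -> "Ensemble":
        """Members that did not go extinct (used for ensemble statistics)."""
        alive = [m for m in self.members if not m.terminated_early]
        if not alive:
            raise ExtinctionError("every ensemble member went extinct")
        return Ensemble(members=alive, meta=dict(self.meta))

    def counts_array(self, horizon: int | None = None) -> np.ndarray:
        """Stack member counts into an (n_runs, horizon+1, M) array."""
        h = self.horizon if horizon is None else min(horizon, self.horizon)
        return np.stack([m.counts[: h + 1] for m in self.members])
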