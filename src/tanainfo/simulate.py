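"""Tangled Nature model: interaction sampling, fitness, and run drivers.

The model follows the classic formulation: species ``i`` has fitness

    H_i(t) = (k / N(t)) * sum_j J_ij * n_j(t)  -  mu * N(t)

and reproduces with logistic probability ``p_off = 1 / (1 + exp(-H_i))``.
Each timestep first kills a uniformly chosen individual with probability
``p_kill`` and then lets a uniformly chosen individual reproduce.  A
successful reproduction replaces the parent with two daughters whose
genomes mutate independently, per bit, with probability ``p_mut`` — the
rule that places the error threshold at
``p_off (2 (1 - p_mut)^L - 1) = p_kill``, i.e. near ``p_mut = 0.05`` at
the standard parameters.  A generation is ``round(N(t)/p_kill)``
timesteps, the average number needed to kill every currently living
individual.
"""

from __future__ import annotations

import math

import numpy as np

from ._kernel import simulate_counts
from .model import (
    EcosystemState,
    Ensemble,
    ExtinctionError,
    InteractionMatrix,
    ModelParams,
    Trajectory,
)

__all__ = [
    "sample_interactions",
    "fitness",
    "reproduction_prob",
    "timestep",
    "initial_state",
    "run",
    "run_ensemble",
]

DEFAULT_NEUTRAL_WEIGHT = 0.1


def sample_interactions(
    params: ModelParams,
    rng: np.random.Generator,
    *,
    pairwise: bool = False,
    neutral: bool = False,
    neutral_weight: float = DEFAULT_NEUTRAL_WEIGHT,
) -> InteractionMatrix:
    """Draw the random interaction web ``J``.

    Each directed off-diagonal entry is permitted independently with
    probability ``theta`` and, if permitted, drawn Uniform(-1, 1).  With
    ``pairwise=True`` the coupling mask is symmetric (both directions of a
    pair are permitted or absent together, weights still independent).  With
    ``neutral=True`` every permitted entry is replaced by the single constant
    ``neutral_weight`` (the neutral control in which no interaction structure
    can be selected).
    """
    M = params.n_species
    if pairwise:
        upper = rng.random((M, M)) < params.theta
        mask = np.triu(upper, k=1)
        mask = mask | mask.T
    else:
        mask = rng.random((M, M)) < params.theta
    np.fill_diagonal(mask, False)
    weights = np.where(mask, rng.uniform(-1.0, 1.0, size=(M, M)), 0.0)
    if neutral:
        weights = np.where(mask, float(neutral_weight), 0.0)
    return InteractionMatrix(weights=weights, neutral_flag=neutral)


def fitness(
    i: int, state: EcosystemState, J: InteractionMatrix, params: ModelParams
) -> float:
    """Fitness H_i of species ``i`` in ``state`` under interaction web ``J``."""
    N = state.total
    if N <= 0:
        raise ExtinctionError("fitness is undefined for an empty ecosystem")
    acc = 0.0
    row = J.weights[i]
    for j, n_j in state.populations.items():
        acc += row[j] * n_j
    return params.k * acc / N - params.mu * N


def reproduction_prob(H: float) -> float:
    """Logistic map from fitness to offspring probability, in (0, 1)."""
    if not math.isfinite(H):
        raise ValueError("fitness must be finite")
    if H >= 0:
        return 1.0 / (1.0 + math.exp(-H))
    e = math.exp(H)
    return e / (1.0 + e)


def _state_arrays(state: EcosystemState) -> tuple[np.ndarray, np.ndarray]:
    ids = np.fromiter(state.populations.keys(), dtype=np.int64)
    counts = np.fromiter(state.populations.values(), dtype=np.int64)
    keep = counts > 0
    return ids[keep], counts[keep]


def _pick_individual(ids, counts, total, rng) -> int:
    """Uniform draw over individuals = population-weighted draw over species."""
    u = int(rng.integers(total))
    acc = 0
    for sid, c in zip(ids, counts):
        acc += int(c)
        if u < acc:
            return int(sid)
    return int(ids[-1])  # unreachable for consistent inputs


def timestep(
    state: EcosystemState,
    J: InteractionMatrix,
    params: ModelParams,
    rng,
) -> EcosystemState:
    """One elementary kill/birth update (pure-Python reference path).

    ``rng`` needs ``random()`` for probability draws and ``integers(n)`` for
    uniform index draws, so a stub with scripted values can drive the branch
    structure deterministically in tests.  A successful reproduction removes
    the parent and adds two independently mutated daughters (net +1).
    Raises :class:`ExtinctionError` when the annihilation step empties the
    ecosystem.
    """
    pops = dict(state.populations)
    ids, counts = _state_arrays(state)
    total = int(counts.sum())
    if total <= 0:
        raise ExtinctionError("timestep requires a non-empty ecosystem")

    if rng.random() < params.p_kill:
        victim = _pick_individual(ids, counts, total, rng)
        pops[victim] -= 1
        if pops[victim] == 0:
            del pops[victim]
        total -= 1
        if total == 0:
            raise ExtinctionError(
                f"population went extinct at generation {state.generation}"
            )
        ids = np.fromiter(pops.keys(), dtype=np.int64)
        counts = np.fromiter(pops.values(), dtype=np.int64)

    parent = _pick_individual(ids, counts, total, rng)
    interim = EcosystemState(populations=pops, generation=state.generation)
    H = fitness(parent, interim, J, params)
    if rng.random() < reproduction_prob(H):
        pops[parent] -= 1
        if pops[parent] == 0:
            del pops[parent]
        for _ in range(2):
            child = parent
            if params.p_mut > 0.0:
                for b in range(params.L):
                    if rng.random() < params.p_mut:
                        child ^= 1 << b
            pops[child] = pops.get(child, 0) + 1
    return EcosystemState(populations=pops, generation=state.generation)


def initial_state(params: ModelParams, rng: np.random.Generator) -> EcosystemState:
    """``n0`` individuals spread uniformly over ``n0_species`` random species."""
    species = rng.choice(params.n_species, size=params.n0_species, replace=False)
    base, extra = divmod(params.n0, params.n0_species)
    pops = {}
    for idx, s in enumerate(sorted(int(x) for x in species)):
        pops[s] = base + (1 if idx < extra else 0)
    return EcosystemState(populations={s: c for s, c in pops.items() if c > 0},
                          generation=0)


def generation_length(N: int, p_kill: float) -> int:
    """Timesteps per generation: round(N / p_kill), floor 1."""
    return max(1, int(round(N / p_kill)))


def run(
    params: ModelParams,
    n_generations: int,
    *,
    J: InteractionMatrix | None = None,
    interaction_seed: int | None = None,
    neutral: bool = False,
    pairwise: bool = False,
    engine: str = "numba",
) -> Trajectory:
    """Simulate one trajectory of ``n_generations`` generations.

    The interaction matrix is resampled from ``interaction_seed`` (default:
    derived from ``params.seed``) unless an explicit ``J`` is supplied.  A run
    whose population hits zero stops early with ``terminated_early`` set.  The
    compiled engine is the production path; ``engine="python"`` drives the
    reference :func:`timestep` and is only meant for short validation runs.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    ss = np.random.SeedSequence(params.seed)
    init_ss, dyn_ss, j_ss = ss.spawn(3)
    if J is None:
        if interaction_seed is None:
            interaction_seed = int(j_ss.generate_state(1)[0] % (2**31))
        J = sample_interactions(
            params,
            np.random.default_rng(interaction_seed),
            pairwise=pairwise,
            neutral=neutral,
        )
    state0 = initial_state(params, np.random.default_rng(init_ss))
    ids = np.fromiter(state0.populations.keys(), dtype=np.int64)
    cnts = np.fromiter(state0.populations.values(), dtype=np.int64)

    if engine == "numba":
        dyn_seed = int(dyn_ss.generate_state(1)[0] % (2**31))
        counts, tsteps, extinct = simulate_counts(
            J.weights,
            params.L,
            params.p_kill,
            params.p_mut,
            params.k,
            params.mu,
            ids,
            cnts,
            n_generations,
            dyn_seed,
        )
        # counts stay far below the int16 range; halve ensemble memory
        counts = counts.astype(np.int16)
    elif engine == "python":
        rng = np.random.default_rng(dyn_ss)
        counts = np.zeros((n_generations + 1, params.n_species), np.int32)
        counts[0, ids] = cnts
        tsteps_list = []
        state = state0
        extinct = False
        g = 0
        for g in range(1, n_generations + 1):
            T = generation_length(state.total, params.p_kill)
            tsteps_list.append(T)
            try:
                for _ in range(T):
                    state = timestep(state, J, params, rng)
            except ExtinctionError:
                extinct = True
            row = np.zeros(params.n_species, np.int32)
            for s, c in state.populations.items():
                row[s] = c
            if extinct:
                row[:] = 0
            counts[g] = row
            if extinct:
                break
        counts = counts[: g + 1]
        tsteps = np.asarray(tsteps_list, dtype=np.int64)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    return Trajectory(
        params=params,
        counts=counts,
        terminated_early=bool(extinct),
        interaction_seed=interaction_seed,
        timesteps_per_generation=tsteps,
    )


def run_ensemble(
    params: ModelParams,
    n_runs: int,
    n_generations: int,
    master_seed: int,
    *,
    share_interactions: bool = False,
    neutral: bool = False,
    pairwise: bool = False,
) -> Ensemble:
    """Independent runs with per-run seeds derived from ``master_seed``.

    By default every member resamples its own interaction matrix and initial
    condition ("different initial conditions"); ``share_interactions=True``
    reuses one web across the ensemble.  Extinct members are retained and
    flagged; :meth:`Ensemble.surviving` filters them for statistics.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    run_seeds = [int(s % (2**31)) for s in ss.generate_state(n_runs + 1)]
    shared_J = None
    if share_interactions:
        shared_J = sample_interactions(
            params,
            np.random.default_rng(run_seeds[-1]),
            pairwise=pairwise,
            neutral=neutral,
        )
    members = []
    for r in range(n_runs):
        p_r = params.replace(seed=run_seeds[r])
        members.append(
            run(
                p_r,
                n_generations,
                J=shared_J,
                neutral=neutral,
                pairwise=pairwise,
            )
        )
    meta = {
        "master_seed": int(master_seed),
        "run_seeds": run_seeds[:n_runs],
        "share_interactions": bool(share_interactions),
        "neutral": bool(neutral),
        "pairwise": bool(pairwise),
        "n_extinct": int(sum(m.terminated_early for m in members)),
    }
    return Ensemble(members=members, meta=meta)
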