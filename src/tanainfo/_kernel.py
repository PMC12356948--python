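"""Compiled inner loop of the Tangled Nature simulator.

The kernel keeps an explicit array of individuals (genome ids) so that both
the annihilation and the reproduction draw are uniform over *individuals* in
O(1), and a compact list of occupied species so the fitness sum only visits
species with non-zero population.
"""

import numpy as np
from numba import njit

__all__ = ["simulate_counts"]


@njit(cache=True)
def _grow(arr):
    out = np.empty(arr.size * 2, np.int32)
    out[: arr.size] = arr
    return out


@njit(cache=True)
def simulate_counts(
    J,
    L,
    p_kill,
    p_mut,
    k,
    mu,
    init_ids,
    init_counts,
    n_gens,
    seed,
):
    """Run one trajectory; returns (counts, timesteps_per_gen, extinct).

    counts has shape (gens_recorded + 1, M) with row 0 the initial state.
    A generation is round(N/p_kill) timesteps (minimum 1), N taken at the
    generation's start.  Each timestep: kill a uniform individual with
    probability p_kill, then (if anyone is left) a uniform individual
    reproduces with probability 1/(1+exp(-H)).  Reproduction replaces the
    parent with two daughters; each daughter bit flips independently with
    probability p_mut.  This two-daughter rule sets the error threshold at
    p_off*(2*(1-p_mut)**L - 1) = p_kill, i.e. p_mut ~ 0.05 at standard
    parameters.
    """
    M = J.shape[0]
    np.random.seed(seed)

    pop = np.zeros(M, np.int64)
    cap = 1 << 14
    ind = np.empty(cap, np.int32)
    N = 0
    for q in range(init_ids.size):
        s = init_ids[q]
        c = init_counts[q]
        pop[s] += c
        for _ in range(c):
            if N >= cap:
                ind = _grow(ind)
                cap = ind.size
            ind[N] = np.int32(s)
            N += 1

    occ = np.empty(M, np.int32)
    pos = np.full(M, -1, np.int32)
    n_occ = 0
    for s in range(M):
        if pop[s] > 0:
            occ[n_occ] = np.int32(s)
            pos[s] = n_occ
            n_occ += 1

    out = np.zeros((n_gens + 1, M), np.int32)
    tsteps = np.zeros(n_gens, np.int64)
    for s in range(M):
        out[0, s] = np.int32(pop[s])

    p_nomut = (1.0 - p_mut) ** L
    full_mask = (1 << L) - 1
    extinct = False
    gens_done = 0

    for g in range(n_gens):
        T = int(np.rint(N / p_kill))
        if T < 1:
            T = 1
        tsteps[g] = T
        for _ in range(T):
            # annihilation
            if np.random.random() < p_kill:
                j = np.random.randint(0, N)
                s = ind[j]
                N -= 1
                ind[j] = ind[N]
                pop[s] -= 1
                if pop[s] == 0:
                    pz = pos[s]
                    n_occ -= 1
                    last = occ[n_occ]
                    occ[pz] = last
                    pos[last] = pz
                    pos[s] = -1
                if N == 0:
                    extinct = True
                    break
            # reproduction
            j = np.random.randint(0, N)
            si = ind[j]
            acc = 0.0
            for q in range(n_occ):
                sj = occ[q]
                acc += J[si, sj] * pop[sj]
            H = k * acc / N - mu * N
            if np.random.random() < 1.0 / (1.0 + np.exp(-H)):
                # parent replaced by two daughters, each mutated per bit
                N -= 1
                ind[j] = ind[N]
                pop[si] -= 1
                if pop[si] == 0:
                    pz = pos[si]
                    n_occ -= 1
                    last = occ[n_occ]
                    occ[pz] = last
                    pos[last] = pz
                    pos[si] = -1
                for _d in range(2):
                    child = si
                    if p_mut > 0.0 and np.random.random() >= p_nomut:
                        if p_mut >= 1.0:
                            child = si ^ full_mask
                        else:
                            # conditioned on >=1 flip: reject all-zero masks
                            mask = 0
                            while mask == 0:
                                mask = 0
                                for b in range(L):
                                    if np.random.random() < p_mut:
                                        mask |= 1 << b
                            child = si ^ mask
                    if N >= cap:
                        ind = _grow(ind)
                        cap = ind.size
                    ind[N] = np.int32(child)
                    N += 1
                    pop[child] += 1
                    if pop[child] == 1:
                        occ[n_occ] = np.int32(child)
                        pos[child] = n_occ
                        n_occ += 1
        for s in range(M):
            out[g + 1, s] = np.int32(pop[s])
        gens_done = g + 1
        if extinct:
            break

    return out[: gens_done + 1], tsteps[:gens_done], extinct
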