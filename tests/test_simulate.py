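"""Simulator contracts: interaction sampling, fitness, timestep, run drivers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tanainfo import (
    EcosystemState,
    ExtinctionError,
    ModelParams,
    fitness,
    reproduction_prob,
    run,
    run_ensemble,
    sample_interactions,
    timestep,
)
from tests.conftest import ScriptedRNG


# --- interaction sampling ---------------------------------------------------


def test_theta_zero_gives_empty_web():
    J = sample_interactions(ModelParams(L=5, theta=0.0), np.random.default_rng(0))
    assert not J.weights.any()


def test_theta_one_gives_full_offdiagonal_web():
    J = sample_interactions(ModelParams(L=5, theta=1.0), np.random.default_rng(0))
    w = J.weights
    off = ~np.eye(w.shape[0], dtype=bool)
    assert np.all(w[off] != 0.0)
    assert np.all(np.abs(w[off]) <= 1.0)
    assert np.all(np.diagonal(w) == 0.0)


def test_theta_quarter_occupancy_within_binomial_interval():
    # fraction of permitted off-diagonal entries at M=1024: binomial oracle
    params = ModelParams(theta=0.25)
    J = sample_interactions(params, np.random.default_rng(42))
    M = params.n_species
    n_offdiag = M * (M - 1)
    k = int(np.count_nonzero(J.weights))
    lo, hi = stats.binom.interval(0.99, n_offdiag, 0.25)
    assert lo <= k <= hi


def test_neutral_web_has_one_constant_weight():
    J = sample_interactions(
        ModelParams(L=6, theta=0.3), np.random.default_rng(1), neutral=True
    )
    vals = np.unique(J.weights[J.weights != 0.0])
    assert J.neutral_flag and len(vals) == 1


def test_pairwise_mask_is_symmetric():
    J = sample_interactions(
        ModelParams(L=6, theta=0.3), np.random.default_rng(2), pairwise=True
    )
    mask = J.weights != 0.0
    assert np.array_equal(mask, mask.T)


# --- fitness and reproduction ----------------------------------------------


def _state(pops, gen=0):
    return EcosystemState(populations=pops, generation=gen)


def test_fitness_interaction_free_equals_minus_mu_n():
    # all J = 0, N = 143, mu = 1/143  ->  H = -1
    params = ModelParams(L=4)
    J = sample_interactions(params.replace(L=4, theta=0.0), np.random.default_rng(0))
    H = fitness(2, _state({1: 143}), J, params.replace(L=4))
    assert H == pytest.approx(-1.0)


def test_fitness_single_neighbor_hand_value():
    # one neighbor with J_ij = 1, n_j = N = 100, k = 33, mu = 1/143
    import tanainfo.model as m

    w = np.zeros((16, 16))
    w[3, 7] = 1.0
    J = m.InteractionMatrix(weights=w)
    params = ModelParams(L=4)
    H = fitness(3, _state({7: 100}), J, params)
    assert H == pytest.approx(33.0 - 100.0 / 143.0, abs=1e-9)
    assert H == pytest.approx(32.3007, abs=1e-4)


def test_fitness_zero_mu_and_no_interactions_is_zero():
    params = ModelParams(L=4, mu=1e-12)
    J = sample_interactions(params.replace(theta=0.0), np.random.default_rng(0))
    assert fitness(0, _state({5: 50}), J, params) == pytest.approx(0.0, abs=1e-9)


def test_fitness_undefined_for_empty_ecosystem():
    params = ModelParams(L=4)
    J = sample_interactions(params.replace(theta=0.0), np.random.default_rng(0))
    with pytest.raises(ExtinctionError):
        fitness(0, _state({}), J, params)


def test_reproduction_prob_examples():
    assert reproduction_prob(0.0) == pytest.approx(0.5)
    assert reproduction_prob(-1.0) == pytest.approx(1.0 / (1.0 + math.e), abs=1e-9)
    assert reproduction_prob(800.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        reproduction_prob(float("nan"))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(-30, 30), st.floats(-30, 30))
def test_reproduction_prob_monotone_and_bounded(a, b):
    pa, pb = reproduction_prob(a), reproduction_prob(b)
    assert 0.0 < pa < 1.0
    if a < b:
        assert pa <= pb


# --- timestep (scripted randomness) ----------------------------------------


def _two_species_setup(p_mut=0.0):
    params = ModelParams(L=4, p_kill=0.2, p_mut=p_mut, n0=10, n0_species=2)
    J = sample_interactions(params.replace(theta=0.0), np.random.default_rng(0))
    state = _state({3: 6, 9: 4})
    return params, J, state


def test_timestep_birth_without_mutation_adds_one_to_parent_species():
    params, J, state = _two_species_setup(p_mut=0.0)
    # kill draw fails (0.9 >= p_kill); parent is individual 0 (species 3);
    # birth succeeds (0.0 < p_off)
    rng = ScriptedRNG(uniforms=[0.9, 0.0], integer_draws=[0])
    new = timestep(state, J, params, rng)
    assert new.total == state.total + 1
    assert new.count(3) == state.count(3) + 1


def test_timestep_kill_without_birth_removes_one():
    params, J, state = _two_species_setup()
    # kill succeeds (0.0 < p_kill) on individual 0; birth fails (0.99 >= p_off)
    rng = ScriptedRNG(uniforms=[0.0, 0.99], integer_draws=[0, 0])
    new = timestep(state, J, params, rng)
    assert new.total == state.total - 1
    assert new.count(3) == state.count(3) - 1


def test_timestep_full_mutation_creates_bitwise_complement():
    params, J, state = _two_species_setup(p_mut=1.0)
    # no kill; parent species 3; birth succeeds; every bit of both daughters
    # flips (all mutation draws < 1)
    rng = ScriptedRNG(
        uniforms=[0.9, 0.0] + [0.0] * (2 * params.L), integer_draws=[0]
    )
    new = timestep(state, J, params, rng)
    complement = 3 ^ (2**params.L - 1)
    assert new.count(complement) == 2
    assert new.count(3) == state.count(3) - 1
    assert new.total == state.total + 1


def test_timestep_signals_extinction():
    params = ModelParams(L=4, p_kill=1.0, n0=1, n0_species=1)
    J = sample_interactions(params.replace(theta=0.0), np.random.default_rng(0))
    with pytest.raises(ExtinctionError):
        timestep(_state({5: 1}), J, params, ScriptedRNG([0.0], [0]))


def test_timestep_population_change_bounded_by_one():
    params = ModelParams(L=6, p_mut=0.05, n0=60, n0_species=3)
    J = sample_interactions(params, np.random.default_rng(3))
    rng = np.random.default_rng(4)
    state = _state({1: 20, 2: 20, 40: 20})
    for _ in range(400):
        new = timestep(state, J, params, rng)
        assert abs(new.total - state.total) <= 1
        assert all(c >= 0 for c in new.populations.values())
        state = new


def test_forced_death_reaches_extinction_within_n0_steps():
    # p_kill = 1 and births scripted to fail: population of n0 must vanish
    # within n0 timesteps
    params = ModelParams(L=4, p_kill=1.0, p_mut=0.0, n0=5, n0_species=1)
    J = sample_interactions(params.replace(theta=0.0), np.random.default_rng(0))
    state = _state({7: 5})
    steps = 0
    with pytest.raises(ExtinctionError):
        for _ in range(params.n0):
            steps += 1
            state = timestep(
                state, J, params, ScriptedRNG([0.0, 0.99], [0, 0])
            )
    assert steps <= params.n0


# --- run / run_ensemble -----------------------------------------------------


def test_generation_length_rule():
    traj = run(ModelParams(p_mut=0.01, seed=5), 30)
    # N(t)/p_kill timesteps per generation, N at the generation's start
    expect = np.maximum(1, np.rint(traj.totals[:-1] / 0.2)).astype(int)
    assert np.array_equal(traj.timesteps_per_generation, expect)
    assert traj.timesteps_per_generation[0] == 2500  # N=500, p_kill=0.2


def test_no_mutation_never_creates_new_species():
    traj = run(ModelParams(p_mut=0.0, seed=11, n0_species=5), 150)
    initial = set(np.nonzero(traj.counts[0])[0])
    occupied_ever = set(np.nonzero(traj.counts.sum(axis=0))[0])
    assert occupied_ever <= initial


def test_seeded_run_is_bit_reproducible():
    p = ModelParams(p_mut=0.02, seed=123)
    a, b = run(p, 60), run(p, 60)
    assert np.array_equal(a.counts, b.counts)
    assert a.interaction_seed == b.interaction_seed


def test_different_seeds_differ():
    a = run(ModelParams(p_mut=0.02, seed=1), 40)
    b = run(ModelParams(p_mut=0.02, seed=2), 40)
    assert not np.array_equal(a.counts, b.counts)


def test_python_and_numba_engines_agree_statistically():
    # same model, independent randomness: stationary population within 25%
    p = ModelParams(L=6, mu=1.0 / 30.0, n0=100, n0_species=4, p_mut=0.01)
    mean_n = {}
    for engine in ("numba", "python"):
        totals = []
        for seed in (1, 2, 3):
            traj = run(p.replace(seed=seed), 120, engine=engine)
            totals.append(traj.totals[40:].mean())
        mean_n[engine] = np.mean(totals)
    assert mean_n["python"] == pytest.approx(mean_n["numba"], rel=0.25)


def test_ensemble_seeded_determinism_and_horizon(small_ensemble):
    p = ModelParams(p_mut=0.03)
    e1 = run_ensemble(p, 3, 50, master_seed=99)
    e2 = run_ensemble(p, 3, 50, master_seed=99)
    for a, b in zip(e1.members, e2.members):
        assert np.array_equal(a.counts, b.counts)
    assert not np.array_equal(e1.members[0].counts, e1.members[1].counts)
    assert e1.horizon == 50
    assert e1.meta["run_seeds"] == e2.meta["run_seeds"]
    assert small_ensemble.horizon == 120


def test_shared_interaction_web_mode():
    p = ModelParams(p_mut=0.02)
    ens = run_ensemble(p, 3, 30, master_seed=5, share_interactions=True)
    assert ens.meta["share_interactions"]
    assert all(m.interaction_seed is None for m in ens.members)
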