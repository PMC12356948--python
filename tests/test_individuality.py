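"""Rank alignment, subset enumeration, and the individuality measures."""

import itertools

import numpy as np
import pytest

from tanainfo.fixtures import VarProcessSpec, analytic_info, planted_block_ensemble, simulate_var
from tanainfo.gaussian_info import EstimationError, gaussian_mi
from tanainfo.individuality import (
    RankAligned,
    SubsetSpec,
    colonial_individuality,
    enumerate_subsets,
    environment_determined_individuality,
    environment_pop,
    individuality_score,
    organismal_individuality,
    rank_align,
    scale_sweep,
)
from tanainfo.infodyn import transfer_entropy


def _aligned_from(data):
    return RankAligned(
        series=data,
        totals=data.sum(axis=2),
        rank_masses=np.sort(data.mean(axis=(0, 1)))[::-1],
        window=(0, data.shape[1] - 1),
    )


# --- rank alignment ---------------------------------------------------------


def test_rank_align_sorting_contract():
    counts = np.zeros((1, 5, 8), dtype=int)
    counts[0, :, 2] = 10
    counts[0, :, 5] = 5
    counts[0, :, 7] = 1
    al = rank_align(counts, n_ranks=3)
    assert np.all(al.series[0, :, 0] == 10)
    assert np.all(al.series[0, :, 1] == 5)
    assert np.all(al.series[0, :, 2] == 1)
    assert np.array_equal(al.totals[0], np.full(5, 16))


def test_rank_align_is_label_invariant():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 40, size=(3, 12, 10))
    perm = rng.permutation(10)
    al1 = rank_align(counts, n_ranks=6)
    al2 = rank_align(counts[:, :, perm], n_ranks=6)
    # identical sorted populations -> identical rank-aligned arrays
    np.testing.assert_array_equal(al1.series, al2.series)
    np.testing.assert_allclose(al1.rank_masses, al2.rank_masses)


def test_rank_align_breaks_ties_by_species_id():
    counts = np.zeros((1, 4, 6), dtype=int)
    counts[0, :, 4] = 7
    counts[0, :, 1] = 7
    al = rank_align(counts, n_ranks=2)
    # equal time-averaged populations: lower species id takes rank 1
    assert np.all(al.series[0, :, 0] == 7) and np.all(al.series[0, :, 1] == 7)
    al_again = rank_align(counts, n_ranks=2)
    np.testing.assert_array_equal(al.series, al_again.series)


def test_rank_align_rejects_empty_window():
    counts = np.zeros((2, 6, 4), dtype=int)
    counts[0, :, 1] = 3  # run 1 stays empty
    with pytest.raises(ValueError):
        rank_align(counts, n_ranks=2)


# --- subset enumeration -----------------------------------------------------


def test_singleton_subsets_in_rank_order():
    out = enumerate_subsets(1, 3, np.array([9.0, 4.0, 2.0, 1.0]))
    assert [s.rank_positions for s in out] == [(1,), (2,), (3,)]


def test_pair_subsets_masses_10_5_1():
    out = enumerate_subsets(2, 10, np.array([10.0, 5.0, 1.0]))
    assert [s.rank_positions for s in out] == [(1, 2), (1, 3), (2, 3)]
    assert [s.total_rank_mass for s in out] == [15.0, 11.0, 6.0]


def test_enumeration_matches_bruteforce_ordering():
    masses = np.array([12.0, 8.0, 5.0, 3.0, 1.5, 0.5])
    for K in (2, 3, 4):
        got = [set(s.rank_positions) for s in enumerate_subsets(K, 100, masses)]
        brute = sorted(
            itertools.combinations(range(1, 7), K),
            key=lambda c: -sum(masses[i - 1] for i in c),
        )
        assert len(got) == len(brute)
        got_masses = [sum(masses[i - 1] for i in s) for s in got]
        assert got_masses == sorted(got_masses, reverse=True)
        assert {frozenset(s) for s in got} == {frozenset(s) for s in brute}
        assert got[0] == set(range(1, K + 1))


def test_enumeration_limit_and_errors():
    masses = np.array([3.0, 2.0, 1.0])
    assert len(enumerate_subsets(2, 2, masses)) == 2
    with pytest.raises(ValueError):
        enumerate_subsets(4, 5, masses)
    with pytest.raises(ValueError):
        SubsetSpec(rank_positions=(1, 1), total_rank_mass=2.0)


# --- environment ------------------------------------------------------------


def test_environment_population_examples():
    assert environment_pop(475, 100) == 375.0
    assert environment_pop(50, 50) == 0.0
    assert environment_pop(50, np.zeros(0)) == 50.0
    with pytest.raises(ValueError):
        environment_pop(10, 11)


# --- individuality measures -------------------------------------------------


def test_independent_future_has_no_organismal_individuality():
    rng = np.random.default_rng(1)
    S = rng.standard_normal((800, 10, 2))
    res = organismal_individuality(S)
    assert res.value < 0.02
    assert res.measure == "A*"


def test_scale_one_organismal_equals_plain_lag1_mi():
    spec = VarProcessSpec(coeffs=[[0.8]], noise_cov=[[1.0]],
                          n_ensemble=600, horizon=6, seed=2)
    X = simulate_var(spec)
    res = organismal_individuality(X[:, :, 0])
    manual = np.mean(
        [gaussian_mi(X[:, t, 0], X[:, t + 1, 0]) for t in range(5)]
    )
    assert res.scale == 1
    assert res.value == pytest.approx(manual, abs=1e-9)


def test_var_block_organismal_matches_analytic():
    _, spec = planted_block_ensemble(K0=3, coupling=0.8, n_ensemble=2000,
                                     horizon=30, seed=3)
    X = simulate_var(spec)
    res = organismal_individuality(X[:, :, :3])
    expect = analytic_info(spec, "mi_lag1", subset=(0, 1, 2))
    assert res.value == pytest.approx(expect, rel=0.1)


def test_colonial_with_independent_environment_equals_a_star():
    spec = VarProcessSpec(coeffs=[[0.7]], noise_cov=[[1.0]],
                          n_ensemble=3000, horizon=10, seed=4)
    X = simulate_var(spec)
    E = np.random.default_rng(5).standard_normal(X.shape[:2])
    a_star = organismal_individuality(X[:, :, 0]).value
    a = colonial_individuality(X[:, :, 0], E).value
    assert a == pytest.approx(a_star, abs=0.02)


def test_colonial_vanishes_when_environment_explains_the_group():
    rng = np.random.default_rng(6)
    E = simulate_var(
        VarProcessSpec(coeffs=[[0.9]], noise_cov=[[1.0]],
                       n_ensemble=3000, horizon=10, seed=7)
    )[:, :, 0]
    S = E + 1e-5 * rng.standard_normal(E.shape)
    assert colonial_individuality(S, E).value < 0.02


def test_env_det_equals_transfer_entropy_on_identical_inputs():
    A = np.array([[0.6, 0.4], [0.0, 0.7]])  # component 1 drives component 0
    spec = VarProcessSpec(coeffs=A, noise_cov=np.eye(2),
                          n_ensemble=2000, horizon=12, seed=8)
    X = simulate_var(spec)
    S, E = X[:, :, 0], X[:, :, 1]
    nc = environment_determined_individuality(S, E)
    te = transfer_entropy(E, S)
    assert nc.value == pytest.approx(te.value, abs=1e-9)
    expect = analytic_info(spec, "env_det", subset=(0,), env=1)
    assert nc.value == pytest.approx(expect, rel=0.15, abs=0.01)


def test_individuality_score_algebra():
    assert individuality_score(1.2, 1) == 1.2
    assert individuality_score(0.0, 7) == 0.0
    assert individuality_score(1.0, 4) == 2 * individuality_score(1.0, 8)
    with pytest.raises(ValueError):
        individuality_score(1.0, 0)


# --- scale sweep ------------------------------------------------------------


def test_scale_sweep_pure_noise_scores_near_zero_and_tie_rule():
    rng = np.random.default_rng(9)
    data = rng.standard_normal((1500, 25, 8)) * np.linspace(4, 1, 8) + 50
    al = _aligned_from(data)
    tab, best = scale_sweep(al, k_range=range(1, 5), subset_limit=5,
                            tie_tol=0.02)
    assert (tab.score.dropna() < 0.05).all()
    assert best == 1  # ties (all ~0) resolve toward the smallest scale


def test_scale_sweep_recovers_planted_block():
    data, _ = planted_block_ensemble(K0=3, n_ensemble=400, horizon=60, seed=10)
    al = _aligned_from(data)
    tab, best = scale_sweep(al, k_range=range(1, 7), subset_limit=1)
    assert best == 3
    assert tab.loc[tab.scale == 3, "score"].iloc[0] > tab.loc[
        tab.scale == 1, "score"
    ].iloc[0]


def test_scale_sweep_surfaces_refusals():
    rng = np.random.default_rng(11)
    data = rng.standard_normal((40, 10, 8)) + 30
    al = _aligned_from(data)
    tab, best = scale_sweep(al, k_range=range(1, 7), subset_limit=3,
                            min_ratio=10.0)
    refused = tab[tab.status != "ok"]
    assert not refused.empty  # 2K > 40/10 for the larger scales
    assert refused.score.isna().all()
    assert best is not None
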