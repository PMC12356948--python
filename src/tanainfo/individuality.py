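"""Information individuality of species groups across scales.

A group of K species, represented by the joint population vector
S(t) = (n_1(t), ..., n_K(t)), is scored by how well it predicts its own
future across the ensemble:

    organismal individuality           A* = I(S(t); S(t+1))
    colonial individuality             A  = I(S(t); S(t+1) | E(t))
    environment-determined             nC = I(E(t); S(t+1) | S(t))

with environment population E(t) = N(t) - sum_i n_i(t).  The normalized
individuality score A*/K compensates for the dimension-driven growth of
multivariate MI; the *optimal scale* at a mutation rate is the K that
maximizes the mean normalized score over sampled groups.

Species identities differ between runs (each run evolves its own community
under its own interaction web), so groups are defined over *rank positions*:
within each run species are ranked by time-averaged population, and
rank r becomes a cross-ensemble random variable.  Groups of ranks are
enumerated in decreasing total rank mass, starting from the K most populous
ranks, exactly as a rank-ordered subset scan.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaussian_info import (
    EstimationError,
    InfoResult,
    MIN_ENSEMBLE_RATIO,
    check_ensemble_size,
    cmi_from_cov,
    lagged_cov_stack,
    mi_from_cov,
)
from .model import Ensemble

__all__ = [
    "SubsetSpec",
    "RankAligned",
    "rank_align",
    "enumerate_subsets",
    "environment_pop",
    "organismal_individuality",
    "colonial_individuality",
    "environment_determined_individuality",
    "individuality_score",
    "scale_sweep",
]


@dataclass(frozen=True)
class SubsetSpec:
    """A group of K rank positions (1-based), ordered by total rank mass."""

    rank_positions: tuple[int, ...]
    total_rank_mass: float

    def __post_init__(self):
        if len(set(self.rank_positions)) != len(self.rank_positions):
            raise ValueError("rank positions must be distinct")
        if any(r < 1 for r in self.rank_positions):
            raise ValueError("rank positions are 1-based")

    @property
    def K(self) -> int:
        return len(self.rank_positions)


@dataclass
class RankAligned:
    """Rank-aligned ensemble series.

    ``series`` has shape (n_runs, T, n_ranks): entry [e, t, r] is the
    population, at generation ``t`` of the window, of the species holding
    rank ``r+1`` (by time-averaged population) in run ``e``.  ``totals`` is
    N(t) per run, ``rank_masses`` the ensemble-mean time-averaged population
    per rank.
    """

    series: np.ndarray
    totals: np.ndarray
    rank_masses: np.ndarray
    window: tuple[int, int]

    @property
    def n_runs(self) -> int:
        return self.series.shape[0]

    @property
    def n_ranks(self) -> int:
        return self.series.shape[2]


def rank_align(
    ensemble: Ensemble | np.ndarray,
    window: tuple[int, int] | None = None,
    n_ranks: int = 16,
) -> RankAligned:
    """Align species across runs by within-run population rank.

    Within each run, species are ranked by their time-averaged population
    over the window (ties broken by ascending species id); rank ``r`` then
    indexes a comparable variable across runs.  Permuting species labels
    within runs leaves the result unchanged.
    """
    if isinstance(ensemble, Ensemble):
        counts = ensemble.surviving().counts_array()
    else:
        counts = np.asarray(ensemble)
        if counts.ndim != 3:
            raise ValueError("expected (n_runs, T, M) counts")
    n_runs, T, M = counts.shape
    lo, hi = (0, T - 1) if window is None else window
    if not (0 <= lo <= hi <= T - 1):
        raise ValueError(f"window {window} outside [0, {T - 1}]")
    if n_ranks > M:
        raise ValueError("n_ranks exceeds the number of species")
    win = counts[:, lo : hi + 1, :].astype(float)
    series = np.empty((n_runs, hi - lo + 1, n_ranks))
    masses = np.empty((n_runs, n_ranks))
    for e in range(n_runs):
        avg = win[e].mean(axis=0)
        if not np.any(avg > 0):
            raise ValueError(f"run {e} has no occupied species in the window")
        order = np.lexsort((np.arange(M), -avg))[:n_ranks]
        series[e] = win[e][:, order]
        masses[e] = avg[order]
    return RankAligned(
        series=series,
        totals=win.sum(axis=2),
        rank_masses=masses.mean(axis=0),
        window=(lo, hi),
    )


def enumerate_subsets(K: int, limit: int, rank_masses: np.ndarray) -> list[SubsetSpec]:
    """Best-first enumeration of K-subsets of ranks by total rank mass.

    Emits subsets of rank positions in non-increasing order of summed rank
    mass, starting with ranks {1..K}, truncated at ``limit``.  Masses must
    be sorted non-increasing (rank order guarantees this).
    """
    masses = np.asarray(rank_masses, dtype=float)
    R = masses.size
    if K < 1 or K > R:
        raise ValueError(f"K={K} outside the available {R} ranks")
    if limit < 1:
        raise ValueError("limit must be >= 1")
    if np.any(np.diff(masses) > 1e-9):
        raise ValueError("rank masses must be non-increasing")

    first = tuple(range(K))
    heap = [(-float(masses[list(first)].sum()), first)]
    seen = {first}
    out: list[SubsetSpec] = []
    while heap and len(out) < limit:
        neg_mass, subset = heapq.heappop(heap)
        out.append(
            SubsetSpec(
                rank_positions=tuple(r + 1 for r in subset),
                total_rank_mass=-neg_mass,
            )
        )
        # successors: bump any member one rank down (toward smaller mass)
        s = set(subset)
        for pos, r in enumerate(subset):
            nxt = r + 1
            if nxt < R and nxt not in s:
                cand = tuple(sorted(subset[:pos] + (nxt,) + subset[pos + 1 :]))
                if cand not in seen:
                    seen.add(cand)
                    heapq.heappush(
                        heap, (-float(masses[list(cand)].sum()), cand)
                    )
    return out


def environment_pop(total, subset_pops):
    """Environment population E(t) = N(t) - sum of the group's populations."""
    total = np.asarray(total, dtype=float)
    subtotal = np.asarray(subset_pops, dtype=float)
    if subtotal.ndim > total.ndim:
        subtotal = subtotal.sum(axis=-1)
    env = total - subtotal
    if np.any(env < 0):
        raise ValueError("subset populations exceed the total population")
    return env


def _measure_series(S, E, kind, min_ratio=MIN_ENSEMBLE_RATIO):
    """Per-generation individuality estimates from raw ensemble series."""
    S = np.asarray(S, dtype=float)
    if S.ndim == 2:
        S = S[:, :, None]
    n_ens, T, K = S.shape
    need_env = kind in ("colonial", "env_det")
    dims = {"a_star": 2 * K, "colonial": 2 * K + 1, "env_det": 2 * K + 1}[kind]
    check_ensemble_size(n_ens, dims, min_ratio)
    if need_env:
        E = np.asarray(E, dtype=float)
        C, _ = lagged_cov_stack(S, extras=E[:, :, None])
        D = K + 1
        s_now = np.arange(K)
        s_next = D + np.arange(K)
        e_now = np.array([K])
        if kind == "colonial":
            vals = cmi_from_cov(C, s_now, s_next, e_now)
        else:
            vals = cmi_from_cov(C, e_now, s_next, s_now)
    else:
        C, _ = lagged_cov_stack(S)
        s_now = np.arange(K)
        s_next = K + np.arange(K)
        vals = mi_from_cov(C, s_now, s_next)
    return vals


def _as_result(vals, name, K) -> InfoResult:
    return InfoResult(
        measure=name,
        value=float(np.mean(vals)),
        dispersion=float(np.std(vals)),
        n_times=len(vals),
        scale=K,
    )


def organismal_individuality(S, *, min_ratio=MIN_ENSEMBLE_RATIO) -> InfoResult:
    """A* = I(S(t); S(t+1)), time-averaged across the ensemble.

    ``S`` has shape (n_ens, T, K) (or (n_ens, T) for a single species, where
    A* reduces to the plain lag-1 ensemble MI of that series).
    """
    S = np.asarray(S, dtype=float)
    K = 1 if S.ndim == 2 else S.shape[2]
    vals = _measure_series(S, None, "a_star", min_ratio)
    return _as_result(vals, "A*", K)


def colonial_individuality(S, E, *, min_ratio=MIN_ENSEMBLE_RATIO) -> InfoResult:
    """A = I(S(t); S(t+1) | E(t)): self-prediction beyond the environment."""
    S = np.asarray(S, dtype=float)
    K = 1 if S.ndim == 2 else S.shape[2]
    vals = _measure_series(S, E, "colonial", min_ratio)
    return _as_result(vals, "A", K)


def environment_determined_individuality(
    S, E, *, min_ratio=MIN_ENSEMBLE_RATIO
) -> InfoResult:
    """nC = I(E(t); S(t+1) | S(t)); identical to transfer entropy E -> S."""
    S = np.asarray(S, dtype=float)
    K = 1 if S.ndim == 2 else S.shape[2]
    vals = _measure_series(S, E, "env_det", min_ratio)
    return _as_result(vals, "nC", K)


def individuality_score(a_star: float, K: int) -> float:
    """Normalized individuality score A*/K, in nats per species."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return a_star / K


def scale_sweep(
    aligned: RankAligned,
    k_range=range(1, 16),
    subset_limit: int = 10_000,
    *,
    min_ratio: float = MIN_ENSEMBLE_RATIO,
    times: np.ndarray | None = None,
    p_mut: float | None = None,
    tie_tol: float = 0.0,
) -> tuple[pd.DataFrame, int | None]:
    """Mean normalized individuality score per scale K and the optimal scale.

    For each K, the normalized score A*/K is averaged over the enumerated
    rank subsets (up to ``subset_limit`` per K, in decreasing rank mass).
    Scales whose joint dimension exceeds the ensemble-size ratio are
    *refused*, not silently dropped: they appear in the table with a status
    column.  The optimal scale is the argmax of the mean score over scored
    scales, ties broken toward smaller K; ``None`` if nothing was scored.
    A larger scale must beat the incumbent by more than ``tie_tol`` (nats
    per species) to take over, so callers can neutralize the small positive
    estimator bias that grows with dimension.
    """
    C, _ = lagged_cov_stack(aligned.series, times=times)
    R = aligned.n_ranks
    rows = []
    best_k, best_score = None, -np.inf
    for K in k_range:
        if K > R:
            rows.append(
                {"p_mut": p_mut, "scale": K, "score": np.nan, "sd": np.nan,
                 "n_subsets": 0, "status": "refused: K exceeds available ranks"}
            )
            continue
        try:
            check_ensemble_size(aligned.n_runs, 2 * K, min_ratio)
        except EstimationError as err:
            rows.append(
                {"p_mut": p_mut, "scale": K, "score": np.nan, "sd": np.nan,
                 "n_subsets": 0, "status": f"refused: {err}"}
            )
            continue
        subsets = enumerate_subsets(K, subset_limit, aligned.rank_masses)
        scores = []
        for spec in subsets:
            idx = np.asarray(spec.rank_positions, int) - 1
            a_star_t = mi_from_cov(C, idx, R + idx)
            scores.append(individuality_score(float(a_star_t.mean()), K))
        mean_score = float(np.mean(scores))
        rows.append(
            {"p_mut": p_mut, "scale": K, "score": mean_score,
             "sd": float(np.std(scores)), "n_subsets": len(subsets),
             "status": "ok"}
        )
        if mean_score > best_score + tie_tol:
            best_score, best_k = mean_score, K
    return pd.DataFrame(rows), best_k
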