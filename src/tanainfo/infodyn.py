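"""Transfer entropy and integrated information for species–environment pairs.

Transfer entropy from source S to target E (lag 1, Markov condition):

    TE(S -> E) = I(S(t); E(t+1) | E(t))

Whole-minus-sum integrated information of a joint system X = (X_1, X_2):

    Phi_WMS = I(X(t); X(t+1)) - sum_i I(X_i(t); X_i(t+1))

which can be negative when the parts are highly correlated; the revised
measure corrects that redundancy with the smallest pairwise lagged MI:

    Phi_R = Phi_WMS + min_{i,j} I(X_i(t); X_j(t+1)).

All estimates use the Gaussian ensemble estimators (cross-ensemble samples
per generation, averaged over generations) and are reported in nats.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gaussian_info import (
    InfoResult,
    MIN_ENSEMBLE_RATIO,
    check_ensemble_size,
    cmi_from_cov,
    lagged_cov_stack,
    mi_from_cov,
)
from .individuality import RankAligned, environment_pop

__all__ = [
    "transfer_entropy",
    "phi_wms",
    "phi_r",
    "species_environment_profile",
]


def _ensure3d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[:, :, None]
    if X.ndim != 3:
        raise ValueError("series must have shape (n_ens, T, d)")
    return X


def transfer_entropy(source, target, *, min_ratio=MIN_ENSEMBLE_RATIO) -> InfoResult:
    """TE(source -> target) in nats; supports multivariate sources.

    Invariant under invertible affine rescaling of either series and
    directional: for a one-way coupled pair only the driven direction is
    positive (up to estimator noise).
    """
    S, Tg = _ensure3d(source), _ensure3d(target)
    if S.shape[:2] != Tg.shape[:2]:
        raise ValueError("source and target must share (n_ens, T)")
    n_ens = S.shape[0]
    ds, dt = S.shape[2], Tg.shape[2]
    check_ensemble_size(n_ens, ds + 2 * dt, min_ratio)
    C, _ = lagged_cov_stack(np.concatenate([S, Tg], axis=2))
    D = ds + dt
    s_now = np.arange(ds)
    t_now = ds + np.arange(dt)
    t_next = D + ds + np.arange(dt)
    vals = cmi_from_cov(C, s_now, t_next, t_now)
    return InfoResult(
        measure="TE",
        value=float(vals.mean()),
        dispersion=float(vals.std()),
        n_times=len(vals),
    )


def _phi_terms(X, min_ratio):
    X = _ensure3d(X)
    n_ens, T, d = X.shape
    if d < 2:
        raise ValueError("integrated information needs at least two parts")
    check_ensemble_size(n_ens, 2 * d, min_ratio)
    C, _ = lagged_cov_stack(X)
    now = np.arange(d)
    nxt = d + np.arange(d)
    whole = mi_from_cov(C, now, nxt)
    parts = sum(mi_from_cov(C, [i], [d + i]) for i in range(d))
    pairwise = np.stack(
        [mi_from_cov(C, [i], [d + j]) for i in range(d) for j in range(d)]
    )
    return whole - parts, pairwise


def phi_wms(X, *, min_ratio=MIN_ENSEMBLE_RATIO) -> InfoResult:
    """Whole-minus-sum integrated information of the joint series X."""
    wms, _ = _phi_terms(X, min_ratio)
    return InfoResult(
        measure="Phi_WMS",
        value=float(wms.mean()),
        dispersion=float(wms.std()),
        n_times=len(wms),
    )


def phi_r(X, *, min_ratio=MIN_ENSEMBLE_RATIO,
          include_self_pairs: bool = True) -> InfoResult:
    """Redundancy-corrected integrated information.

    Adds the minimum lagged pairwise MI over ordered pairs (i, j).  The
    printed minimum is unrestricted (includes i = j); set
    ``include_self_pairs=False`` for the cross-pair-only variant.  Since the
    added term is a clamped MI, ``phi_r >= phi_wms`` holds exactly.
    """
    wms, pairwise = _phi_terms(X, min_ratio)
    if not include_self_pairs:
        d = int(round(np.sqrt(pairwise.shape[0])))
        keep = [i * d + j for i in range(d) for j in range(d) if i != j]
        pairwise = pairwise[keep]
    vals = wms + pairwise.min(axis=0)
    return InfoResult(
        measure="Phi_R",
        value=float(vals.mean()),
        dispersion=float(vals.std()),
        n_times=len(vals),
    )


def species_environment_profile(
    aligned: RankAligned,
    *,
    scales: tuple[int, ...] = (1, 6),
    n_species_avg: int = 6,
    subset_limit: int = 100,
    min_ratio: float = MIN_ENSEMBLE_RATIO,
    p_mut: float | None = None,
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """TE in both directions and (at scale 1) Phi for species–environment.

    At scale 1 the joint variable is X = (n_i, E) for each of the
    ``n_species_avg`` top-ranked species, with E the scalar environment of
    that species; measures are averaged over those species.  At higher
    scales the source is the K-dimensional group of top ranks (and the
    ``subset_limit`` next rank subsets), E its scalar environment.
    Integrated information is reported at scale 1 only.  Refusals surface
    as rows with a status message rather than being dropped.
    """
    from .individuality import enumerate_subsets

    rows = []
    R = aligned.n_ranks
    S_all = aligned.series
    N = aligned.totals
    C_full, _ = lagged_cov_stack(S_all, extras=N[:, :, None], times=times)
    D = R + 1  # variables per time slice: R ranks + total N
    n_idx = np.array([R])

    def _pair_measures(idx: np.ndarray) -> dict[str, float] | str:
        """TE both ways for group `idx` (rank indices, 0-based) vs its E."""
        K = idx.size
        try:
            check_ensemble_size(aligned.n_runs, 2 * K + 2, min_ratio)
        except Exception as err:  # refusal, surfaced by caller
            return str(err)
        # E(t) = N(t) - sum of group counts: linear map of the slice vars
        B = np.zeros((2 * (K + 1), 2 * D))
        for a, r in enumerate(idx):
            B[a, r] = 1.0
            B[K + 1 + a, D + r] = 1.0
        B[K, n_idx[0]] = 1.0
        B[K, idx] = -1.0
        B[2 * K + 1, D + n_idx[0]] = 1.0
        B[2 * K + 1, D + idx] = -1.0
        C = np.einsum("ai,tij,bj->tab", B, C_full, B)
        s_now = np.arange(K)
        e_now = np.array([K])
        s_next = K + 1 + np.arange(K)
        e_next = np.array([2 * K + 1])
        te_se = cmi_from_cov(C, s_now, e_next, e_now)
        te_es = cmi_from_cov(C, e_now, s_next, s_now)
        out = {
            "TE_S_to_E": float(te_se.mean()),
            "TE_E_to_S": float(te_es.mean()),
        }
        if K == 1:
            whole = mi_from_cov(C, np.r_[s_now, e_now], np.r_[s_next, e_next])
            parts = mi_from_cov(C, s_now, s_next) + mi_from_cov(C, e_now, e_next)
            wms = whole - parts
            pairwise = np.stack(
                [
                    mi_from_cov(C, [a], [b])
                    for a in (0, 1)
                    for b in (2, 3)
                ]
            )
            out["Phi_WMS"] = float(wms.mean())
            out["Phi_R"] = float((wms + pairwise.min(axis=0)).mean())
        return out

    for K in scales:
        if K > R:
            rows.append({"p_mut": p_mut, "scale": K, "measure": "all",
                         "value": np.nan, "status": "refused: K exceeds ranks"})
            continue
        if K == 1:
            groups = [np.array([r]) for r in range(min(n_species_avg, R))]
        else:
            subsets = enumerate_subsets(K, subset_limit, aligned.rank_masses)
            groups = [np.asarray(s.rank_positions, int) - 1 for s in subsets]
        acc: dict[str, list[float]] = {}
        status = "ok"
        for idx in groups:
            res = _pair_measures(idx)
            if isinstance(res, str):
                status = f"refused: {res}"
                break
            for k, v in res.items():
                acc.setdefault(k, []).append(v)
        if status != "ok":
            rows.append({"p_mut": p_mut, "scale": K, "measure": "all",
                         "value": np.nan, "status": status})
            continue
        for meas, vals in acc.items():
            rows.append(
                {"p_mut": p_mut, "scale": K, "measure": meas,
                 "value": float(np.mean(vals)), "sd": float(np.std(vals)),
                 "n_groups": len(vals), "status": "ok"}
            )
    return pd.DataFrame(rows)
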