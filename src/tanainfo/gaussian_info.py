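"""Gaussian estimators of mutual information and conditional MI.

All measures are computed under a multivariate-Gaussian model from sample
covariances via log-determinants:

    I(X; Y)      = 0.5 * [ ln det S_X + ln det S_Y - ln det S_XY ]
    I(X; Y | Z)  = 0.5 * [ ln det S_XZ + ln det S_YZ - ln det S_XYZ - ln det S_Z ]

in nats.  Because the Tangled Nature model is non-stationary, estimates are
taken *across ensemble members at a fixed generation* (the cross-realization
distribution), then averaged over generations — the ensemble method used
when a single time series cannot supply a stationary distribution.

Every covariance block receives a small relative ridge before the
determinant so that locally degenerate count data stay invertible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EstimationError",
    "RIDGE_REL",
    "MIN_ENSEMBLE_RATIO",
    "gaussian_mi",
    "gaussian_cmi",
    "lagged_cov_stack",
    "mi_from_cov",
    "cmi_from_cov",
    "InfoResult",
    "ensemble_measure_over_time",
]

RIDGE_REL = 1e-9
MIN_ENSEMBLE_RATIO = 10.0

# An estimated MI per effective dimension beyond this many nats can only
# come from a numerically degenerate (near-duplicated) block at the default
# ridge; treat it as a degeneracy rather than a finite estimate.
_MI_CAP_PER_DIM = 0.25 * np.log(1.0 / RIDGE_REL)


class EstimationError(ValueError):
    """An information estimate was refused (degenerate or under-sampled)."""


def _as2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("samples must be a (n_samples, d) array")
    return X


def _ridge_logdet(C: np.ndarray, name: str, ridge_rel: float = RIDGE_REL) -> float:
    """log-determinant of a covariance block after a relative ridge."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    d = C.shape[0]
    lam = ridge_rel * max(np.trace(C), np.finfo(float).tiny) / d
    sign, logdet = np.linalg.slogdet(C + lam * np.eye(d))
    if sign <= 0 or not np.isfinite(logdet):
        raise EstimationError(f"covariance block {name!r} is degenerate after ridge")
    return float(logdet)


def gaussian_mi(X, Y, *, ridge_rel: float = RIDGE_REL, clamp: bool = True) -> float:
    """Gaussian mutual information I(X; Y) in nats from samples.

    Requires more samples than the joint dimension; raises
    :class:`EstimationError` if a covariance block is degenerate or the
    estimate exceeds the numerical cap (e.g. MI of a variable with a copy of
    itself, which diverges under a continuous model).
    """
    X, Y = _as2d(X), _as2d(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of samples")
    n, dx = X.shape
    dy = Y.shape[1]
    if n <= dx + dy + 1:
        raise EstimationError(
            f"need more than {dx + dy + 1} samples for joint dimension "
            f"{dx + dy}, got {n}"
        )
    J = np.cov(np.hstack([X, Y]), rowvar=False)
    J = np.atleast_2d(J)
    ld_x = _ridge_logdet(J[:dx, :dx], "X", ridge_rel)
    ld_y = _ridge_logdet(J[dx:, dx:], "Y", ridge_rel)
    ld_xy = _ridge_logdet(J, "XY", ridge_rel)
    mi = 0.5 * (ld_x + ld_y - ld_xy)
    cap = _MI_CAP_PER_DIM * max(1, min(dx, dy))
    if mi > cap:
        raise EstimationError(
            f"MI estimate {mi:.2f} nats exceeds the degeneracy cap {cap:.2f}; "
            "the joint covariance block 'XY' is near-singular"
        )
    return max(mi, 0.0) if clamp else mi


def gaussian_cmi(X, Y, Z=None, *, ridge_rel: float = RIDGE_REL,
                 clamp: bool = True) -> float:
    """Gaussian conditional mutual information I(X; Y | Z) in nats.

    With ``Z`` empty or ``None`` this reduces to :func:`gaussian_mi`.  The
    four determinants are evaluated from one joint covariance pass.
    """
    X, Y = _as2d(X), _as2d(Y)
    if Z is None or (hasattr(Z, "size") and np.asarray(Z).size == 0):
        return gaussian_mi(X, Y, ridge_rel=ridge_rel, clamp=clamp)
    Z = _as2d(Z)
    if not (X.shape[0] == Y.shape[0] == Z.shape[0]):
        raise ValueError("X, Y, Z must have the same number of samples")
    n = X.shape[0]
    dx, dy, dz = X.shape[1], Y.shape[1], Z.shape[1]
    if n <= dx + dy + dz + 1:
        raise EstimationError(
            f"need more than {dx + dy + dz + 1} samples for joint dimension "
            f"{dx + dy + dz}, got {n}"
        )
    J = np.atleast_2d(np.cov(np.hstack([X, Y, Z]), rowvar=False))
    ix = np.arange(dx)
    iy = np.arange(dx, dx + dy)
    iz = np.arange(dx + dy, dx + dy + dz)
    ld_xz = _ridge_logdet(J[np.ix_(np.r_[ix, iz], np.r_[ix, iz])], "XZ", ridge_rel)
    ld_yz = _ridge_logdet(J[np.ix_(np.r_[iy, iz], np.r_[iy, iz])], "YZ", ridge_rel)
    ld_xyz = _ridge_logdet(J, "XYZ", ridge_rel)
    ld_z = _ridge_logdet(J[np.ix_(iz, iz)], "Z", ridge_rel)
    cmi = 0.5 * (ld_xz + ld_yz - ld_xyz - ld_z)
    cap = _MI_CAP_PER_DIM * max(1, min(dx, dy))
    if cmi > cap:
        raise EstimationError(
            f"CMI estimate {cmi:.2f} nats exceeds the degeneracy cap {cap:.2f}"
        )
    return max(cmi, 0.0) if clamp else cmi


# ---------------------------------------------------------------------------
# covariance-stack fast path
#
# For subset sweeps it is wasteful to rebuild sample covariances per subset:
# instead one covariance of the full augmented vector is taken per generation
# and every measure becomes log-determinants of sub-blocks (optionally after
# a linear map, e.g. the environment E = N - sum of subset counts).


def lagged_cov_stack(data: np.ndarray, extras: np.ndarray | None = None,
                     times: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-generation covariance of (V(t), V(t+1)) across the ensemble.

    ``data`` has shape (n_ens, T, d); ``extras`` optionally appends scalar
    series of shape (n_ens, T, d_e).  Returns ``(C, times)`` where ``C`` has
    shape (len(times), 2*D, 2*D) with variable order
    ``[V(t) (D dims), V(t+1) (D dims)]``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be (n_ens, T, d)")
    if extras is not None:
        extras = np.asarray(extras, dtype=float)
        if extras.ndim == 2:
            extras = extras[:, :, None]
        data = np.concatenate([data, extras], axis=2)
    n_ens, T, D = data.shape
    if T < 2:
        raise ValueError("need at least two time points for a lag-1 stack")
    if times is None:
        times = np.arange(T - 1)
    times = np.asarray(times, dtype=int)
    C = np.empty((times.size, 2 * D, 2 * D))
    for q, t in enumerate(times):
        V = np.hstack([data[:, t, :], data[:, t + 1, :]])
        C[q] = np.atleast_2d(np.cov(V, rowvar=False))
    return C, times


def _stack_logdet(C: np.ndarray, name: str, ridge_rel: float = RIDGE_REL) -> np.ndarray:
    d = C.shape[-1]
    tr = np.trace(C, axis1=-2, axis2=-1)
    lam = ridge_rel * np.maximum(tr, np.finfo(float).tiny) / d
    sign, logdet = np.linalg.slogdet(C + lam[:, None, None] * np.eye(d))
    if np.any(sign <= 0) or not np.all(np.isfinite(logdet)):
        raise EstimationError(f"covariance block {name!r} degenerate after ridge")
    return logdet


def mi_from_cov(C: np.ndarray, ix: Sequence[int], iy: Sequence[int],
                *, ridge_rel: float = RIDGE_REL, clamp: bool = True) -> np.ndarray:
    """Per-time MI between index groups of a stacked covariance (T, D, D)."""
    ix, iy = np.asarray(ix, int), np.asarray(iy, int)
    ixy = np.r_[ix, iy]
    ld_x = _stack_logdet(C[:, ix[:, None], ix[None, :]], "X", ridge_rel)
    ld_y = _stack_logdet(C[:, iy[:, None], iy[None, :]], "Y", ridge_rel)
    ld_xy = _stack_logdet(C[:, ixy[:, None], ixy[None, :]], "XY", ridge_rel)
    mi = 0.5 * (ld_x + ld_y - ld_xy)
    return np.maximum(mi, 0.0) if clamp else mi


def cmi_from_cov(C: np.ndarray, ix, iy, iz,
                 *, ridge_rel: float = RIDGE_REL, clamp: bool = True) -> np.ndarray:
    """Per-time conditional MI I(X;Y|Z) from a stacked covariance."""
    ix, iy, iz = (np.asarray(v, int) for v in (ix, iy, iz))
    if iz.size == 0:
        return mi_from_cov(C, ix, iy, ridge_rel=ridge_rel, clamp=clamp)
    ixz, iyz, ixyz = np.r_[ix, iz], np.r_[iy, iz], np.r_[ix, iy, iz]
    ld_xz = _stack_logdet(C[:, ixz[:, None], ixz[None, :]], "XZ", ridge_rel)
    ld_yz = _stack_logdet(C[:, iyz[:, None], iyz[None, :]], "YZ", ridge_rel)
    ld_xyz = _stack_logdet(C[:, ixyz[:, None], ixyz[None, :]], "XYZ", ridge_rel)
    ld_z = _stack_logdet(C[:, iz[:, None], iz[None, :]], "Z", ridge_rel)
    cmi = 0.5 * (ld_xz + ld_yz - ld_xyz - ld_z)
    return np.maximum(cmi, 0.0) if clamp else cmi


@dataclass(frozen=True)
class InfoResult:
    """A named information measure with its estimation context.

    ``value`` is in nats (for normalized individuality scores: nats per
    species).  ``dispersion`` is the SD of the per-generation estimates over
    the averaging window.
    """

    measure: str
    value: float
    dispersion: float
    n_times: int
    scale: int | None = None
    p_mut: float | None = None
    window: tuple[int, int] | None = None
    n_subsets: int = 1

    def __post_init__(self):
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def check_ensemble_size(n_ens: int, joint_dim: int,
                        min_ratio: float = MIN_ENSEMBLE_RATIO) -> None:
    """Refuse estimates whose ensemble is too small for the dimension."""
    if n_ens < min_ratio * joint_dim:
        raise EstimationError(
            f"ensemble of {n_ens} members is below the required "
            f"{min_ratio:g}:1 ratio for joint dimension {joint_dim}"
        )


def ensemble_measure_over_time(
    data: np.ndarray,
    measure: Callable[[np.ndarray, np.ndarray], float],
    *,
    window: tuple[int, int] | None = None,
    measure_name: str = "measure",
    min_ratio: float = MIN_ENSEMBLE_RATIO,
    joint_dim: int | None = None,
    times: np.ndarray | None = None,
) -> InfoResult:
    """Average a lag-1 ensemble measure over generations.

    For each generation ``t`` in the window, the cross-ensemble samples at
    ``t`` and ``t+1`` are handed to ``measure(X_t, X_t1)``; the per-time
    values are averaged.  ``data`` has shape (n_ens, T, d).  A window of a
    single generation reduces to the single-time estimate.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    n_ens, T, d = data.shape
    if T < 2:
        raise ValueError("need at least two time points for a lag-1 measure")
    if joint_dim is None:
        joint_dim = 2 * d
    check_ensemble_size(n_ens, joint_dim, min_ratio)
    # t ranges over generations whose successor is still inside the data
    lo, hi = (0, T - 2) if window is None else window
    if not (0 <= lo <= hi <= T - 2):
        raise ValueError(f"window {window} outside [0, {T - 2}]")
    if times is None:
        times = np.arange(lo, hi + 1)
    vals = np.array([measure(data[:, t, :], data[:, t + 1, :]) for t in times])
    return InfoResult(
        measure=measure_name,
        value=float(vals.mean()),
        dispersion=float(vals.std(ddof=0)),
        n_times=len(times),
        window=(int(lo), int(hi)),
    )
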