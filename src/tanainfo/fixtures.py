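"""Synthetic Gaussian ensembles with analytically known information content.

A stationary VAR(1) process  X(t+1) = A X(t) + eps,  eps ~ N(0, Q)  has
stationary covariance S solving the discrete Lyapunov equation
S = A S A' + Q, and lag-1 joint covariance

    Cov[(X(t), X(t+1))] = [[S, S A'], [A S, S]].

Every Gaussian information measure used in this package is a closed-form
function of that joint covariance, so these ensembles are exact oracles for
the estimators.  Fixtures are continuous-valued by design — the estimation
model is Gaussian, so ground truth must be exact under the model; count-like
features (positive, rank-ordered magnitudes) are emulated only by affine
shifts in the planted-block fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

__all__ = [
    "VarProcessSpec",
    "stationary_cov",
    "lagged_joint_cov",
    "simulate_var",
    "analytic_info",
    "planted_block_ensemble",
]


@dataclass(frozen=True)
class VarProcessSpec:
    """Specification of a stationary VAR(1) ensemble."""

    coeffs: np.ndarray
    noise_cov: np.ndarray
    n_ensemble: int = 1000
    horizon: int = 50
    seed: int = 0

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        Q = np.atleast_2d(np.asarray(self.noise_cov, dtype=float))
        object.__setattr__(self, "coeffs", A)
        object.__setattr__(self, "noise_cov", Q)
        if A.shape[0] != A.shape[1] or A.shape != Q.shape:
            raise ValueError("coeffs and noise_cov must be square and congruent")
        if np.max(np.abs(np.linalg.eigvals(A))) >= 1.0:
            raise ValueError("VAR(1) is non-stationary: spectral radius >= 1")
        if not np.allclose(Q, Q.T):
            raise ValueError("noise covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(Q)) <= 0:
            raise ValueError("noise covariance must be positive definite")
        if self.n_ensemble < 1 or self.horizon < 2:
            raise ValueError("need n_ensemble >= 1 and horizon >= 2")

    @property
    def dimension(self) -> int:
        return self.coeffs.shape[0]


def stationary_cov(spec: VarProcessSpec) -> np.ndarray:
    """Stationary covariance S solving S = A S A' + Q."""
    return solve_discrete_lyapunov(spec.coeffs, spec.noise_cov)


def lagged_joint_cov(spec: VarProcessSpec) -> np.ndarray:
    """Exact covariance of the stacked vector (X(t), X(t+1)), shape (2d, 2d)."""
    S = stationary_cov(spec)
    A = spec.coeffs
    top = np.hstack([S, S @ A.T])
    bot = np.hstack([A @ S, S])
    return np.vstack([top, bot])


def simulate_var(spec: VarProcessSpec) -> np.ndarray:
    """Independent stationary realizations, shape (n_ensemble, horizon, d).

    Each member is initialized from the exact stationary distribution, so
    every generation is a valid stationary cross-ensemble sample.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.dimension
    S = stationary_cov(spec)
    L_s = np.linalg.cholesky(S + 1e-12 * np.eye(d))
    L_q = np.linalg.cholesky(spec.noise_cov)
    X = np.empty((spec.n_ensemble, spec.horizon, d))
    X[:, 0, :] = rng.standard_normal((spec.n_ensemble, d)) @ L_s.T
    A_T = spec.coeffs.T
    for t in range(1, spec.horizon):
        eps = rng.standard_normal((spec.n_ensemble, d)) @ L_q.T
        X[:, t, :] = X[:, t - 1, :] @ A_T + eps
    return X


# -- closed-form measures ----------------------------------------------------
# Deliberately self-contained (own logdet / conditioning code) so the oracle
# shares no covariance-handling path with the estimators it validates.


def _ld(M) -> float:
    M = np.atleast_2d(M)
    sign, val = np.linalg.slogdet(M)
    if sign <= 0:
        raise ValueError("matrix block is not positive definite")
    return float(val)


def _mi_blocks(J: np.ndarray, ix, iy) -> float:
    ix, iy = np.asarray(ix, int), np.asarray(iy, int)
    ixy = np.r_[ix, iy]
    return 0.5 * (
        _ld(J[np.ix_(ix, ix)]) + _ld(J[np.ix_(iy, iy)]) - _ld(J[np.ix_(ixy, ixy)])
    )


def _cmi_blocks(J: np.ndarray, ix, iy, iz) -> float:
    ix, iy, iz = (np.asarray(v, int) for v in (ix, iy, iz))
    if iz.size == 0:
        return _mi_blocks(J, ix, iy)
    ixz, iyz, ixyz = np.r_[ix, iz], np.r_[iy, iz], np.r_[ix, iy, iz]
    return 0.5 * (
        _ld(J[np.ix_(ixz, ixz)])
        + _ld(J[np.ix_(iyz, iyz)])
        - _ld(J[np.ix_(ixyz, ixyz)])
        - _ld(J[np.ix_(iz, iz)])
    )


def analytic_info(
    spec: VarProcessSpec,
    measure: str,
    *,
    subset: tuple[int, ...] | None = None,
    env: int | None = None,
    parts: tuple[int, ...] | None = None,
    include_self_pairs: bool = True,
) -> float:
    """Closed-form value of an information measure for a VAR(1) fixture.

    Supported measures (variable indices refer to process components;
    primed copies live at index ``i + d`` in the lagged joint covariance):

    - ``"mi_lag1"``: I(S(t); S(t+1)) over ``subset`` — organismal
      individuality A* of the subset.
    - ``"colonial"``: I(S(t); S(t+1) | E(t)) with scalar environment
      component ``env``.
    - ``"env_det"``: I(E(t); S(t+1) | S(t)) — equals TE(E -> S).
    - ``"te"``: transfer entropy from ``subset`` (source) to ``env``
      (target): I(S(t); E(t+1) | E(t)).
    - ``"phi_wms"`` / ``"phi_r"``: integrated information of the joint
      system over ``parts`` (defaults to all components).
    """
    d = spec.dimension
    J = lagged_joint_cov(spec)
    sub = tuple(range(d)) if subset is None else tuple(subset)
    s_now = np.asarray(sub, int)
    s_next = s_now + d

    if measure == "mi_lag1":
        return _mi_blocks(J, s_now, s_next)
    if measure == "colonial":
        if env is None:
            raise ValueError("colonial individuality needs an env component")
        return _cmi_blocks(J, s_now, s_next, np.array([env]))
    if measure == "env_det":
        if env is None:
            raise ValueError("env_det needs an env component")
        return _cmi_blocks(J, np.array([env]), s_next, s_now)
    if measure == "te":
        if env is None:
            raise ValueError("te needs a target component")
        return _cmi_blocks(J, s_now, np.array([env + d]), np.array([env]))
    if measure in ("phi_wms", "phi_r"):
        p = tuple(range(d)) if parts is None else tuple(parts)
        p_now = np.asarray(p, int)
        p_next = p_now + d
        whole = _mi_blocks(J, p_now, p_next)
        parts_sum = sum(_mi_blocks(J, [i], [i + d]) for i in p)
        phi = whole - parts_sum
        if measure == "phi_wms":
            return phi
        pair_mis = [
            _mi_blocks(J, [i], [j + d])
            for i in p
            for j in p
            if include_self_pairs or i != j
        ]
        return phi + max(min(pair_mis), 0.0)
    raise ValueError(f"unsupported measure {measure!r}")


def planted_block_ensemble(
    K0: int,
    coupling: float = 0.85,
    n_ranks: int = 10,
    n_ensemble: int = 400,
    horizon: int = 60,
    seed: int = 0,
    noise_scale: float = 1.0,
) -> tuple[np.ndarray, VarProcessSpec]:
    """Ensemble whose first ``K0`` ranks form one jointly self-predicting unit.

    The block follows a cyclically rotating VAR(1): component ``i`` at
    ``t+1`` is driven by component ``i+1 (mod K0)`` at ``t`` with weight
    ``coupling``.  Individually each block member is then barely
    self-predicting, while the block as a whole carries
    ``-K0/2 * ln(1 - coupling^2)`` nats about its own future — so the
    normalized score peaks exactly at scale ``K0``.  Remaining ranks are
    temporally independent noise.  Marginal scales and offsets decrease
    with rank to emulate rank-aligned, positive population series.

    Returns ``(data, spec)`` with data of shape (n_ensemble, horizon,
    n_ranks); ``spec`` describes the underlying VAR for analytic checks.
    """
    if not 1 <= K0 <= n_ranks:
        raise ValueError("need 1 <= K0 <= n_ranks")
    if not 0 <= abs(coupling) < 1:
        raise ValueError("|coupling| must be < 1 for stationarity")
    A = np.zeros((n_ranks, n_ranks))
    for i in range(K0):
        A[i, (i + 1) % K0] = coupling
    Q = np.eye(n_ranks) * noise_scale**2
    spec = VarProcessSpec(
        coeffs=A, noise_cov=Q, n_ensemble=n_ensemble, horizon=horizon, seed=seed
    )
    X = simulate_var(spec)
    # affine count-likeness: decreasing magnitude and positive offset by rank
    scales = 10.0 * 0.9 ** np.arange(n_ranks)
    offsets = 100.0 * 0.85 ** np.arange(n_ranks) + 20.0
    return X * scales + offsets, spec
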