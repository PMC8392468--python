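"""Small multivariate-normal conditioning helpers shared across modules."""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular


def condition_mvn(
    mean: np.ndarray,
    cov: np.ndarray,
    obs_idx: np.ndarray,
    obs_values: np.ndarray,
    jitter: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Condition ``N(mean, cov)`` on exact values at ``obs_idx``.

    Returns the conditional mean and covariance of the remaining coordinates,
    in their original relative order.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    n = mean.shape[0]
    obs_idx = np.asarray(obs_idx, dtype=int)
    rest = np.setdiff1d(np.arange(n), obs_idx)
    S_oo = cov[np.ix_(obs_idx, obs_idx)] + jitter * np.eye(len(obs_idx))
    S_ro = cov[np.ix_(rest, obs_idx)]
    c = cho_factor(S_oo, lower=True)
    gain = cho_solve(c, S_ro.T).T
    m = mean[rest] + gain @ (np.asarray(obs_values, dtype=float) - mean[obs_idx])
    V = cov[np.ix_(rest, rest)] - gain @ S_ro.T
    V = 0.5 * (V + V.T)
    return m, V


def sample_mvn(
    rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray, jitter: float = 1e-10
) -> np.ndarray:
    """One draw from ``N(mean, cov)`` via a jittered Cholesky factor."""
    cov = np.asarray(cov, dtype=float)
    L = cholesky(cov + jitter * np.eye(cov.shape[0]), lower=True)
    return np.asarray(mean, dtype=float) + L @ rng.standard_normal(cov.shape[0])


def chol_logdet(L: np.ndarray) -> float:
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def whiten(L: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Solve ``L z = x`` for a lower-triangular Cholesky factor ``L``."""
    return solve_triangular(L, x, lower=True)
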