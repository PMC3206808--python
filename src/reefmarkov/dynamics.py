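"""Markov-chain dynamics: projection, equilibrium, damping ratio, and
posterior summaries of derived statistics.

All matrices are column-stochastic (columns = source states), so the state
distribution evolves as p(t+1) = P p(t) and the equilibrium is the right
eigenvector of P for eigenvalue 1, normalized to sum to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .estimation import DirichletPosterior
from .surveys import CoverSummary

__all__ = [
    "project_distribution",
    "stationary_distribution",
    "damping_ratio",
    "cover_from_distribution",
    "DerivedStatSummary",
    "summarize_derived",
]

logger = logging.getLogger(__name__)


def _as_distribution(p, m: int | None = None) -> np.ndarray:
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise ValueError("state distribution must be a vector")
    if m is not None and len(p) != m:
        raise ValueError(f"dimension mismatch: expected length {m}, got {len(p)}")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("state distribution must be nonnegative and sum to 1")
    return p


def project_distribution(P: np.ndarray, p0, horizon: int) -> np.ndarray:
    """Iterate p(t+1) = P p(t) for ``horizon`` steps.

    Returns an array of shape (horizon + 1, m) whose first row is ``p0``.
    """
    P = np.asarray(P, float)
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    p = _as_distribution(p0, P.shape[0])
    out = np.empty((horizon + 1, P.shape[0]))
    out[0] = p
    for t in range(horizon):
        out[t + 1] = P @ out[t]
    return out


def stationary_distribution(P: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Equilibrium state distribution pi with P pi = pi, normalized to sum 1.

    Valid for irreducible column-stochastic matrices (all posterior draws and
    posterior means are strictly positive, hence irreducible).  A transition
    matrix whose eigenvalue 1 is not simple has no unique stationary
    distribution and raises ``ValueError``.
    """
    P = np.asarray(P, float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    eigvals, eigvecs = np.linalg.eig(P)
    near_one = np.abs(eigvals - 1.0) < 1e-8
    if near_one.sum() > 1:
        raise ValueError(
            "eigenvalue 1 is not simple: the chain is reducible and has no "
            "unique stationary distribution"
        )
    k = int(np.argmin(np.abs(eigvals - 1.0)))
    v = np.real(eigvecs[:, k])
    v = v / v.sum()
    if np.any(v < -1e-8):
        raise ValueError("stationary eigenvector has negative entries (reducible chain?)")
    pi = np.clip(v, 0.0, None)
    pi /= pi.sum()
    resid = np.max(np.abs(P @ pi - pi))
    if resid > tol:
        raise ValueError(f"stationary residual {resid:.2e} exceeds tolerance {tol:.0e}")
    return pi


def damping_ratio(P: np.ndarray) -> float:
    """Ratio of the dominant eigenvalue to the magnitude of the second one.

    For a column-stochastic matrix the dominant eigenvalue is exactly 1, so
    rho = 1 / |lambda_2| with eigenvalues sorted by modulus.  Larger values
    mean faster convergence to the stationary distribution.  A rank-one matrix
    (all subdominant eigenvalues zero) returns ``inf``.
    """
    P = np.asarray(P, float)
    if P.shape[0] < 2:
        raise ValueError("damping ratio requires at least two states")
    mags = np.sort(np.abs(np.linalg.eigvals(P)))
    lam2 = mags[-2]
    if lam2 < 1e-12:  # rank-one chain: equilibrium reached in one step
        return np.inf
    # lambda_1 taken as its theoretical value 1, avoiding spurious rho < 1
    # from floating-point rounding of the top eigenvalue
    return 1.0 / lam2


def cover_from_distribution(p, covers: CoverSummary) -> tuple[float, float]:
    """Projected (coral %, algae %) cover: q_c = sum_i c_i p_i, q_a = sum_i a_i p_i."""
    p = np.asarray(p, float)
    if len(p) != len(covers.c):
        raise ValueError("distribution and cover summary lengths differ")
    return float(covers.c @ p), float(covers.a @ p)


@dataclass
class DerivedStatSummary:
    """Posterior mean and equal-tailed credible intervals of a derived statistic."""

    mean: np.ndarray
    ci50: tuple[np.ndarray, np.ndarray]
    ci95: tuple[np.ndarray, np.ndarray]
    n_rep: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        lo50, hi50 = self.ci50
        lo95, hi95 = self.ci95
        if np.any(np.asarray(lo50) > np.asarray(hi50)) or np.any(
            np.asarray(lo95) > np.asarray(hi95)
        ):
            raise ValueError("credible interval bounds out of order")


def summarize_derived(
    stat_fn: Callable[[np.ndarray, np.ndarray], float | np.ndarray],
    trans_post: DirichletPosterior,
    init_alpha: np.ndarray | None = None,
    n_rep: int = 10000,
    rng: np.random.Generator | None = None,
) -> DerivedStatSummary:
    """Posterior summary of ``stat_fn(P, p0)`` by Monte Carlo over the posteriors.

    For each of ``n_rep`` replicates, a transition matrix is drawn from the
    column-wise Dirichlet posterior and an initial state distribution from its
    Dirichlet posterior; the statistic is evaluated on the pair and the sample
    mean and the 25/75 and 2.5/97.5 empirical percentiles (linear interpolation
    between order statistics) are returned.

    ``stat_fn`` always receives both draws, even if it uses only one.
    Replicates where the statistic is non-finite (e.g. an infinite damping
    ratio for a degenerate draw) are dropped with a logged count; more than 1%
    non-finite replicates is an error.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    m = trans_post.m
    if init_alpha is None:
        init_alpha = np.ones(m)
    init_alpha = np.asarray(init_alpha, float)
    if len(init_alpha) != m or np.any(init_alpha <= 0):
        raise ValueError("init_alpha must be a positive vector of length m")

    Ps = trans_post.sample(rng, size=n_rep)
    p0s = rng.dirichlet(init_alpha, size=n_rep)
    vals = np.asarray([np.asarray(stat_fn(Ps[r], p0s[r]), float) for r in range(n_rep)])

    flat = vals.reshape(n_rep, -1)
    finite = np.all(np.isfinite(flat), axis=1)
    n_bad = int(n_rep - finite.sum())
    if n_bad > 0.01 * n_rep:
        raise ValueError(
            f"statistic non-finite in {n_bad}/{n_rep} replicates (> 1%)"
        )
    if n_bad:
        logger.warning("dropped %d non-finite replicate(s) of %d", n_bad, n_rep)
        vals = vals[finite]

    mean = vals.mean(axis=0)
    lo50, hi50 = np.percentile(vals, [25, 75], axis=0)
    lo95, hi95 = np.percentile(vals, [2.5, 97.5], axis=0)
    if vals.ndim == 1:
        mean = float(mean)
        lo50, hi50, lo95, hi95 = map(float, (lo50, hi50, lo95, hi95))
    return DerivedStatSummary(mean, (lo50, hi50), (lo95, hi95), n_rep, n_bad)
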