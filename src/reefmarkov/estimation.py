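"""Transition-probability estimation from count matrices.

The transitions out of each source state j are multinomial with probability
vector p_.j (a column of the transition matrix).  With an independent
Dirichlet(alpha0, ..., alpha0) prior on each column, the posterior for column
j is Dirichlet(n_.j + alpha0): conjugacy makes both the posterior mean (the
add-one pseudocount estimate for alpha0 = 1) and exact posterior sampling
trivial.  The classical MLE n_ij / n_.j is kept alongside for likelihood-ratio
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transitions import TransitionCounts

__all__ = [
    "DirichletPosterior",
    "mle_matrix",
    "dirichlet_posterior",
    "posterior_mean_matrix",
    "sample_transition_matrix",
]

#: default seed for stochastic operations when the caller supplies none
DEFAULT_SEED = 20111102


def _check_column_stochastic(P: np.ndarray, tol: float = 1e-12) -> None:
    if np.any(P < -tol) or np.any(P > 1 + tol):
        raise ValueError("transition probabilities must lie in [0, 1]")
    if not np.allclose(P.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("columns of a transition matrix must sum to 1")


def mle_matrix(counts: TransitionCounts) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood transition matrix p_ij = n_ij / n_.j.

    Columns with no observed transitions (n_.j = 0) cannot be estimated and
    are set to the uniform column 1/m.

    Returns
    -------
    P : ndarray, shape (m, m)
        Column-stochastic matrix.
    unobserved : ndarray of bool, shape (m,)
        Flags the source states whose column fell back to uniform.
    """
    n = counts.n.astype(float)
    tot = n.sum(axis=0)
    unobserved = tot == 0
    safe = np.where(unobserved, 1.0, tot)
    P = n / safe
    P[:, unobserved] = 1.0 / counts.m
    return P, unobserved


@dataclass
class DirichletPosterior:
    """Independent Dirichlet posteriors over the columns of a transition matrix.

    ``alpha[:, j]`` holds the Dirichlet parameters n_.j + prior_alpha over
    destination states for source state j.
    """

    alpha: np.ndarray
    prior_alpha: float = 1.0
    labels: tuple[str, ...] = field(default=("A", "B", "C", "D", "E", "F"))

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, float)
        if self.alpha.ndim != 2 or self.alpha.shape[0] != self.alpha.shape[1]:
            raise ValueError("alpha must be a square matrix")
        if np.any(self.alpha <= 0):
            raise ValueError("Dirichlet parameters must be strictly positive")

    @property
    def m(self) -> int:
        return self.alpha.shape[0]

    def mean(self) -> np.ndarray:
        """Posterior-mean transition matrix (add-one pseudocount estimates for
        a uniform prior): p_ij = alpha_ij / sum_k alpha_kj.  Strictly positive."""
        return self.alpha / self.alpha.sum(axis=0, keepdims=True)

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Draw transition matrices from the posterior, column by column.

        Returns shape (m, m) when ``size`` is None, else (size, m, m).  Each
        column is an independent Dirichlet draw (via normalized gammas), so
        every sampled matrix is column-stochastic and almost surely strictly
        positive.
        """
        n = 1 if size is None else int(size)
        P = np.empty((n, self.m, self.m))
        for j in range(self.m):
            g = rng.gamma(self.alpha[:, j], size=(n, self.m))
            P[:, :, j] = g / g.sum(axis=1, keepdims=True)
        return P[0] if size is None else P


def dirichlet_posterior(
    counts: TransitionCounts, prior_alpha: float = 1.0
) -> DirichletPosterior:
    """Conjugate posterior for the transition matrix: alpha_ij = n_ij + prior_alpha."""
    if prior_alpha <= 0:
        raise ValueError(f"prior_alpha must be > 0, got {prior_alpha}")
    return DirichletPosterior(
        counts.n + float(prior_alpha), float(prior_alpha), counts.labels
    )


def posterior_mean_matrix(post: DirichletPosterior) -> np.ndarray:
    """Posterior-mean transition matrix of a :class:`DirichletPosterior`."""
    return post.mean()


def sample_transition_matrix(
    post: DirichletPosterior, rng: np.random.Generator
) -> np.ndarray:
    """One transition matrix drawn from the posterior (see ``DirichletPosterior.sample``)."""
    return post.sample(rng)


def initial_state_posterior(
    state_counts: np.ndarray, prior_alpha: float = 1.0
) -> np.ndarray:
    """Dirichlet posterior parameters for the initial state distribution.

    The state counts in the reference year are multinomial with the initial
    state probabilities; a uniform Dirichlet prior (independent of the
    transition-probability priors) gives posterior Dirichlet(counts + alpha0).
    """
    if prior_alpha <= 0:
        raise ValueError(f"prior_alpha must be > 0, got {prior_alpha}")
    counts = np.asarray(state_counts, float)
    if counts.ndim != 1 or np.any(counts < 0):
        raise ValueError("state counts must be a nonnegative vector")
    return counts + float(prior_alpha)
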