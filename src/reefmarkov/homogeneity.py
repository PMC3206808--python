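"""Likelihood-ratio tests for homogeneity of transition probabilities.

Tests whether K >= 2 subsets of the data (regions, time periods, MPA status)
share one transition matrix.  With per-subset MLEs p_hat(k) and the pooled
MLE p_hat, the statistic

    L = 2 sum_k sum_ij n_ij(k) log[ p_hat_ij(k) / p_hat_ij ]

is asymptotically chi-squared with (K - 1) m (m - 1) degrees of freedom under
the null.  Terms with n_ij(k) = 0 contribute nothing (0 log 0 = 0), and source
columns empty in a subset contribute nothing for that subset; the degrees of
freedom are not reduced for empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .transitions import TransitionCounts

__all__ = ["LRTResult", "pool_counts", "lrt_homogeneity"]


@dataclass
class LRTResult:
    """Result of a likelihood-ratio homogeneity test."""

    statistic: float
    df: int
    p_value: float
    subset_labels: tuple[str, ...]
    subset_pair_counts: tuple[int, ...]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        pairs = ", ".join(
            f"{lab}: {n}" for lab, n in zip(self.subset_labels, self.subset_pair_counts)
        )
        return (
            f"LRT homogeneity: L = {self.statistic:.4f}, df = {self.df}, "
            f"p = {self.p_value:.4g} ({pairs})"
        )


def pool_counts(subsets: list[TransitionCounts]) -> TransitionCounts:
    """Elementwise sum of count matrices (the null-hypothesis pooled counts)."""
    if not subsets:
        raise ValueError("need at least one subset")
    out = subsets[0]
    for s in subsets[1:]:
        out = out + s
    return out


def lrt_homogeneity(
    subsets: list[TransitionCounts], labels: list[str] | None = None
) -> LRTResult:
    """Likelihood-ratio test that all subsets share one transition matrix."""
    K = len(subsets)
    if K < 2:
        raise ValueError("homogeneity test needs at least two subsets")
    for idx, s in enumerate(subsets):
        if s.total == 0:
            raise ValueError(f"subset {idx} has no observed transitions")
    pooled = pool_counts(subsets)
    m = pooled.m

    def _mle(counts: TransitionCounts) -> np.ndarray:
        n = counts.n.astype(float)
        tot = n.sum(axis=0)
        return n / np.where(tot > 0, tot, 1.0)

    p_pool = _mle(pooled)
    L = 0.0
    for s in subsets:
        p_k = _mle(s)
        mask = s.n > 0  # 0 * log(.) = 0 convention
        L += 2.0 * float(np.sum(s.n[mask] * np.log(p_k[mask] / p_pool[mask])))
    df = (K - 1) * m * (m - 1)
    p_value = float(chi2.sf(L, df))
    if labels is None:
        labels = [f"subset{k}" for k in range(K)]
    return LRTResult(
        statistic=float(L),
        df=df,
        p_value=p_value,
        subset_labels=tuple(labels),
        subset_pair_counts=tuple(s.total for s in subsets),
    )
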