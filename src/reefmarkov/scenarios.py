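"""Environmental-change scenarios via a baseline-category logit perturbation.

The response of a transition-probability column to an abstract environmental
variable x (negative = unfavourable to coral, e.g. warming; positive =
favourable, e.g. increased herbivory) is modelled as a baseline-category logit
with persistence in the source state as the baseline:

    log[ p_ij(x) / p_jj(x) ] = alpha_ij + beta_ij x,   alpha_jj = beta_jj = 0.

Intercepts alpha_ij = log(p0_ij / p0_jj) reproduce the current matrix at
x = 0 exactly.  The slopes beta_ij are +-1 or 0 according to whether the move
from source state j to destination state i raises or lowers coral and algal
cover (a sign table over the two cover changes); their magnitude is arbitrary
since x itself is unitless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import stationary_distribution
from .estimation import DirichletPosterior
from .states import StateScheme
from .surveys import CoverSummary

__all__ = ["build_beta_matrix", "scenario_matrix", "ScenarioCurve", "scenario_curve"]

# beta as a function of (sign of coral-cover change, sign of algal-cover change),
# signs indexed -1, 0, +1
_SIGN_TABLE = {
    (-1, -1): 0, (-1, 0): -1, (-1, 1): -1,
    (0, -1): 1, (0, 0): 0, (0, 1): -1,
    (1, -1): 1, (1, 0): 1, (1, 1): 0,
}


def _interval_sign(src: tuple[float, float], dst: tuple[float, float], rule: str) -> int:
    """Sign of the cover change from a source to a destination interval.

    ``dominance``: +1 only if the destination interval lies entirely at or
    above the source interval (dest lower bound >= source upper bound), -1 for
    the reverse, 0 if the intervals overlap.  ``midpoint``: sign of the
    difference of interval midpoints.
    """
    if rule == "dominance":
        if dst[0] >= src[1]:
            return 1
        if dst[1] <= src[0]:
            return -1
        return 0
    if rule == "midpoint":
        ds = (dst[0] + dst[1]) / 2 - (src[0] + src[1]) / 2
        return int(np.sign(ds))
    raise ValueError(f"unknown comparison rule {rule!r}")


def build_beta_matrix(
    scheme: StateScheme | None = None,
    magnitude: float = 1.0,
    comparison: str = "dominance",
) -> np.ndarray:
    """Slope matrix beta (destination i, source j) from the state-cover geometry.

    For each ordered pair j -> i the signs of the coral and algal cover
    changes are read off the state intervals (see ``_interval_sign``) and
    mapped through the sign table; diagonal entries are zero by construction.
    """
    scheme = scheme or StateScheme()
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    m = scheme.m
    beta = np.zeros((m, m))
    for j in range(m):
        for i in range(m):
            if i == j:
                continue
            sc = _interval_sign(scheme.coral_interval(j), scheme.coral_interval(i), comparison)
            sa = _interval_sign(scheme.algae_interval(j), scheme.algae_interval(i), comparison)
            beta[i, j] = _SIGN_TABLE[(sc, sa)] * magnitude
    return beta


def scenario_matrix(P0: np.ndarray, beta: np.ndarray, x: float) -> np.ndarray:
    """Transition matrix at environmental condition x.

    ``P0`` must be strictly positive (posterior draws and posterior means
    always are); a zero entry makes the logit intercept undefined.
    At x = 0 the input matrix is returned exactly.
    """
    P0 = np.asarray(P0, float)
    if np.any(P0 <= 0):
        raise ValueError(
            "scenario_matrix requires a strictly positive matrix; use posterior "
            "draws or posterior means, which are positive by construction"
        )
    logits = np.log(P0 / np.diag(P0)[None, :]) + np.asarray(beta, float) * x
    ex = np.exp(logits - logits.max(axis=0, keepdims=True))
    return ex / ex.sum(axis=0, keepdims=True)


def _stationary_stack(Ps: np.ndarray) -> np.ndarray:
    """Stationary distributions of a stack of positive column-stochastic matrices."""
    eigvals, eigvecs = np.linalg.eig(Ps)
    k = np.argmin(np.abs(eigvals - 1.0), axis=1)
    v = np.real(np.take_along_axis(eigvecs, k[:, None, None], axis=2)[:, :, 0])
    v = v / v.sum(axis=1, keepdims=True)
    return np.clip(v, 0.0, None) / np.clip(v, 0.0, None).sum(axis=1, keepdims=True)


@dataclass
class ScenarioCurve:
    """Posterior summaries of equilibrium quantities along the scenario axis.

    ``coral``, ``algae``: dicts with keys mean/lo50/hi50/lo95/hi95, each an
    array over ``x_grid`` (percent cover).  ``states``: same keys with arrays
    of shape (len(x_grid), m) of equilibrium state probabilities.
    """

    x_grid: np.ndarray
    coral: dict[str, np.ndarray]
    algae: dict[str, np.ndarray]
    states: dict[str, np.ndarray]
    n_rep: int
    labels: tuple[str, ...] = field(default=("A", "B", "C", "D", "E", "F"))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (x, statistic)."""
        rows = []
        for name, d in (("coral", self.coral), ("algae", self.algae)):
            for k, x in enumerate(self.x_grid):
                rows.append(
                    dict(x=x, statistic=name, mean=d["mean"][k],
                         lo50=d["lo50"][k], hi50=d["hi50"][k],
                         lo95=d["lo95"][k], hi95=d["hi95"][k])
                )
        for i, lab in enumerate(self.labels):
            for k, x in enumerate(self.x_grid):
                rows.append(
                    dict(x=x, statistic=f"pi_{lab}", mean=self.states["mean"][k, i],
                         lo50=self.states["lo50"][k, i], hi50=self.states["hi50"][k, i],
                         lo95=self.states["lo95"][k, i], hi95=self.states["hi95"][k, i])
                )
        return pd.DataFrame(rows)


def scenario_curve(
    trans_post: DirichletPosterior,
    covers: CoverSummary,
    beta: np.ndarray | None = None,
    x_grid: np.ndarray | None = None,
    n_rep: int = 10000,
    rng: np.random.Generator | None = None,
) -> ScenarioCurve:
    """Posterior scenario response of equilibrium state and cover distributions.

    For each posterior replicate, the drawn transition matrix is transformed
    by the logit model at every x in ``x_grid`` (default 41 points on
    [-2, 2]); the stationary distribution and the equilibrium coral and algal
    cover are computed, then summarized across replicates per x (mean, 50%
    and 95% equal-tailed intervals).  The intercepts are recomputed for every
    draw, so the bands carry the full posterior uncertainty.
    """
    rng = np.random.default_rng() if rng is None else rng
    if beta is None:
        beta = build_beta_matrix(covers.scheme)
    beta = np.asarray(beta, float)
    if x_grid is None:
        x_grid = np.linspace(-2.0, 2.0, 41)
    x_grid = np.asarray(x_grid, float)
    m = trans_post.m

    Ps = trans_post.sample(rng, size=n_rep)  # (n_rep, m, m)
    logit0 = np.log(Ps / np.einsum("rii->ri", Ps)[:, None, :])
    pis = np.empty((n_rep, len(x_grid), m))
    for k, x in enumerate(x_grid):
        logits = logit0 + beta[None, :, :] * x
        ex = np.exp(logits - logits.max(axis=1, keepdims=True))
        Px = ex / ex.sum(axis=1, keepdims=True)
        pis[:, k, :] = _stationary_stack(Px)
    qc = pis @ covers.c
    qa = pis @ covers.a

    def _summ(vals: np.ndarray) -> dict[str, np.ndarray]:
        lo50, hi50, lo95, hi95 = np.percentile(vals, [25, 75, 2.5, 97.5], axis=0)
        return dict(mean=vals.mean(axis=0), lo50=lo50, hi50=hi50, lo95=lo95, hi95=hi95)

    return ScenarioCurve(
        x_grid=x_grid,
        coral=_summ(qc),
        algae=_summ(qa),
        states=_summ(pis),
        n_rep=n_rep,
        labels=tuple(covers.scheme.labels),
    )
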