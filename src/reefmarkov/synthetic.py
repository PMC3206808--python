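"""Synthetic reef-survey generator with the statistical structure the
Markov analysis assumes.

Each reef is an independent realization of the same first-order Markov chain
on the discrete reef states; covers are drawn uniformly within the generating
state's cell (clipped to coral + algae <= 100), so classifying a generated
observation always recovers the generating state.  Survey designs mimic the
two study regions: a Caribbean-like design with few observations per reef
(median 2, range 2-7) and a GBR-like design with long annual series
(median 9, range 2-11), both over 1996-2006, with configurable per-year
dropout producing gap years.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import load_caribbean_counts, load_gbr_counts
from .estimation import dirichlet_posterior
from .dynamics import stationary_distribution
from .states import StateScheme

__all__ = ["TrueModel", "SurveyDesign", "make_true_model", "simulate_surveys"]


@dataclass
class TrueModel:
    """Ground truth for simulation: transition matrix, initial distribution, scheme."""

    P_true: np.ndarray
    init: np.ndarray
    scheme: StateScheme = field(default_factory=StateScheme)

    def __post_init__(self) -> None:
        self.P_true = np.asarray(self.P_true, float)
        m = self.scheme.m
        if self.P_true.shape != (m, m):
            raise ValueError(f"P_true must be {m}x{m}")
        if np.any(self.P_true < 0) or not np.allclose(self.P_true.sum(axis=0), 1.0):
            raise ValueError("P_true must be column-stochastic")
        self.init = np.asarray(self.init, float)
        if len(self.init) != m or np.any(self.init < 0) or not np.isclose(self.init.sum(), 1.0):
            raise ValueError("init must be a probability vector of length m")

    def sample_cover(self, state: int, rng: np.random.Generator) -> tuple[float, float]:
        """Uniform (coral, algae) within the state's clipped cell, by rejection."""
        clo, chi = self.scheme.coral_interval(state)
        alo, ahi = self.scheme.algae_interval(state)
        while True:
            c = rng.uniform(clo, chi)
            a = rng.uniform(alo, ahi)
            if c + a <= 100 and int(self.scheme.classify_index(c, a)) == state:
                return c, a

    def to_manifest(self) -> dict:
        return {
            "P_true": self.P_true.tolist(),
            "init": self.init.tolist(),
            "labels": list(self.scheme.labels),
            "boundaries": list(self.scheme.boundaries),
        }


@dataclass
class SurveyDesign:
    """Observation design: how many reefs, when, and how often they are surveyed.

    ``obs_per_reef`` maps a number of survey years per reef (the span of a
    consecutive run before dropout) to its probability; every reef retains at
    least two observations.  ``dropout`` is the independent probability that
    each year after a reef's first observed year is missing, creating gap
    years like those in real monitoring series.
    """

    n_reefs: int
    year_range: tuple[int, int] = (1996, 2006)
    obs_per_reef: dict[int, float] = field(default_factory=lambda: {2: 1.0})
    dropout: float = 0.1
    mpa_fraction: float = 0.65
    region: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_reefs < 1:
            raise ValueError("need at least one reef")
        if min(self.obs_per_reef) < 2:
            raise ValueError("every reef needs at least 2 observations")
        tot = sum(self.obs_per_reef.values())
        if not np.isclose(tot, 1.0):
            self.obs_per_reef = {k: v / tot for k, v in self.obs_per_reef.items()}
        span = self.year_range[1] - self.year_range[0] + 1
        if max(self.obs_per_reef) > span:
            raise ValueError("obs_per_reef exceeds the year range")

    @classmethod
    def caribbean_like(cls, n_reefs: int = 69) -> "SurveyDesign":
        """Short survey series: median 2 observations per reef, range 2-7."""
        return cls(
            n_reefs=n_reefs,
            obs_per_reef={2: 0.60, 3: 0.15, 4: 0.10, 5: 0.07, 6: 0.05, 7: 0.03},
            mpa_fraction=0.65,
            region="caribbean-like",
        )

    @classmethod
    def gbr_like(cls, n_reefs: int = 55) -> "SurveyDesign":
        """Long annual series: median 9 observations per reef, range 2-11."""
        return cls(
            n_reefs=n_reefs,
            obs_per_reef={2: 0.05, 3: 0.05, 4: 0.05, 5: 0.05, 6: 0.05,
                          7: 0.05, 8: 0.10, 9: 0.25, 10: 0.20, 11: 0.15},
            mpa_fraction=0.96,
            region="gbr-like",
        )


def make_true_model(
    preset: str = "caribbean-like",
    rng: np.random.Generator | None = None,
    P: np.ndarray | None = None,
    scheme: StateScheme | None = None,
) -> TrueModel:
    """Ground-truth model for a preset or a custom transition matrix.

    The regional presets use the add-one posterior-mean matrices computed from
    the packaged count tables as truth, with the matrix's own stationary
    distribution as the initial state distribution (both regions were observed
    close to equilibrium).  ``preset="custom"`` requires an explicit
    column-stochastic ``P``.
    """
    scheme = scheme or StateScheme()
    if preset == "caribbean-like":
        P = dirichlet_posterior(load_caribbean_counts()).mean()
    elif preset == "gbr-like":
        P = dirichlet_posterior(load_gbr_counts()).mean()
    elif preset == "custom":
        if P is None:
            raise ValueError("custom preset requires a transition matrix P")
        P = np.asarray(P, float)
        if np.any(P < 0) or not np.allclose(P.sum(axis=0), 1.0):
            raise ValueError("custom P must be column-stochastic")
    else:
        raise ValueError(f"unknown preset {preset!r}")
    try:
        init = stationary_distribution(P)
    except ValueError:
        init = np.full(scheme.m, 1.0 / scheme.m)  # reducible custom truth
    return TrueModel(P, init, scheme)


def simulate_surveys(
    model: TrueModel, design: SurveyDesign, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate a survey table (reef, year, coral, algae, mpa, region).

    Per reef: the initial state is drawn from ``model.init``; the state then
    evolves annually by ``model.P_true`` over a consecutive run of years whose
    length is drawn from ``design.obs_per_reef``; each year after the first is
    independently dropped with probability ``design.dropout`` (at least two
    observations are always retained); covers are drawn uniformly within the
    state cell.
    """
    m = model.scheme.m
    spans = np.array(sorted(design.obs_per_reef))
    probs = np.array([design.obs_per_reef[s] for s in spans])
    y0, y1 = design.year_range
    rows = []
    for r in range(design.n_reefs):
        span = int(rng.choice(spans, p=probs))
        start = int(rng.integers(y0, y1 - span + 2))
        states = np.empty(span, int)
        states[0] = rng.choice(m, p=model.init)
        for t in range(1, span):
            states[t] = rng.choice(m, p=model.P_true[:, states[t - 1]])
        keep = np.ones(span, bool)
        if design.dropout > 0 and span > 2:
            keep[1:] = rng.random(span - 1) >= design.dropout
            if keep.sum() < 2:  # retain at least two observations
                keep[:2] = True
        mpa = bool(rng.random() < design.mpa_fraction)
        for t in np.flatnonzero(keep):
            coral, algae = model.sample_cover(int(states[t]), rng)
            rows.append(
                dict(reef=f"{design.region}-{r:04d}", year=start + int(t),
                     coral=coral, algae=algae, mpa=mpa, region=design.region)
            )
    return pd.DataFrame(rows)


def write_manifest(path, model: TrueModel, design: SurveyDesign, seed: int) -> None:
    """Record the simulation truth (matrix, design, seed) for recovery tests."""
    manifest = {
        "truth": model.to_manifest(),
        "design": {
            "n_reefs": design.n_reefs,
            "year_range": list(design.year_range),
            "obs_per_reef": {str(k): v for k, v in design.obs_per_reef.items()},
            "dropout": design.dropout,
            "mpa_fraction": design.mpa_fraction,
            "region": design.region,
        },
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
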