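"""Reading, validating, pooling and classifying reef survey tables.

Surveys are held as pandas DataFrames with the canonical columns ``reef``,
``year``, ``coral``, ``algae`` plus optional ``lat``, ``lon``, ``mpa`` and
``region``.  Each row is one observation of percent hard-coral and macroalgal
cover on one reef in one calendar year.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .states import FEASIBILITY_TOL, StateScheme

__all__ = [
    "REQUIRED_COLUMNS",
    "read_surveys",
    "validate_surveys",
    "pool_to_reef_year",
    "classify_surveys",
    "state_cover_means",
    "year_state_counts",
    "CoverSummary",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("reef", "year", "coral", "algae")
OPTIONAL_COLUMNS = ("lat", "lon", "mpa", "region")


class SurveyFormatError(ValueError):
    """Input table does not have the required structure."""


class SurveyValidationError(ValueError):
    """Rows violate the cover invariants."""


def read_surveys(path, dialect: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited survey table into a validated DataFrame.

    Parameters
    ----------
    path : str or Path
        CSV or TSV file with a header row (delimiter chosen by extension:
        ``.tsv``/``.tab`` means tab, anything else comma).
    dialect : dict, optional
        Mapping from canonical column names (``reef``, ``year``, ``coral``,
        ``algae``, ``lat``, ``lon``, ``mpa``, ``region``) to the column names
        used in the file.

    Returns
    -------
    DataFrame with canonical columns, one row per observation.

    Raises
    ------
    SurveyFormatError
        If a required column is missing.
    SurveyValidationError
        If any row has covers outside [0, 100] or coral + algae > 100
        (tolerance 1e-6); the message names the offending rows.
    """
    sep = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    keep = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep].copy()
    df["year"] = df["year"].astype(int)
    df["coral"] = df["coral"].astype(float)
    df["algae"] = df["algae"].astype(float)
    validate_surveys(df)
    return df


def validate_surveys(df: pd.DataFrame) -> None:
    """Check the cover invariants, reporting row indices of violations."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"missing required column(s) {missing}")
    coral = df["coral"].to_numpy(float)
    algae = df["algae"].to_numpy(float)
    bad = (
        (coral < 0)
        | (coral > 100)
        | (algae < 0)
        | (algae > 100)
        | (coral + algae > 100 + FEASIBILITY_TOL)
        | ~np.isfinite(coral)
        | ~np.isfinite(algae)
    )
    if bad.any():
        rows = df.index[bad].tolist()
        detail = df.loc[bad, ["reef", "year", "coral", "algae"]].head(10)
        raise SurveyValidationError(
            f"{bad.sum()} row(s) violate cover invariants (0 <= cover <= 100, "
            f"coral + algae <= 100) at index {rows[:20]}:\n{detail}"
        )


def pool_to_reef_year(df: pd.DataFrame) -> pd.DataFrame:
    """Pool replicate observations into one mean record per (reef, year).

    Coral and algae covers are unweighted arithmetic means over the replicates;
    metadata (lat, lon, mpa, region) is taken from the first record of each
    group, with a warning if MPA flags conflict within a group.  Idempotent.
    """
    if df.empty:
        return df.copy()
    agg: dict = {"coral": "mean", "algae": "mean"}
    for c in OPTIONAL_COLUMNS:
        if c in df.columns:
            agg[c] = "first"
    if "mpa" in df.columns:
        conflicts = (
            df.dropna(subset=["mpa"]).groupby(["reef", "year"])["mpa"].nunique()
        )
        n_bad = int((conflicts > 1).sum())
        if n_bad:
            warnings.warn(
                f"{n_bad} (reef, year) group(s) have conflicting MPA flags; "
                "keeping the first value of each group",
                stacklevel=2,
            )
    out = df.groupby(["reef", "year"], as_index=False, sort=True).agg(agg)
    return out


def classify_surveys(df: pd.DataFrame, scheme: StateScheme | None = None) -> pd.DataFrame:
    """Append a ``state`` column of state labels to a survey table."""
    scheme = scheme or StateScheme()
    out = df.copy()
    if len(out):
        out["state"] = scheme.classify(out["coral"].to_numpy(), out["algae"].to_numpy())
    else:
        out["state"] = pd.Series([], dtype=str)
    return out


class CoverSummary:
    """Mean percent cover of coral and macroalgae within each state.

    Attributes
    ----------
    c, a : ndarray, shape (m,)
        Mean coral / macroalgal cover per state.  States with no observations
        fall back to the centroid of the state cell clipped to the feasible
        triangle; ``fallback`` marks where this approximation was used.
    n_obs : ndarray of int, shape (m,)
        Number of observations per state.
    """

    def __init__(self, c, a, n_obs, scheme: StateScheme, fallback=None):
        self.c = np.asarray(c, float)
        self.a = np.asarray(a, float)
        self.n_obs = np.asarray(n_obs, int)
        self.scheme = scheme
        self.fallback = (
            np.zeros(scheme.m, bool) if fallback is None else np.asarray(fallback, bool)
        )
        if not (len(self.c) == len(self.a) == len(self.n_obs) == scheme.m):
            raise ValueError("cover summary length mismatch with scheme")

    @classmethod
    def from_centroids(cls, scheme: StateScheme | None = None) -> "CoverSummary":
        """Cover summary using only the clipped-cell centroids (no data)."""
        scheme = scheme or StateScheme()
        cents = [scheme.cell_centroid(i) for i in range(scheme.m)]
        c = [x for x, _ in cents]
        a = [y for _, y in cents]
        return cls(c, a, np.zeros(scheme.m, int), scheme, np.ones(scheme.m, bool))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": list(self.scheme.labels),
                "c": self.c,
                "a": self.a,
                "n_obs": self.n_obs,
                "fallback": self.fallback,
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CoverSummary(\n{self.to_frame()}\n)"


def state_cover_means(df: pd.DataFrame, scheme: StateScheme | None = None) -> CoverSummary:
    """Mean coral and macroalgal cover per state, from classified surveys.

    Empty input is an error.  States with no observations get the centroid of
    their clipped cell as a documented fallback, flagged in the result.
    """
    scheme = scheme or StateScheme()
    if df.empty:
        raise ValueError("cannot compute cover means from an empty survey table")
    if "state" not in df.columns:
        df = classify_surveys(df, scheme)
    c = np.empty(scheme.m)
    a = np.empty(scheme.m)
    n_obs = np.zeros(scheme.m, int)
    fallback = np.zeros(scheme.m, bool)
    grouped = df.groupby("state")
    for i, lab in enumerate(scheme.labels):
        if lab in grouped.groups:
            g = grouped.get_group(lab)
            c[i] = g["coral"].mean()
            a[i] = g["algae"].mean()
            n_obs[i] = len(g)
        else:
            c[i], a[i] = scheme.cell_centroid(i)
            fallback[i] = True
            logger.info("state %s has no observations; using cell centroid", lab)
    return CoverSummary(c, a, n_obs, scheme, fallback)


def year_state_counts(
    df: pd.DataFrame,
    year: int,
    scheme: StateScheme | None = None,
    allow_empty: bool = False,
) -> np.ndarray:
    """Number of reefs in each state in a given calendar year.

    Input must be pooled to one record per (reef, year).  A year absent from
    the data raises an error listing the available years, unless
    ``allow_empty`` is set, in which case a zero vector is returned.
    """
    scheme = scheme or StateScheme()
    sub = df[df["year"] == year]
    if sub.empty and not allow_empty:
        avail = sorted(df["year"].unique().tolist())
        raise ValueError(f"no surveys in year {year}; available years: {avail}")
    if sub["reef"].duplicated().any():
        raise ValueError("surveys must be pooled to one record per (reef, year)")
    if "state" not in sub.columns:
        sub = classify_surveys(sub, scheme)
    counts = np.zeros(scheme.m, int)
    for i, lab in enumerate(scheme.labels):
        counts[i] = int((sub["state"] == lab).sum())
    return counts
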