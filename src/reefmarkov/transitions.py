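"""Transition-count matrices from consecutive-year state pairs.

Orientation convention, fixed throughout the package: **columns are source
states, rows are destination states** — entry ``n[i, j]`` counts reefs that
were in state j in year t and state i in year t+1.  All CSV I/O writes an
explicit ``# source=columns`` header line to prevent transpose mistakes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import StateScheme
from .surveys import classify_surveys

__all__ = ["TransitionCounts", "count_transitions"]


@dataclass
class TransitionCounts:
    """m x m matrix of observed annual transitions (columns = source state)."""

    n: np.ndarray
    labels: tuple[str, ...] = field(default=("A", "B", "C", "D", "E", "F"))

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n)
        if self.n.ndim != 2 or self.n.shape[0] != self.n.shape[1]:
            raise ValueError(f"counts must be square, got shape {self.n.shape}")
        if np.any(self.n < 0) or not np.all(np.equal(np.mod(self.n, 1), 0)):
            raise ValueError("counts must be nonnegative integers")
        self.n = self.n.astype(np.int64)
        self.labels = tuple(self.labels)
        if len(self.labels) != self.n.shape[0]:
            raise ValueError("label count does not match matrix dimension")

    @property
    def m(self) -> int:
        return self.n.shape[0]

    @property
    def column_totals(self) -> np.ndarray:
        """Number of observed transitions out of each source state."""
        return self.n.sum(axis=0)

    @property
    def total(self) -> int:
        """Grand total: the number of consecutive-year observation pairs."""
        return int(self.n.sum())

    def __add__(self, other: "TransitionCounts") -> "TransitionCounts":
        if self.n.shape != other.n.shape or self.labels != other.labels:
            raise ValueError("cannot add counts with different state schemes")
        return TransitionCounts(self.n + other.n, self.labels)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TransitionCounts)
            and self.labels == other.labels
            and np.array_equal(self.n, other.n)
        )

    # ------------------------------------------------------------------
    # CSV I/O in the layout of the published tables:
    # rows = destination states, columns = source states, final Total row.
    # ------------------------------------------------------------------
    def to_csv(self, path_or_buf) -> None:
        df = pd.DataFrame(self.n, index=list(self.labels), columns=list(self.labels))
        df.loc["Total"] = self.column_totals
        text = "# source=columns\n" + df.to_csv(index_label="state")
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf) -> "TransitionCounts":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
        df = pd.read_csv(io.StringIO("\n".join(lines)), index_col=0)
        df.index = df.index.astype(str)
        if "Total" in df.index:
            body = df.drop(index="Total")
            if not np.array_equal(
                body.to_numpy().sum(axis=0), df.loc["Total"].to_numpy()
            ):
                raise ValueError("Total row does not match column sums")
            df = body
        labels = tuple(str(c) for c in df.columns)
        if tuple(df.index) != labels:
            raise ValueError(
                f"row labels {tuple(df.index)} != column labels {labels}"
            )
        return cls(df.to_numpy(), labels)


def count_transitions(
    df: pd.DataFrame, scheme: StateScheme | None = None
) -> TransitionCounts:
    """Count state transitions between consecutive calendar years per reef.

    Input must be pooled to one record per (reef, year).  Only strictly
    consecutive years form a pair: a reef observed in years t and t+2 with a
    gap contributes nothing, while years t, t+1, t+2 contribute two pairs.
    Empty input yields the zero matrix.
    """
    scheme = scheme or StateScheme()
    n = np.zeros((scheme.m, scheme.m), np.int64)
    if df.empty:
        return TransitionCounts(n, scheme.labels)
    if df.duplicated(subset=["reef", "year"]).any():
        raise ValueError("surveys must be pooled to one record per (reef, year)")
    if "state" not in df.columns:
        df = classify_surveys(df, scheme)
    idx = {lab: i for i, lab in enumerate(scheme.labels)}
    for _, g in df.groupby("reef"):
        g = g.sort_values("year")
        years = g["year"].to_numpy()
        states = g["state"].to_numpy()
        consec = np.diff(years) == 1
        for k in np.flatnonzero(consec):
            n[idx[states[k + 1]], idx[states[k]]] += 1
    return TransitionCounts(n, scheme.labels)
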