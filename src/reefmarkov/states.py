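"""Discrete reef states defined by joint intervals of coral and macroalgal cover.

A reef observation is a point (coral %, algae %) in the feasible triangle
{coral >= 0, algae >= 0, coral + algae <= 100}.  The default scheme carves the
triangle into six states A-F using cover boundaries at 25% and 50%:

=====  ===========  ============
state  % coral      % macroalgae
=====  ===========  ============
A      <= 25        <= 25
B      <= 25        25-50
C      <= 50        > 50
D      25-50        <= 25
E      25-50        25-50
F      > 50         <= 50
=====  ===========  ============

Intervals follow the convention that the lower category is closed at a shared
boundary: "<= 25" is [0, 25], "25-50" is (25, 50], "> 50" is (50, 100].  The
boundaries are configurable (for sensitivity analyses), subject to the
constraint that the cells still partition the feasible triangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, box

__all__ = ["StateScheme", "FEASIBILITY_TOL"]

#: tolerance on coral + algae <= 100, absorbing rounding in source tables
FEASIBILITY_TOL = 1e-6

_DEFAULT_LABELS = ("A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class StateScheme:
    """Six-state classification of (coral, algae) cover with configurable boundaries.

    Parameters
    ----------
    b1, b2 : float
        The two cover boundaries in percent (defaults 25 and 50).  ``b2`` is the
        "domination" threshold and must be >= 50 so that the six cells partition
        the feasible triangle (if algae > b2 then coral <= 100 - b2 <= b2, and
        symmetrically for coral).
    labels : tuple of str
        Ordered state names, low-cover state first.
    """

    b1: float = 25.0
    b2: float = 50.0
    labels: tuple[str, ...] = field(default=_DEFAULT_LABELS)

    def __post_init__(self) -> None:
        if not (0 < self.b1 < self.b2):
            raise ValueError(f"require 0 < b1 < b2, got b1={self.b1}, b2={self.b2}")
        if self.b2 < 50:
            raise ValueError(
                f"b2={self.b2} < 50 breaks the partition: points with both covers "
                "above b2 would be feasible but unclassifiable"
            )
        if len(self.labels) != 6:
            raise ValueError("exactly six state labels required")

    @property
    def m(self) -> int:
        """Number of states."""
        return len(self.labels)

    @property
    def boundaries(self) -> tuple[float, float]:
        return (self.b1, self.b2)

    # ------------------------------------------------------------------
    # cell geometry
    # ------------------------------------------------------------------
    def coral_interval(self, state: int | str) -> tuple[float, float]:
        """Closure [lo, hi] of the coral-cover interval of a state."""
        i = self._index(state)
        b1, b2 = self.b1, self.b2
        return [(0, b1), (0, b1), (0, b2), (b1, b2), (b1, b2), (b2, 100)][i]

    def algae_interval(self, state: int | str) -> tuple[float, float]:
        """Closure [lo, hi] of the macroalgal-cover interval of a state."""
        i = self._index(state)
        b1, b2 = self.b1, self.b2
        return [(0, b1), (b1, b2), (b2, 100), (0, b1), (b1, b2), (0, b2)][i]

    def _index(self, state: int | str) -> int:
        if isinstance(state, str):
            return self.labels.index(state)
        return int(state)

    # ------------------------------------------------------------------
    # classification
    # ------------------------------------------------------------------
    def validate_feasible(self, coral, algae) -> None:
        coral = np.asarray(coral, float)
        algae = np.asarray(algae, float)
        bad = (
            (coral < 0)
            | (algae < 0)
            | (coral > 100)
            | (algae > 100)
            | (coral + algae > 100 + FEASIBILITY_TOL)
        )
        if np.any(bad):
            idx = np.flatnonzero(np.atleast_1d(bad))
            raise ValueError(
                f"infeasible cover at positions {idx.tolist()}: require "
                "0 <= coral, algae and coral + algae <= 100"
            )

    def classify_index(self, coral, algae) -> np.ndarray:
        """Classify cover pairs into state indices 0..5 (vectorized).

        Raises ``ValueError`` for infeasible points.  Boundary convention: the
        lower category keeps a shared boundary, e.g. coral = b1 is "low" and
        coral = b2 is "mid".
        """
        coral = np.asarray(coral, float)
        algae = np.asarray(algae, float)
        self.validate_feasible(coral, algae)
        b1, b2 = self.b1, self.b2
        out = np.empty(np.broadcast(coral, algae).shape, dtype=np.intp)
        high_a = algae > b2          # state C
        high_c = (coral > b2) & ~high_a  # state F
        low_c = coral <= b1
        low_a = algae <= b1
        rest = ~(high_a | high_c)
        out[high_a] = 2
        out[high_c] = 5
        out[rest & low_c & low_a] = 0      # A
        out[rest & low_c & ~low_a] = 1     # B
        out[rest & ~low_c & low_a] = 3     # D
        out[rest & ~low_c & ~low_a] = 4    # E
        return out

    def classify(self, coral, algae):
        """Classify cover pairs into state labels.

        Scalar inputs return a single label string; array inputs return an
        array of labels.
        """
        idx = self.classify_index(coral, algae)
        labels = np.asarray(self.labels)
        if idx.ndim == 0:
            return str(labels[idx])
        return labels[idx]

    # ------------------------------------------------------------------
    # cell centroids (fallback covers for states with no observations)
    # ------------------------------------------------------------------
    def cell_polygon(self, state: int | str) -> Polygon:
        """State cell clipped to the feasible triangle, as a shapely polygon."""
        clo, chi = self.coral_interval(state)
        alo, ahi = self.algae_interval(state)
        triangle = Polygon([(0, 0), (100, 0), (0, 100)])
        return box(clo, alo, chi, ahi).intersection(triangle)

    def cell_centroid(self, state: int | str) -> tuple[float, float]:
        """Centroid (coral, algae) of the clipped state cell."""
        c = self.cell_polygon(state).centroid
        return (c.x, c.y)
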