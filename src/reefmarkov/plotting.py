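"""Band plots of posterior projections and scenario curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # noqa: E402 - headless use
import matplotlib.pyplot as plt
import pandas as pd

from .scenarios import ScenarioCurve

__all__ = ["plot_projection", "plot_scenario"]


def _band(ax, x, d, color="C0"):
    ax.fill_between(x, d["lo95"], d["hi95"], color=color, alpha=0.2, lw=0)
    ax.fill_between(x, d["lo50"], d["hi50"], color=color, alpha=0.4, lw=0)
    ax.plot(x, d["mean"], color="k", lw=1.5)


def plot_projection(frame: pd.DataFrame, statistic: str, ax=None):
    """Posterior mean with 50%/95% bands for one statistic of a projection frame."""
    sub = frame[frame["statistic"] == statistic].sort_values("year")
    if sub.empty:
        raise ValueError(f"statistic {statistic!r} not in frame")
    if ax is None:
        _, ax = plt.subplots()
    _band(ax, sub["year"], sub)
    ax.set_xlabel("year")
    ax.set_ylabel(statistic)
    return ax


def plot_scenario(curve: ScenarioCurve, which: str = "coral", ax=None):
    """Equilibrium cover response to the environmental continuum with bands."""
    d = {"coral": curve.coral, "algae": curve.algae}[which]
    if ax is None:
        _, ax = plt.subplots()
    _band(ax, curve.x_grid, d)
    ax.set_xlabel("environmental condition x")
    ax.set_ylabel(f"equilibrium {which} cover (%)")
    return ax
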