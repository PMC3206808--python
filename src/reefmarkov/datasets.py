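"""Packaged transition-count tables for the Caribbean and Great Barrier Reef.

The two 6x6 matrices of observed annual transitions between reef states
(columns = source states) from the 1996-2006 monitoring compilation:
100 consecutive-year observation pairs on 69 Caribbean reefs and 374 pairs
on 55 Great Barrier Reef reefs.
"""

from importlib import resources

from .transitions import TransitionCounts

__all__ = ["load_caribbean_counts", "load_gbr_counts"]


def _load(name: str) -> TransitionCounts:
    ref = resources.files("reefmarkov.data").joinpath(name)
    with ref.open() as fh:
        return TransitionCounts.from_csv(fh)


def load_caribbean_counts() -> TransitionCounts:
    """Observed annual reef-state transition counts for the Caribbean (100 pairs)."""
    return _load("caribbean_counts.csv")


def load_gbr_counts() -> TransitionCounts:
    """Observed annual reef-state transition counts for the Great Barrier Reef (374 pairs)."""
    return _load("gbr_counts.csv")
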