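"""Gel-band quantification arithmetic and fold-change reporting.

Band intensities are densitometry values in arbitrary units; only ratios
matter, so every quantity here is invariant to rescaling a whole lane.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GelLaneQuant",
    "ReleaseQuant",
    "percent_cleaved",
    "fraction_released",
    "fold_change",
]


@dataclass(frozen=True)
class GelLaneQuant:
    """Band intensities of one plasmid-cleavage gel lane."""

    linear: float
    nicked: float
    supercoiled: float

    def __post_init__(self):
        if min(self.linear, self.nicked, self.supercoiled) < 0:
            raise ValueError("band intensities must be >= 0")


@dataclass(frozen=True)
class ReleaseQuant:
    """Released versus enzyme-bound product bands on a native gel."""

    released: float
    bound: float

    def __post_init__(self):
        if min(self.released, self.bound) < 0:
            raise ValueError("band intensities must be >= 0")


def percent_cleaved(lane: GelLaneQuant) -> float:
    """Linear product as a percentage of total plasmid DNA in the lane.

    100 * linear / (linear + nicked + supercoiled).
    """
    total = lane.linear + lane.nicked + lane.supercoiled
    if total == 0:
        raise ValueError("all-zero lane: percent cleaved is undefined")
    # divide before scaling so the result cannot exceed 100 by roundoff
    return 100.0 * (lane.linear / total)


def fraction_released(q: ReleaseQuant) -> float:
    """released / (released + bound), in [0, 1]."""
    total = q.released + q.bound
    if total == 0:
        raise ValueError("released + bound must be > 0")
    return q.released / total


def fold_change(a: float, b: float) -> float:
    """Ratio a/b of two rate constants (dimensionless)."""
    if b == 0:
        raise ValueError("cannot form a fold change over a zero rate")
    return a / b
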