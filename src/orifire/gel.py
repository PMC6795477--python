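"""Gel-quantification arithmetic.

Inputs are already-extracted region intensities (no image processing):
CHEF-gel well/lane signals with a background section measured above the
well, and 2D-gel bubble-arc vs 1N-spot signals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger(__name__)

__all__ = ["LaneQuant", "GelRegionQuant", "chef_well_fraction", "bubble_ratio"]


@dataclass(frozen=True)
class LaneQuant:
    """One CHEF-gel lane: well, lane and background intensities."""

    well_signal: float
    lane_signal: float
    background_signal: float
    sample: str = ""
    time: str = ""

    def __post_init__(self) -> None:
        if min(self.well_signal, self.lane_signal, self.background_signal) < 0:
            raise ValueError("signals must be non-negative")


@dataclass(frozen=True)
class GelRegionQuant:
    """One 2D-gel quantification: bubble-arc and 1N-spot intensities."""

    bubble_signal: float
    one_n_signal: float
    sample: str = ""
    time: str = ""

    def __post_init__(self) -> None:
        if self.bubble_signal < 0 or self.one_n_signal < 0:
            raise ValueError("signals must be non-negative")


def chef_well_fraction(q: LaneQuant, background_scale: float = 1.0) -> float:
    """Fraction of a chromosome's signal retained in the well.

    The background section is subtracted from both the well and the lane
    signal (optionally scaled by ``background_scale`` if the measured
    areas differ); the corrected well signal is divided by the corrected
    total.  Negative corrected signals are clipped at zero with a
    warning; a zero corrected total yields NaN.
    """
    bg = q.background_signal * background_scale
    well = q.well_signal - bg
    lane = q.lane_signal - bg
    if well < 0 or lane < 0:
        logger.warning(
            "chef_well_fraction: negative corrected signal for %s %s; clipped at 0",
            q.sample,
            q.time,
        )
        well = max(well, 0.0)
        lane = max(lane, 0.0)
    total = well + lane
    if total == 0:
        logger.warning(
            "chef_well_fraction: zero corrected total for %s %s", q.sample, q.time
        )
        return math.nan
    return well / total


def bubble_ratio(
    q: GelRegionQuant, reference: GelRegionQuant | None = None
) -> float | tuple[float, float]:
    """Bubble:1N ratio; with a reference, also the ratio relative to it."""
    if q.one_n_signal == 0:
        raise ValueError("1N signal must be positive for a defined ratio")
    ratio = q.bubble_signal / q.one_n_signal
    if reference is None:
        return ratio
    ref = bubble_ratio(reference)
    assert isinstance(ref, float)
    if ref == 0:
        raise ValueError("reference bubble:1N ratio is zero")
    return ratio, ratio / ref
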