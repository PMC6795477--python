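"""Whole-genome marker-frequency analysis (MFA).

Read depth of an asynchronous (or S-phase) sample, binned at 1 kb, is
normalized to the sample's own genome-wide average depth — excluding the
rDNA, 2-micron plasmid and mitochondrial DNA — then divided bin-by-bin by
the identically normalized depth of a non-replicating G1 control.  Poorly
mapped regions are masked, and the ratio is LOESS-smoothed in 50 kb
windows to produce the replication profile: local maxima mark active
origins, local minima mark termination zones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome import BinnedTrack, GenomeMap, RegionMask
from .smoothing import loess_points

logger = logging.getLogger(__name__)

__all__ = [
    "DepthTable",
    "normalize_depth",
    "marker_frequency",
    "apply_masks",
    "loess_smooth",
    "smooth_profile",
]


@dataclass
class DepthTable:
    """Per-chromosome raw read counts on a 1 kb grid for one sample."""

    label: str
    tracks: dict[str, BinnedTrack]

    @property
    def total_reads(self) -> float:
        return float(
            sum(np.nansum(t.values) for t in self.tracks.values())
        )


def _excluded_mask(track: BinnedTrack, genome: GenomeMap) -> np.ndarray:
    """True for bins excluded from the normalization mean."""
    if track.chrom in genome.special_labels:
        return np.ones(len(track), dtype=bool)
    excl = np.zeros(len(track), dtype=bool)
    pos = track.positions
    for a in genome.arrays:
        if a.chrom == track.chrom and a.label in genome.special_labels:
            excl |= (pos + track.step - 1 >= a.start) & (pos <= a.end)
    return excl


def normalize_depth(
    depth: DepthTable, genome: GenomeMap
) -> dict[str, BinnedTrack]:
    """Divide every bin by the mean count over non-excluded bins.

    Excluded chromosomes/regions (``genome.special_labels``) do not
    influence the mean but still receive normalized values.  The mean of
    the non-excluded output bins is exactly 1.
    """
    num = 0.0
    cnt = 0
    for track in depth.tracks.values():
        excl = _excluded_mask(track, genome)
        v = track.values[~excl]
        v = v[np.isfinite(v)]
        num += v.sum()
        cnt += len(v)
    if cnt == 0:
        raise ValueError("all bins are excluded; cannot compute mean depth")
    mean = num / cnt
    if mean == 0:
        raise ValueError("mean depth is zero over non-excluded bins")
    return {c: t.copy(values=t.values / mean) for c, t in depth.tracks.items()}


def marker_frequency(
    s_norm: dict[str, BinnedTrack], g1_norm: dict[str, BinnedTrack]
) -> dict[str, BinnedTrack]:
    """Per-bin S/G1 ratio on matching grids; G1 zeros become NaN."""
    out = {}
    masked = 0
    for chrom, s in s_norm.items():
        if chrom not in g1_norm:
            raise ValueError(f"chromosome {chrom} missing from G1 sample")
        g = g1_norm[chrom]
        if s.start != g.start or s.step != g.step or len(s) != len(g):
            raise ValueError(f"grid mismatch on {chrom}")
        ratio = np.full(len(s), np.nan)
        ok = np.isfinite(g.values) & (g.values != 0) & np.isfinite(s.values)
        ratio[ok] = s.values[ok] / g.values[ok]
        masked += int((~ok).sum())
        out[chrom] = s.copy(values=ratio)
    if masked:
        logger.info("marker_frequency: %d bins masked (zero/missing G1)", masked)
    return out


def apply_masks(
    tracks: dict[str, BinnedTrack], masks: list[RegionMask]
) -> dict[str, BinnedTrack]:
    """Set bins overlapping any mask to NaN (before smoothing)."""
    out = {c: t.copy() for c, t in tracks.items()}
    for m in masks:
        t = out.get(m.chrom)
        if t is None:
            continue
        pos = t.positions
        hit = (pos + t.step - 1 >= m.start) & (pos <= m.end)
        t.values[hit] = np.nan
    return out


def loess_smooth(track: BinnedTrack, window_bp: int) -> BinnedTrack:
    """LOESS (tricube local linear, fixed bp bandwidth) on the track grid.

    ``window_bp`` is the full window width; it must span at least three
    grid steps.  Output is NaN where fewer than 3 finite points fall in
    the window.
    """
    if window_bp < 3 * track.step:
        raise ValueError(
            f"window_bp={window_bp} too small for step {track.step}; need >= 3 steps"
        )
    pos = track.positions.astype(float)
    sm = loess_points(pos, track.values, pos, float(window_bp))
    return track.copy(values=sm)


def smooth_profile(
    tracks: dict[str, BinnedTrack], window_bp: int = 50_000
) -> dict[str, BinnedTrack]:
    """Smooth every chromosome of a marker-frequency track set."""
    return {c: loess_smooth(t, window_bp) for c, t in tracks.items()}
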