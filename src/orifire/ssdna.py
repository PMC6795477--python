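"""ssDNA replication-profile processing.

In hydroxyurea, stalled replication forks carry stable single-stranded
DNA; the ratio of ssDNA labelled in an S-phase sample to a G1 control,
measured at microarray probes, peaks at active early origins.  The
pipeline is:

    form_ratio  →  filter_outliers  →  smooth_to_grid  →  call_peaks
                                         ↓
                                     rescale  →  peak_area

* Outliers are removed genome-wide: values more than 8 standard
  deviations above, or 2 below, the genome mean are discarded.
* Smoothing is tricube local linear regression over a 6 kb window (9 kb
  for the noisier overexpression samples), evaluated on a regular
  0.25 kb grid.
* For cross-sample comparison each sample is affinely rescaled so the
  modal smoothed value (the non-replicating baseline) maps to 1.0 and the
  genome-wide maximum to 2.0:
      rescaled_i = (v_i − baseline) / (v_max − baseline) + 1
  with the baseline estimated as the mode of a Gaussian kernel density
  (Silverman bandwidth) over all smoothed values.
* Peaks are all local maxima of the smoothed profile; significant peaks
  are the top 5% by height, and a significant peak on the shoulder of a
  taller one less than 5 kb away is merged into it.
* Peak area is the sum of the rescaled values in a 10 kb (or 16 kb)
  window centred on the origin — 41 (or 65) grid points; missing points
  count the baseline value 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome import BinnedTrack, ProbeTrack, extract_window
from .smoothing import loess_points

logger = logging.getLogger(__name__)

__all__ = [
    "PeakCall",
    "PeakSet",
    "RescaleInfo",
    "form_ratio",
    "filter_outliers",
    "smooth_to_grid",
    "rescale_track",
    "call_peaks",
    "peak_area",
    "FINE_GRID_STEP",
]

FINE_GRID_STEP = 250  # bp, the smoothed ssDNA evaluation grid


def form_ratio(
    s_probes: dict[str, ProbeTrack], g1_probes: dict[str, ProbeTrack]
) -> dict[str, ProbeTrack]:
    """Per-probe S/G1 ratio; probes with zero or missing G1 are dropped."""
    out = {}
    dropped = 0
    for chrom, s in s_probes.items():
        if chrom not in g1_probes:
            raise ValueError(f"chromosome {chrom} missing from G1 sample")
        g = g1_probes[chrom]
        if len(s) != len(g) or not np.array_equal(s.positions, g.positions):
            raise ValueError(f"probe position mismatch on {chrom}")
        ok = np.isfinite(g.values) & (g.values != 0) & np.isfinite(s.values)
        dropped += int((~ok).sum())
        out[chrom] = ProbeTrack(chrom, s.positions[ok], s.values[ok] / g.values[ok])
    if dropped:
        logger.info("form_ratio: dropped %d probes with zero/missing G1", dropped)
    return out


def filter_outliers(
    tracks: dict[str, ProbeTrack],
    sd_above: float = 8.0,
    sd_below: float = 2.0,
) -> dict[str, ProbeTrack]:
    """Drop probes more than ``sd_above`` SD above or ``sd_below`` SD below
    the genome-wide mean.

    Mean and sample SD are computed once, over all chromosomes, before any
    removal.
    """
    allv = np.concatenate([t.values for t in tracks.values()]) if tracks else np.array([])
    allv = allv[np.isfinite(allv)]
    if len(allv) < 2:
        raise ValueError("need at least 2 finite values genome-wide")
    mean = allv.mean()
    sd = allv.std(ddof=1)
    hi = mean + sd_above * sd
    lo = mean - sd_below * sd
    out = {}
    removed = 0
    for chrom, t in tracks.items():
        keep = np.isfinite(t.values) & (t.values <= hi) & (t.values >= lo)
        removed += int((~keep).sum())
        out[chrom] = ProbeTrack(chrom, t.positions[keep], t.values[keep])
    logger.info(
        "filter_outliers: removed %d probes (mean=%.4g, sd=%.4g)", removed, mean, sd
    )
    return out


def smooth_to_grid(
    tracks: dict[str, ProbeTrack],
    window_bp: int = 6000,
    grid_step: int = FINE_GRID_STEP,
) -> dict[str, BinnedTrack]:
    """LOESS-smooth probe ratios onto a regular grid (default 0.25 kb).

    Same local-regression contract as :func:`orifire.mfa.loess_smooth`;
    use ``window_bp=9000`` for the noisier overexpression samples.
    """
    out = {}
    for chrom, t in tracks.items():
        if len(t) == 0:
            logger.warning("smooth_to_grid: chromosome %s has no probes", chrom)
            out[chrom] = BinnedTrack(chrom, 1, grid_step, np.array([]))
            continue
        last = int(t.positions[-1])
        grid = np.arange(1, last + 1, grid_step, dtype=float)
        sm = loess_points(t.positions.astype(float), t.values, grid, float(window_bp))
        out[chrom] = BinnedTrack(chrom, 1, grid_step, sm)
    return out


@dataclass(frozen=True)
class RescaleInfo:
    baseline: float  # modal smoothed value, maps to 1.0
    vmax: float  # genome-wide maximum, maps to 2.0


def rescale_track(
    tracks: dict[str, BinnedTrack],
) -> tuple[dict[str, BinnedTrack], RescaleInfo]:
    """Affinely rescale a smoothed track set to the [1, 2] comparison scale.

    baseline → 1.0 and genome-wide max → 2.0 via
    ``(v − baseline) / (vmax − baseline) + 1``.  The baseline is the KDE
    mode (Silverman bandwidth) of all smoothed values.
    """
    allv = np.concatenate([t.values for t in tracks.values()])
    allv = allv[np.isfinite(allv)]
    if len(allv) == 0:
        raise ValueError("no finite smoothed values to rescale")
    vmax = float(allv.max())
    baseline = _kde_mode(allv)
    if vmax <= baseline:
        raise ValueError("genome-wide max does not exceed the baseline; flat profile?")
    scale = vmax - baseline
    out = {
        c: t.copy(values=(t.values - baseline) / scale + 1.0) for c, t in tracks.items()
    }
    return out, RescaleInfo(baseline=baseline, vmax=vmax)


def _kde_mode(values: np.ndarray) -> float:
    """Argmax of a Gaussian KDE (Silverman's rule) over the value range."""
    if np.ptp(values) == 0:
        return float(values[0])
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), 2048)
    return float(grid[np.argmax(kde(grid))])


@dataclass
class PeakCall:
    chrom: str
    position: int  # bp, grid point of the local maximum
    height: float  # smoothed value at the maximum
    significant: bool
    merged_into: "PeakCall | None" = None


@dataclass
class PeakSet:
    """All local maxima of a smoothed profile plus the significant subset."""

    sample: str
    peaks: list[PeakCall]
    threshold: float  # 95th percentile of raw peak heights
    n_raw: int

    @property
    def significant(self) -> list[PeakCall]:
        return [p for p in self.peaks if p.significant]

    @property
    def n_significant(self) -> int:
        return len(self.significant)


def _local_maxima(track: BinnedTrack) -> list[tuple[int, float]]:
    """Interior grid points where the first difference changes + to −.

    NaN stretches split the profile into independent runs.  A flat-topped
    maximum is reported at its leftmost point.
    """
    v = track.values
    pos = track.positions
    peaks: list[tuple[int, float]] = []
    finite = np.isfinite(v)
    i = 0
    n = len(v)
    while i < n:
        if not finite[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and finite[j + 1]:
            j += 1
        seg = v[i : j + 1]
        if len(seg) >= 3:
            d = np.diff(seg)
            sign = np.sign(d)
            # carry the last nonzero slope through plateaus
            last = 0.0
            for k in range(len(sign)):
                s = sign[k]
                if s == 0:
                    continue
                if last > 0 and s < 0:
                    # peak at the first index of the plateau/apex
                    apex = k
                    while apex > 0 and sign[apex - 1] == 0:
                        apex -= 1
                    peaks.append((int(pos[i + apex]), float(seg[apex])))
                last = s
        i = j + 1
    return peaks


def call_peaks(
    tracks: dict[str, BinnedTrack],
    sample: str = "",
    top_fraction: float = 0.05,
    merge_distance: int = 5000,
) -> PeakSet:
    """Call origin peaks on a smoothed profile.

    All local maxima (including baseline noise bumps) are collected
    genome-wide; the significance threshold is the (1 − top_fraction)
    quantile of their heights.  Significant peaks closer than
    ``merge_distance`` are merged keeping the taller (ties → leftmost),
    which generalizes the shoulder-peak exclusion.
    """
    raw: list[PeakCall] = []
    for chrom, t in tracks.items():
        if len(t) < 3:
            if len(t):
                logger.warning("call_peaks: %s has < 3 grid points, skipped", chrom)
            continue
        for p, h in _local_maxima(t):
            raw.append(PeakCall(chrom, p, h, significant=False))
    if not raw:
        return PeakSet(sample, [], threshold=np.nan, n_raw=0)

    heights = np.array([p.height for p in raw])
    threshold = float(np.quantile(heights, 1.0 - top_fraction))
    for p in raw:
        p.significant = p.height >= threshold

    # shoulder rule: keep the taller of significant peaks < merge_distance apart
    sig = sorted(
        [p for p in raw if p.significant], key=lambda p: (-p.height, p.chrom, p.position)
    )
    kept: list[PeakCall] = []
    for p in sig:
        near = next(
            (
                q
                for q in kept
                if q.chrom == p.chrom and abs(q.position - p.position) < merge_distance
            ),
            None,
        )
        if near is not None:
            p.significant = False
            p.merged_into = near
        else:
            kept.append(p)

    raw.sort(key=lambda p: (p.chrom, p.position))
    return PeakSet(sample, raw, threshold=threshold, n_raw=len(raw))


def peak_area(
    track: BinnedTrack,
    origin_position: int,
    half_width: int = 5000,
    baseline_fill: float = 1.0,
) -> float:
    """Sum of rescaled values in the window centred on an origin.

    A 10 kb window on the 0.25 kb grid sums 41 points (a flat baseline
    gives exactly 41.0); the 16 kb variant sums 65.  Missing grid points
    contribute ``baseline_fill`` (the rescaled baseline, 1.0).
    """
    w = extract_window(track, origin_position, half_width)
    n_missing = int(np.isnan(w).sum())
    if n_missing:
        logger.debug(
            "peak_area: %d missing points at %s:%d filled with baseline",
            n_missing,
            track.chrom,
            origin_position,
        )
    return float(np.where(np.isnan(w), baseline_fill, w).sum())
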