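"""Genome, origin, mask and signal-track types.

Coordinates are 1-based and inclusive throughout the package; conversion to
the 0-based half-open convention happens only at BED/bedGraph boundaries
(see :mod:`orifire.io`).

An *origin* here is a chromosomal coordinate carrying three parameters:

``competence``
    the intrinsic probability (per cell cycle) that the origin assembles a
    functional initiation complex and is able to fire,
``t_mean`` / ``t_sd``
    the mean and spread (minutes into S phase) of its stochastic firing
    time.

Population-level *efficiency* — the fraction of cells in which the origin
actually fires — emerges from competence plus passive replication by forks
arriving from neighbours, and is an output of the simulator rather than a
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "OriginSpec",
    "Chromosome",
    "TandemArray",
    "GenomeMap",
    "RegionMask",
    "BinnedTrack",
    "ProbeTrack",
    "make_demo_genome",
    "make_random_genome",
    "extract_window",
]


@dataclass(frozen=True)
class OriginSpec:
    """A replication origin with stochastic firing parameters."""

    id: str
    chrom: str
    position: int  # bp, 1-based
    competence: float  # P(origin is able to fire) in [0, 1]
    t_mean: float = 10.0  # minutes into S phase
    t_sd: float = 5.0  # minutes

    def __post_init__(self) -> None:
        if not 0.0 <= self.competence <= 1.0:
            raise ValueError(f"competence must be in [0, 1], got {self.competence}")
        if self.t_mean < 0 or self.t_sd < 0:
            raise ValueError("firing-time parameters must be non-negative")
        if self.position < 1:
            raise ValueError("position must be a positive 1-based coordinate")


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int  # bp
    centromere: int | None = None  # bp, 1-based

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("chromosome length must be positive")
        if self.centromere is not None and not 1 <= self.centromere <= self.length:
            raise ValueError(f"centromere outside chromosome {self.name}")


@dataclass(frozen=True)
class TandemArray:
    """A tandem repeat array (e.g. the rDNA locus) with one origin per repeat."""

    chrom: str
    start: int  # bp, 1-based inclusive
    end: int  # bp, 1-based inclusive
    repeat_length: int  # bp
    origin_competence: float  # per-repeat firing probability
    label: str = "rDNA"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("array start must be <= end")
        if not 0.0 <= self.origin_competence <= 1.0:
            raise ValueError("origin_competence must be in [0, 1]")

    @property
    def n_repeats(self) -> int:
        return (self.end - self.start + 1) // self.repeat_length


@dataclass
class GenomeMap:
    """A model genome: chromosomes, unique origins, tandem arrays, and the
    chromosome/region labels excluded from depth normalization (rDNA,
    2-micron plasmid, mitochondrial DNA)."""

    chromosomes: tuple[Chromosome, ...]
    origins: tuple[OriginSpec, ...]
    arrays: tuple[TandemArray, ...] = ()
    special_labels: frozenset[str] = frozenset({"rDNA", "2-micron", "chrM"})

    def __post_init__(self) -> None:
        self.chromosomes = tuple(self.chromosomes)
        order = {c.name: i for i, c in enumerate(self.chromosomes)}
        self.origins = tuple(
            sorted(self.origins, key=lambda o: (order.get(o.chrom, 1 << 30), o.position))
        )
        self.arrays = tuple(self.arrays)
        self.special_labels = frozenset(self.special_labels)
        for o in self.origins:
            if o.chrom not in order:
                raise ValueError(f"origin {o.id} on unknown chromosome {o.chrom}")
            if o.position > self.chrom_length(o.chrom):
                raise ValueError(f"origin {o.id} beyond end of {o.chrom}")
            for a in self.arrays:
                if a.chrom == o.chrom and a.start <= o.position <= a.end:
                    raise ValueError(
                        f"unique origin {o.id} overlaps tandem array on {a.chrom}"
                    )

    def chrom_length(self, name: str) -> int:
        for c in self.chromosomes:
            if c.name == name:
                return c.length
        raise KeyError(f"unknown chromosome {name!r}")

    def centromere(self, name: str) -> int:
        for c in self.chromosomes:
            if c.name == name:
                if c.centromere is None:
                    raise ValueError(f"chromosome {name} has no centromere coordinate")
                return c.centromere
        raise KeyError(f"unknown chromosome {name!r}")

    def origins_on(self, chrom: str) -> tuple[OriginSpec, ...]:
        return tuple(o for o in self.origins if o.chrom == chrom)


@dataclass(frozen=True)
class RegionMask:
    """An interval excluded from profiles (poorly mapped or repetitive)."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("mask start must be <= end")


class BinnedTrack:
    """A genomic signal on a regular grid of points.

    ``positions[i] = start + i * step`` (1-based bp).  For binned data (1 kb
    read-count bins) the grid point is the bin start and the bin covers
    ``[position, position + step - 1]``; for smoothed profiles the grid
    point is the evaluation coordinate itself.  Missing values are NaN and
    never silently dropped.
    """

    __slots__ = ("chrom", "start", "step", "values")

    def __init__(self, chrom: str, start: int, step: int, values: Sequence[float]):
        if step <= 0:
            raise ValueError("step must be positive")
        self.chrom = chrom
        self.start = int(start)
        self.step = int(step)
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def positions(self) -> np.ndarray:
        return self.start + self.step * np.arange(len(self.values), dtype=np.int64)

    @property
    def end(self) -> int:
        """Last grid point (1-based bp)."""
        return self.start + self.step * (len(self.values) - 1)

    def copy(self, values: np.ndarray | None = None) -> "BinnedTrack":
        v = self.values.copy() if values is None else np.asarray(values, float)
        return BinnedTrack(self.chrom, self.start, self.step, v)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"BinnedTrack({self.chrom!r}, start={self.start}, step={self.step}, "
            f"n={len(self.values)})"
        )


class ProbeTrack:
    """A genomic signal at irregular probe positions (microarray-style)."""

    __slots__ = ("chrom", "positions", "values")

    def __init__(self, chrom: str, positions: Sequence[int], values: Sequence[float]):
        self.chrom = chrom
        self.positions = np.asarray(positions, dtype=np.int64)
        self.values = np.asarray(values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("probe positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)

    def copy(self, values: np.ndarray | None = None) -> "ProbeTrack":
        v = self.values.copy() if values is None else np.asarray(values, float)
        return ProbeTrack(self.chrom, self.positions.copy(), v)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"ProbeTrack({self.chrom!r}, n={len(self)})"


# ---------------------------------------------------------------------------
# fixture genomes

_DEMO_STYLES = ("five_origin", "chr12like", "minimal")


def make_demo_genome(style: str) -> GenomeMap:
    """Return one of the built-in fixture genomes.

    ``"five_origin"``
        a single 1 Mb chromosome with five origins of staggered timing
        (two early, one mid-S, two late), used to illustrate how subset
        firing dampens marker-frequency amplitude.
    ``"chr12like"``
        a chromosome with unique origins flanking a tandem rDNA-like array
        of 9 kb repeats carrying a single inefficient origin per repeat.
    ``"minimal"``
        one chromosome, one origin; the smallest useful genome.
    """
    if style == "five_origin":
        # deterministic firing times: every cell in the population behaves
        # identically, as in the illustrative subset-firing model
        chrom = Chromosome("chrS", 1_000_000, centromere=500_000)
        origins = (
            OriginSpec("oriE1", "chrS", 100_000, 1.0, t_mean=5.0, t_sd=0.0),
            OriginSpec("oriL1", "chrS", 300_000, 1.0, t_mean=25.0, t_sd=0.0),
            OriginSpec("oriM1", "chrS", 500_000, 1.0, t_mean=15.0, t_sd=0.0),
            OriginSpec("oriL2", "chrS", 700_000, 1.0, t_mean=25.0, t_sd=0.0),
            OriginSpec("oriE2", "chrS", 900_000, 1.0, t_mean=5.0, t_sd=0.0),
        )
        return GenomeMap((chrom,), origins)
    if style == "chr12like":
        chrom = Chromosome("chr12", 1_100_000, centromere=150_000)
        origins = (
            OriginSpec("ori_left1", "chr12", 100_000, 0.9, t_mean=10.0, t_sd=4.0),
            OriginSpec("ori_left2", "chr12", 280_000, 0.7, t_mean=15.0, t_sd=4.0),
            OriginSpec("ori_right1", "chr12", 920_000, 0.8, t_mean=12.0, t_sd=4.0),
            OriginSpec("ori_right2", "chr12", 1_050_000, 0.5, t_mean=25.0, t_sd=5.0),
        )
        # 9 kb repeats, ~50 copies; per-repeat origin fires in ~1 of 5 cells
        array = TandemArray("chr12", 400_001, 850_000, 9_000, 0.2, label="rDNA")
        return GenomeMap((chrom,), origins, arrays=(array,))
    if style == "minimal":
        chrom = Chromosome("chr1", 200_000, centromere=100_000)
        return GenomeMap(
            (chrom,), (OriginSpec("ori1", "chr1", 100_000, 1.0, t_mean=10.0, t_sd=2.0),)
        )
    raise ValueError(f"unknown demo genome style {style!r}; valid styles: {_DEMO_STYLES}")


def make_random_genome(
    rng: np.random.Generator,
    n_chroms: int = 2,
    chrom_length: int = 1_500_000,
    origin_spacing: int = 100_000,
    competence_range: tuple[float, float] = (0.6, 0.95),
    t_mean_range: tuple[float, float] = (5.0, 15.0),
    t_sd: float = 3.0,
) -> GenomeMap:
    """A synthetic genome with yeast-like early-origin density.

    Origins are placed every ``origin_spacing`` bp with ±20% jitter
    (~10 per Mb, matching the density of early origins detected by ssDNA
    mapping) and draw competence and mean firing time uniformly from the
    given ranges, so origin efficiency varies across the genome as it
    does in real data.
    """
    chroms = []
    origins = []
    for ci in range(n_chroms):
        name = f"chr{ci + 1}"
        chroms.append(Chromosome(name, chrom_length, centromere=chrom_length // 2))
        x = origin_spacing // 2
        k = 0
        while x < chrom_length - origin_spacing // 4:
            k += 1
            jitter = int(rng.uniform(-0.2, 0.2) * origin_spacing)
            pos = int(np.clip(x + jitter, 1, chrom_length))
            origins.append(
                OriginSpec(
                    f"{name}_ori{k:02d}",
                    name,
                    pos,
                    competence=float(rng.uniform(*competence_range)),
                    t_mean=float(rng.uniform(*t_mean_range)),
                    t_sd=t_sd,
                )
            )
            x += origin_spacing
    return GenomeMap(tuple(chroms), tuple(origins))


def extract_window(track: BinnedTrack, center: int, half_width: int) -> np.ndarray:
    """Values at grid points from ``center - half_width`` to
    ``center + half_width`` inclusive.

    The window is snapped to the grid point nearest ``center``.  Length is
    always ``2 * half_width // step + 1`` (41 points for a 10 kb window on
    the 0.25 kb grid); grid points outside the track extent are NaN.
    """
    if center < 1:
        raise ValueError("center must be a positive coordinate")
    step = track.step
    n_side = half_width // step
    # snap center to nearest grid index; window edges may pad NaN
    c_idx = int(round((center - track.start) / step))
    if not 0 <= c_idx < len(track.values):
        raise ValueError(
            f"center {center} lies outside the track extent on {track.chrom}"
        )
    out = np.full(2 * n_side + 1, np.nan)
    for j in range(-n_side, n_side + 1):
        i = c_idx + j
        if 0 <= i < len(track.values):
            out[j + n_side] = track.values[i]
    return out
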