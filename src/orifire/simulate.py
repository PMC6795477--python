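"""Stochastic origin firing, fork progression, and population profiles.

The model, per cell:

1. Every origin independently becomes *competent-and-scheduled* with
   probability ``competence`` and draws a firing time from a Normal
   (``t_mean``, ``t_sd``) truncated at zero.
2. Outside hydroxyurea (HU), an origin whose locus has already been
   replicated by an incoming fork at its scheduled time is passively
   replicated instead of firing.  With equal fork speeds the time at which
   a locus x is first replicated is ``min_j (t_j + |x − x_j| / v)`` over
   origins j that actually fired, so firing can be resolved by processing
   scheduled origins in time order.
3. Each fired origin launches two divergent forks at speed ``fork_speed``.
   In HU the dNTP pool is the limiting resource: a cell that fired k
   origins can synthesise at most ``dntp_budget`` kb in total, split
   equally over its 2k forks, so each fork stalls after
   ``d_max = dntp_budget / (2 k)`` kb.  Fewer fired origins per cell ⇒
   longer per-fork travel, which is the quantitative core of the model.

Population read-outs:

* ``simulate_mfa`` pools cells sampled across the cell cycle into a
  marker-frequency track (mean copy number per 1 kb bin, between 1 and 2).
* ``simulate_ssdna`` deposits a Gaussian ssDNA footprint at every fork of
  every HU-arrested cell and evaluates the population mean at microarray
  probe positions, returned as an S/G1-style ratio (baseline 1).
* ``simulate_rdna_array`` is the tandem-array model: one origin per repeat
  firing with probability ``p_fire``, each productive initiation yielding a
  SINGLE unidirectional fork (the replication fork barrier blocks the
  opposing fork) that must cover the span to the next fired repeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome import BinnedTrack, GenomeMap, OriginSpec, ProbeTrack

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "Fork",
    "CellRealization",
    "RdnaSummary",
    "realize_firing",
    "replicate_cell",
    "simulate_mfa",
    "simulate_ssdna",
    "simulate_rdna_array",
    "add_poisson_reads",
    "add_array_noise",
    "make_probe_positions",
]


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters shared across cells.

    fork_speed        kb/min (≈1.5 unchallenged; ≈0.3 under 200 mM HU)
    dntp_budget       kb of total synthesis available per cell in HU
    s_duration        minutes of S phase
    hu_mode           HU arrest: budget-capped forks, no passive demotion
    ssdna_footprint_sd  bp, width of the ssDNA signal around a fork
    ssdna_amplitude   peak S/G1 ratio contribution of one always-present fork
    cell_cycle_fractions  (G1, S, G2) proportions for asynchronous sampling
    """

    fork_speed: float = 1.5
    dntp_budget: float = 200.0
    s_duration: float = 30.0
    hu_mode: bool = False
    ssdna_footprint_sd: float = 1000.0
    ssdna_amplitude: float = 3.0
    cell_cycle_fractions: tuple[float, float, float] = (0.3, 0.5, 0.2)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.fork_speed <= 0:
            raise ValueError("fork_speed must be positive")
        if self.hu_mode and self.dntp_budget <= 0:
            raise ValueError("dntp_budget must be positive in HU mode")
        if abs(sum(self.cell_cycle_fractions) - 1.0) > 1e-9:
            raise ValueError("cell_cycle_fractions must sum to 1")

    @property
    def fork_speed_bp(self) -> float:
        return self.fork_speed * 1000.0


@dataclass(frozen=True)
class Fork:
    chrom: str
    position: float  # bp
    direction: int  # ±1
    active: bool  # False once merged with a converging fork or off-chromosome


@dataclass
class CellRealization:
    """One cell: which origins fired, when, and what got replicated."""

    fired: np.ndarray  # bool per genome origin
    fire_time: np.ndarray  # minutes, NaN for unfired origins
    sample_time: float  # minutes into S phase
    forks: list[Fork] = field(default_factory=list)
    replicated: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    @property
    def n_fired(self) -> int:
        return int(self.fired.sum())


def realize_firing(
    genome: GenomeMap, params: SimParams, rng: np.random.Generator
) -> CellRealization:
    """Draw the firing layer for one cell (no forks yet).

    Outside HU, scheduled origins are processed in firing-time order
    (ties broken by coordinate) and demoted to passively replicated if a
    previously fired origin's fork reaches their locus first.
    """
    origins = genome.origins
    n = len(origins)
    competence = np.array([o.competence for o in origins])
    scheduled = rng.random(n) < competence
    t_mean = np.array([o.t_mean for o in origins])
    t_sd = np.array([o.t_sd for o in origins])
    times = np.full(n, np.nan)
    det = scheduled & (t_sd == 0)
    times[det] = t_mean[det]
    sto = scheduled & (t_sd > 0)
    if sto.any():
        a = (0.0 - t_mean[sto]) / t_sd[sto]
        times[sto] = stats.truncnorm.rvs(
            a, np.inf, loc=t_mean[sto], scale=t_sd[sto], random_state=rng
        )

    fired = np.zeros(n, dtype=bool)
    if params.hu_mode:
        # HU: forks stall near their origins, passive demotion is negligible
        fired[:] = scheduled
    else:
        v = params.fork_speed_bp
        for chrom in {o.chrom for o in origins}:
            idx = [i for i in range(n) if origins[i].chrom == chrom and scheduled[i]]
            order = sorted(idx, key=lambda i: (times[i], origins[i].position))
            fired_here: list[int] = []
            for i in order:
                x = origins[i].position
                covered_at = min(
                    (times[j] + abs(x - origins[j].position) / v for j in fired_here),
                    default=np.inf,
                )
                if covered_at < times[i]:
                    times[i] = np.nan  # passively replicated before firing
                else:
                    fired[i] = True
                    fired_here.append(i)
        times[~fired] = np.nan
    sample_time = params.s_duration
    return CellRealization(fired=fired, fire_time=times, sample_time=sample_time)


def _merge_intervals(iv: list[tuple[float, float]]) -> list[tuple[float, float]]:
    iv = sorted(iv)
    merged: list[tuple[float, float]] = []
    for s, e in iv:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def replicate_cell(
    cell: CellRealization, genome: GenomeMap, params: SimParams
) -> CellRealization:
    """Fill in forks and replicated intervals at ``cell.sample_time``.

    Each fired origin with fire_time ≤ sample_time contributes the interval
    [position − travel, position + travel] clipped to the chromosome, where
    travel = fork_speed × elapsed, capped in HU by d_max = budget/(2k).
    Converging forks from adjacent origins simply merge their intervals; a
    fork is flagged inactive when its front has merged into a neighbouring
    interval or run off the chromosome end.  HU-stalled forks remain active
    (they persist, ssDNA-marked, at their stall positions).
    """
    origins = genome.origins
    t = cell.sample_time
    k = cell.n_fired
    d_max_bp = np.inf
    if params.hu_mode and k > 0:
        d_max_bp = params.dntp_budget * 1000.0 / (2.0 * k)

    by_chrom: dict[str, list[tuple[float, float, float]]] = {}
    for i, o in enumerate(origins):
        if not cell.fired[i] or not cell.fire_time[i] <= t:
            continue
        travel = min(params.fork_speed_bp * (t - cell.fire_time[i]), d_max_bp)
        by_chrom.setdefault(o.chrom, []).append(
            (o.position - travel, o.position + travel, o.position)
        )

    forks: list[Fork] = []
    replicated: dict[str, list[tuple[float, float]]] = {}
    for chrom, spans in by_chrom.items():
        L = genome.chrom_length(chrom)
        merged = _merge_intervals([(max(1.0, s), min(float(L), e)) for s, e, _ in spans])
        replicated[chrom] = merged
        for s, e, x in spans:
            left = max(1.0, s)
            right = min(float(L), e)
            left_active = any(abs(left - ms) < 0.5 for ms, _ in merged) and left > 1.0
            right_active = any(abs(right - me) < 0.5 for _, me in merged) and right < L
            forks.append(Fork(chrom, left, -1, left_active))
            forks.append(Fork(chrom, right, +1, right_active))
    cell.forks = forks
    cell.replicated = replicated
    return cell


# ---------------------------------------------------------------------------
# population profiles


def simulate_mfa(
    genome: GenomeMap,
    params: SimParams,
    n_cells: int,
    rng: np.random.Generator,
    bin_size: int = 1000,
) -> dict[str, BinnedTrack]:
    """Marker-frequency profile of an asynchronous population.

    Cells are assigned to G1/S/G2 by ``cell_cycle_fractions``; S cells get a
    sample time uniform on (0, s_duration).  Per bin the track is the mean
    copy number across cells (1 unreplicated, 2 replicated), which is the
    G1-normalized marker frequency and lies in [1, 2].
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    fg1, fs, fg2 = params.cell_cycle_fractions
    phases = rng.choice(3, size=n_cells, p=[fg1, fs, fg2])

    extra: dict[str, np.ndarray] = {}
    nbins: dict[str, int] = {}
    for c in genome.chromosomes:
        nb = (c.length + bin_size - 1) // bin_size
        nbins[c.name] = nb
        extra[c.name] = np.zeros(nb)

    n_g2 = int((phases == 2).sum())
    for name in extra:
        extra[name] += n_g2  # G2 cells: copy 2 everywhere

    for _ in range(int((phases == 1).sum())):
        cell = realize_firing(genome, params, rng)
        cell.sample_time = rng.uniform(0.0, params.s_duration)
        replicate_cell(cell, genome, params)
        for chrom, spans in cell.replicated.items():
            arr = extra[chrom]
            for s, e in spans:
                i0 = int((s - 1) // bin_size)
                i1 = int((e - 1) // bin_size)
                arr[i0 : i1 + 1] += 1.0

    tracks = {}
    for name, arr in extra.items():
        mf = 1.0 + arr / n_cells
        tracks[name] = BinnedTrack(name, 1, bin_size, mf)
    return tracks


def make_probe_positions(
    genome: GenomeMap, rng: np.random.Generator, mean_spacing: float = 1000.0
) -> dict[str, np.ndarray]:
    """Irregular microarray-like probe positions, ~1 kb apart on average."""
    out = {}
    for c in genome.chromosomes:
        gaps = rng.gamma(shape=4.0, scale=mean_spacing / 4.0, size=int(2 * c.length / mean_spacing) + 8)
        pos = np.cumsum(gaps) + 1
        pos = pos[pos <= c.length].astype(np.int64)
        out[c.name] = np.unique(pos)
    return out


def simulate_ssdna(
    genome: GenomeMap,
    params: SimParams,
    sample_time: float,
    n_cells: int,
    rng: np.random.Generator,
    probe_positions: dict[str, np.ndarray] | None = None,
) -> dict[str, ProbeTrack]:
    """Population ssDNA S/G1 ratio profile in HU.

    Each fork of each cell deposits a Gaussian footprint
    (sd = ``ssdna_footprint_sd``); the population mean, scaled by
    ``ssdna_amplitude``, rides on a baseline of 1.
    """
    if not params.hu_mode:
        raise ValueError("simulate_ssdna is defined in HU (set hu_mode=True)")
    if probe_positions is None:
        probe_positions = make_probe_positions(genome, rng)

    sd = params.ssdna_footprint_sd
    signal = {c: np.zeros(len(p), dtype=float) for c, p in probe_positions.items()}
    for _ in range(n_cells):
        cell = realize_firing(genome, params, rng)
        cell.sample_time = sample_time
        replicate_cell(cell, genome, params)
        for fork in cell.forks:
            pos = probe_positions[fork.chrom]
            a = np.searchsorted(pos, fork.position - 4 * sd)
            b = np.searchsorted(pos, fork.position + 4 * sd)
            if b > a:
                d = (pos[a:b] - fork.position) / sd
                signal[fork.chrom][a:b] += np.exp(-0.5 * d * d)

    tracks = {}
    for chrom, pos in probe_positions.items():
        ratio = 1.0 + params.ssdna_amplitude * signal[chrom] / n_cells
        tracks[chrom] = ProbeTrack(chrom, pos, ratio)
    return tracks


# ---------------------------------------------------------------------------
# tandem (rDNA-like) array model


@dataclass
class RdnaSummary:
    """Replication-completion statistics of a tandem origin array."""

    n_repeats: int
    repeat_len: int
    p_fire: float
    n_cells: int
    frac_replicated: np.ndarray  # per cell
    gap_lengths: np.ndarray  # pooled unreplicated span lengths, bp
    p_complete: float
    mean_active_origins: float
    spacing_analytic: float  # repeat_len / p_fire, bp
    spacing_empirical: float  # mean distance between adjacent fired origins, bp


def simulate_rdna_array(
    n_repeats: int,
    repeat_len: int,
    p_fire: float,
    fork_speed: float,
    time_budget: float,
    n_cells: int,
    rng: np.random.Generator,
) -> RdnaSummary:
    """Unidirectional-fork model of tandem-array replication.

    One origin per repeat fires with probability ``p_fire``.  The fork
    barrier at each repeat makes every productive initiation a single fork
    travelling toward the next repeat downstream, so the span between
    adjacent fired origins must be covered by the upstream origin's fork
    within ``time_budget``; repeats upstream of the first fired origin have
    no covering fork.  The analytic mean spacing between fired origins is
    ``repeat_len / p_fire``.
    """
    if not 0.0 <= p_fire <= 1.0:
        raise ValueError("p_fire must be in [0, 1]")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    total_len = n_repeats * repeat_len
    reach = fork_speed * 1000.0 * time_budget  # bp

    frac = np.zeros(n_cells)
    complete = np.zeros(n_cells, dtype=bool)
    gaps: list[float] = []
    spacings: list[float] = []
    n_active = np.zeros(n_cells)

    fired_all = rng.random((n_cells, n_repeats)) < p_fire
    for c in range(n_cells):
        idx = np.flatnonzero(fired_all[c])
        n_active[c] = len(idx)
        if len(idx) == 0:
            gaps.append(float(total_len))
            continue
        # spans: leading (uncovered), then fired-origin i to next fired origin
        lead = idx[0] * repeat_len
        span = np.diff(np.append(idx, n_repeats)) * repeat_len
        cov = np.minimum(span, reach)
        rep = cov.sum()
        frac[c] = rep / total_len
        cell_gaps = span - cov
        if lead > 0:
            gaps.append(float(lead))
        gaps.extend(float(g) for g in cell_gaps[cell_gaps > 0])
        complete[c] = lead == 0 and not np.any(cell_gaps > 0)
        if len(idx) > 1:
            spacings.extend((np.diff(idx) * repeat_len).tolist())

    spacing_emp = float(np.mean(spacings)) if spacings else np.nan
    analytic = repeat_len / p_fire if p_fire > 0 else np.inf
    return RdnaSummary(
        n_repeats=n_repeats,
        repeat_len=repeat_len,
        p_fire=p_fire,
        n_cells=n_cells,
        frac_replicated=frac,
        gap_lengths=np.asarray(gaps),
        p_complete=float(complete.mean()) if n_cells else np.nan,
        mean_active_origins=float(n_active.mean()),
        spacing_analytic=float(analytic),
        spacing_empirical=spacing_emp,
    )


# ---------------------------------------------------------------------------
# noise layers


def add_poisson_reads(
    track: BinnedTrack, mean_depth: float, rng: np.random.Generator
) -> BinnedTrack:
    """Sequencing-count layer: per-bin counts ~ Poisson(mean_depth × value)."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    lam = mean_depth * track.values
    counts = np.full(len(track), np.nan)
    ok = np.isfinite(lam)
    counts[ok] = rng.poisson(lam[ok]).astype(float)
    return track.copy(values=counts)


def add_array_noise(
    track: ProbeTrack,
    log_sd: float,
    outlier_rate: float,
    rng: np.random.Generator,
) -> ProbeTrack:
    """Microarray noise: multiplicative log-normal scatter plus rare extreme
    spikes (the outliers the 8 SD filter exists to remove)."""
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    v = track.values * np.exp(rng.normal(0.0, log_sd, size=len(track)))
    if outlier_rate > 0:
        hit = rng.random(len(track)) < outlier_rate
        v[hit] = rng.uniform(20.0, 100.0, size=int(hit.sum()))
    return track.copy(values=v)
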