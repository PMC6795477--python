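"""Canonical synthetic study conditions.

These functions pin down the population conditions used by the analysis
drivers, the test suite and the acceptance script, so every consumer runs
the same experiment:

* a wild-type-like genome of six 2 Mb chromosomes with origins every
  ~100 kb (~120 origins — the density of early origins detected by ssDNA
  mapping in a 12 Mb yeast genome) whose competences span 0.3–0.95 and
  mean firing times 5–15 min, so origin efficiency varies widely as it
  does in real data;
* HU ssDNA sampling at 30 min with slow HU forks (0.3 kb/min) and a
  per-cell synthesis budget of 100 kb, sized so a wild-type cell firing
  ~75 origins gives d_max ≈ 0.7 kb per fork — below the 1 kb ssDNA
  footprint, hence resolved origin-centred peaks as in an early HU
  sample;
* competence transforms emulating the depletion/overexpression regimes:

  - UNIFORM scaling: every origin's competence × f (proportional
    depletion — all origins keep their relative efficiencies);
  - WEAK-BIASED scaling: competence additionally multiplied by
    (c/c_max)**strength with per-origin log-normal susceptibility
    scatter, so inefficient origins are disproportionately and somewhat
    idiosyncratically compromised;
  - EQUALIZED: identical high competence and early firing time
    everywhere — origin individuality erased.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .genome import BinnedTrack, GenomeMap, OriginSpec, make_random_genome
from .mfa import DepthTable, marker_frequency, normalize_depth, smooth_profile
from .simulate import SimParams, add_array_noise, add_poisson_reads, simulate_mfa, simulate_ssdna
from .ssdna import RescaleInfo, call_peaks, filter_outliers, rescale_track, smooth_to_grid
from .compare import select_origin_subset

__all__ = [
    "WT_SSDNA_PARAMS",
    "MFA_PARAMS",
    "MFA_DEPTH",
    "MFA_N_CELLS",
    "SAMPLE_TIME_MIN",
    "N_CELLS",
    "NOISE_LOG_SD",
    "OUTLIER_RATE",
    "make_study_genome",
    "scale_competence",
    "bias_weak_origins",
    "equalize_origins",
    "run_ssdna_condition",
    "reference_origin_set",
    "excess_areas",
    "run_mfa_study",
    "peak_trough_amplitudes",
]

# HU ssDNA study conditions for the 12 Mb synthetic genome (see module
# docstring for the sizing of the dNTP budget).
WT_SSDNA_PARAMS = SimParams(
    hu_mode=True,
    fork_speed=0.3,
    dntp_budget=100.0,
    ssdna_footprint_sd=1000.0,
    ssdna_amplitude=3.0,
)

SAMPLE_TIME_MIN = 30.0
N_CELLS = 800
NOISE_LOG_SD = 0.15
OUTLIER_RATE = 0.001


def make_study_genome(rng: np.random.Generator) -> GenomeMap:
    """The wild-type-like genome the synthetic studies run on."""
    return make_random_genome(
        rng,
        n_chroms=6,
        chrom_length=2_000_000,
        origin_spacing=100_000,
        competence_range=(0.3, 0.95),
        t_mean_range=(5.0, 15.0),
        t_sd=3.0,
    )


def _with_origins(genome: GenomeMap, origins: list[OriginSpec]) -> GenomeMap:
    return GenomeMap(
        genome.chromosomes, tuple(origins), genome.arrays, genome.special_labels
    )


def scale_competence(genome: GenomeMap, factor: float) -> GenomeMap:
    """Uniform depletion: every competence × ``factor``."""
    return _with_origins(
        genome,
        [replace(o, competence=min(1.0, o.competence * factor)) for o in genome.origins],
    )


def bias_weak_origins(
    genome: GenomeMap,
    strength: float = 3.0,
    scatter_sd: float = 0.3,
    rng: np.random.Generator | None = None,
) -> GenomeMap:
    """Depletion that hits inefficient origins harder.

    Each competence c is multiplied by ``(c / c_max) ** strength`` — the
    most competent origin is untouched, weak origins fall super-linearly
    — times a per-origin log-normal susceptibility factor
    (sd ``scatter_sd``) for origin-to-origin variability in how severely
    the depletion bites.  This is the regime inferred for Sld3-class
    depletion ("all but the most efficient origins are severely
    affected").
    """
    if rng is None:
        rng = np.random.default_rng(0)
    cmax = max(o.competence for o in genome.origins)
    out = []
    for o in genome.origins:
        c = (
            o.competence
            * (o.competence / cmax) ** strength
            * np.exp(rng.normal(0.0, scatter_sd))
        )
        out.append(replace(o, competence=float(min(1.0, c))))
    return _with_origins(genome, out)


def equalize_origins(
    genome: GenomeMap, competence: float = 0.95, t_mean: float = 10.0
) -> GenomeMap:
    """Erase origin individuality: same high competence and early mean
    firing time everywhere (the SSDDCS-overexpression regime)."""
    return _with_origins(
        genome,
        [replace(o, competence=competence, t_mean=t_mean) for o in genome.origins],
    )


def run_ssdna_condition(
    genome: GenomeMap,
    seed: int | np.random.Generator,
    params: SimParams = WT_SSDNA_PARAMS,
    sample_time: float = SAMPLE_TIME_MIN,
    n_cells: int = N_CELLS,
    window_bp: int = 6000,
    probe_positions: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, BinnedTrack], dict[str, BinnedTrack], RescaleInfo]:
    """Simulate one condition and run the full ssDNA pipeline on it.

    Returns (smoothed, rescaled, rescale_info).  The probe layout is
    shared across conditions of one study (as on a common microarray
    design) by passing ``probe_positions``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = simulate_ssdna(
        genome, params, sample_time, n_cells, rng, probe_positions=probe_positions
    )
    noisy = {
        c: add_array_noise(t, NOISE_LOG_SD, OUTLIER_RATE, rng) for c, t in raw.items()
    }
    smoothed = smooth_to_grid(filter_outliers(noisy), window_bp=window_bp)
    rescaled, info = rescale_track(smoothed)
    return smoothed, rescaled, info


def excess_areas(
    smoothed: dict[str, BinnedTrack],
    info: RescaleInfo,
    origins: list[OriginSpec],
    half_width: int = 5000,
) -> np.ndarray:
    """Baseline-subtracted window areas on the smoothed (un-normalized)
    scale.

    Per-sample max-rescaling cancels a uniform activity factor, so slope
    comparisons across depletion levels use these absolute areas: the sum
    of (smoothed − baseline) over the window, which scales directly with
    per-origin firing probability.
    """
    from .ssdna import peak_area

    n_pts = 2 * (half_width // 250) + 1
    return np.array(
        [
            peak_area(
                smoothed[o.chrom], o.position, half_width, baseline_fill=info.baseline
            )
            - n_pts * info.baseline
            for o in origins
        ]
    )


# Marker-frequency study conditions for the five-origin fixture: an
# unchallenged S phase (1 kb/min forks, 50 min) sequenced at the effort the
# profiles need to resolve origin apexes through a 50 kb smoothing window
# (~2000 reads/bin on a 1 Mb chromosome, i.e. a few million reads).
MFA_PARAMS = SimParams(fork_speed=1.0, s_duration=50.0)
MFA_DEPTH = 2000.0
MFA_N_CELLS = 20_000


def run_mfa_study(
    genome: GenomeMap,
    seed: int,
    params: SimParams = MFA_PARAMS,
    n_cells: int = MFA_N_CELLS,
    depth: float = MFA_DEPTH,
    window_bp: int = 50_000,
) -> dict[str, BinnedTrack]:
    """Simulate an asynchronous population and run the MFA pipeline:
    copy number → Poisson reads (S and G1 samples) → depth normalization →
    S/G1 ratio → 50 kb LOESS.  Returns the smoothed profile."""
    rng = np.random.default_rng(seed)
    mf = simulate_mfa(genome, params, n_cells, rng)
    s_counts = {c: add_poisson_reads(t, depth, rng) for c, t in mf.items()}
    g1_flat = {c: t.copy(values=np.ones(len(t))) for c, t in mf.items()}
    g1_counts = {c: add_poisson_reads(t, depth, rng) for c, t in g1_flat.items()}
    s_norm = normalize_depth(DepthTable("S", s_counts), genome)
    g1_norm = normalize_depth(DepthTable("G1", g1_counts), genome)
    return smooth_profile(marker_frequency(s_norm, g1_norm), window_bp)


def peak_trough_amplitudes(
    track: BinnedTrack, origin_positions: list[int]
) -> np.ndarray:
    """Per-origin peak-to-adjacent-trough amplitude of a smoothed profile.

    Peak = max within ±5 kb of the origin; troughs = minima of the
    segments between adjacent origins (and to the chromosome ends);
    amplitude = peak − mean of the two flanking troughs.
    """
    v, pos = track.values, track.positions
    xs = sorted(origin_positions)
    bounds = [int(pos[0])] + xs + [int(pos[-1])]
    troughs = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        m = (pos >= s) & (pos <= e)
        troughs.append(np.nanmin(v[m]))
    amps = []
    for i, x in enumerate(xs):
        m = (pos >= x - 5000) & (pos <= x + 5000)
        amps.append(np.nanmax(v[m]) - 0.5 * (troughs[i] + troughs[i + 1]))
    return np.array(amps)


def reference_origin_set(
    genome: GenomeMap,
    smoothed_wt: dict[str, BinnedTrack],
    tolerance: int = 2000,
) -> list[OriginSpec]:
    """Define the reusable origin set from the wild-type reference sample.

    Significant peaks (top 5%, 5 kb shoulder merge) are called on the
    smoothed wild-type profile and then confirmed against the known
    origin catalog within ``tolerance`` — the synthetic counterpart of
    cross-checking called peaks against a previously published origin
    list, which drops the handful of baseline-noise maxima that clear the
    top-5% quota.
    """
    ps = call_peaks(smoothed_wt, sample="wt-reference")
    called = [
        OriginSpec(f"peak_{i + 1:03d}", p.chrom, p.position, 1.0)
        for i, p in enumerate(ps.significant)
    ]
    catalog = [(o.chrom, o.position) for o in genome.origins]
    return select_origin_subset(called, genome, "listed", listed=catalog, tolerance=tolerance)
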