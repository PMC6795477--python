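import numpy as np
import pytest

from orifire.genome import Chromosome, GenomeMap, OriginSpec, make_demo_genome
from orifire.simulate import (
    SimParams,
    add_array_noise,
    add_poisson_reads,
    make_probe_positions,
    realize_firing,
    replicate_cell,
    simulate_mfa,
    simulate_rdna_array,
    simulate_ssdna,
)
from orifire.ssdna import _local_maxima, smooth_to_grid


def two_origin_genome(gap_bp, t1=0.0, t2=30.0):
    chrom = Chromosome("c", 1_000_000)
    return GenomeMap(
        (chrom,),
        (
            OriginSpec("a", "c", 300_000, 1.0, t_mean=t1, t_sd=0.0),
            OriginSpec("b", "c", 300_000 + gap_bp, 1.0, t_mean=t2, t_sd=0.0),
        ),
    )


class TestFiring:
    def test_deterministic_limit_all_fire_at_t_mean(self):
        g = make_demo_genome("five_origin")  # competence 1, t_sd 0, 200 kb apart
        cell = realize_firing(g, SimParams(), np.random.default_rng(0))
        assert cell.fired.all()
        assert np.array_equal(cell.fire_time, [o.t_mean for o in g.origins])

    def test_zero_competence_never_fires(self):
        g = make_demo_genome("five_origin")
        g = GenomeMap(
            g.chromosomes,
            tuple(
                OriginSpec(o.id, o.chrom, o.position, 0.0, o.t_mean, o.t_sd)
                for o in g.origins
            ),
        )
        cell = realize_firing(g, SimParams(), np.random.default_rng(0))
        assert cell.n_fired == 0

    def test_passive_replication_demotes_late_neighbor(self):
        # fork from the t=0 origin reaches a 1 kb-distant locus in 1 min,
        # long before its scheduled 30-min firing
        g = two_origin_genome(1000)
        params = SimParams(fork_speed=1.0)
        demoted = 0
        for seed in range(200):
            cell = realize_firing(g, params, np.random.default_rng(seed))
            if cell.fired[0] and not cell.fired[1]:
                demoted += 1
        assert demoted == 200

    def test_hu_mode_skips_passive_demotion(self):
        g = two_origin_genome(1000)
        params = SimParams(fork_speed=1.0, hu_mode=True, dntp_budget=10.0)
        cell = realize_firing(g, params, np.random.default_rng(0))
        assert cell.fired.all()


class TestForkBudget:
    def make_cell(self, genome, params, sample_time):
        cell = realize_firing(genome, params, np.random.default_rng(0))
        cell.sample_time = sample_time
        return replicate_cell(cell, genome, params)

    def test_single_origin_budget_split_between_two_forks(self):
        g = make_demo_genome("minimal")
        params = SimParams(hu_mode=True, fork_speed=100.0, dntp_budget=80.0)
        cell = self.make_cell(g, params, 1000.0)
        (s, e), = cell.replicated["chr1"]
        assert e - s == pytest.approx(80_000)  # 40 kb per fork

    def test_two_origins_halve_per_fork_travel(self):
        g = two_origin_genome(500_000, t1=0.0, t2=0.0)
        params = SimParams(hu_mode=True, fork_speed=100.0, dntp_budget=80.0)
        cell = self.make_cell(g, params, 1000.0)
        spans = cell.replicated["c"]
        assert len(spans) == 2
        for s, e in spans:
            assert e - s == pytest.approx(40_000)  # 20 kb per fork

    def test_completion_limit_covers_chromosome(self):
        g = make_demo_genome("five_origin")
        params = SimParams(fork_speed=2.0, s_duration=60.0)
        cell = self.make_cell(g, params, 1000.0)
        (s, e), = cell.replicated["chrS"]
        assert (s, e) == (1.0, 1_000_000.0)

    def test_population_halving_competence_doubles_travel(self):
        # budget-limited regime: mean per-fork travel = D/(2k) per cell
        chrom = Chromosome("c", 10_000_000)
        origins = tuple(
            OriginSpec(f"o{i}", "c", 200_000 + 300_000 * i, 0.8, 5.0, 2.0)
            for i in range(30)
        )
        g_full = GenomeMap((chrom,), origins)
        g_half = GenomeMap(
            (chrom,),
            tuple(
                OriginSpec(o.id, o.chrom, o.position, 0.4, o.t_mean, o.t_sd)
                for o in origins
            ),
        )
        params = SimParams(hu_mode=True, fork_speed=100.0, dntp_budget=100.0)

        def mean_travel(genome, seed0):
            travels = []
            for seed in range(seed0, seed0 + 300):
                cell = realize_firing(genome, params, np.random.default_rng(seed))
                if cell.n_fired == 0:
                    continue
                cell.sample_time = 1000.0
                travels.append(params.dntp_budget / (2 * cell.n_fired))
            return np.mean(travels)

        ratio = mean_travel(g_half, 0) / mean_travel(g_full, 1000)
        assert ratio == pytest.approx(2.0, rel=0.10)


class TestMfaSimulation:
    def test_all_g1_population_is_flat_one(self, five_origin_genome):
        params = SimParams(cell_cycle_fractions=(1.0, 0.0, 0.0))
        tracks = simulate_mfa(five_origin_genome, params, 50, np.random.default_rng(0))
        assert np.allclose(tracks["chrS"].values, 1.0)

    def test_marker_frequency_bounded_one_to_two(self, five_origin_genome):
        params = SimParams(fork_speed=1.0, s_duration=50.0)
        tracks = simulate_mfa(five_origin_genome, params, 500, np.random.default_rng(1))
        v = tracks["chrS"].values
        assert v.min() >= 1.0 and v.max() <= 2.0

    def test_zero_cells_rejected(self, five_origin_genome):
        with pytest.raises(ValueError):
            simulate_mfa(five_origin_genome, SimParams(), 0, np.random.default_rng(0))

    def test_pooled_maxima_sit_at_origins(self, five_origin_genome):
        # deterministic fork geometry: with full competence the pooled track
        # must peak at each origin bin
        params = SimParams(fork_speed=1.0, s_duration=50.0)
        tracks = simulate_mfa(five_origin_genome, params, 3000, np.random.default_rng(2))
        t = tracks["chrS"]
        for o in five_origin_genome.origins:
            off = min((m[0] - o.position for m in _local_maxima(t)), key=abs)
            assert abs(off) <= t.step


class TestSsdnaSimulation:
    def test_requires_hu_mode(self, minimal_genome):
        with pytest.raises(ValueError):
            simulate_ssdna(minimal_genome, SimParams(), 30.0, 10, np.random.default_rng(0))

    def test_zero_competence_gives_flat_baseline(self, minimal_genome):
        g = GenomeMap(
            minimal_genome.chromosomes,
            (OriginSpec("o", "chr1", 100_000, 0.0),),
        )
        params = SimParams(hu_mode=True)
        tracks = simulate_ssdna(g, params, 30.0, 20, np.random.default_rng(0))
        assert np.allclose(tracks["chr1"].values, 1.0)

    def test_single_peak_centered_at_efficient_origin(self, minimal_genome):
        probes = {"chr1": np.arange(80_000, 120_001, 100, dtype=np.int64)}
        params = SimParams(hu_mode=True, fork_speed=1.0, dntp_budget=1.0,
                           ssdna_footprint_sd=1000.0)
        tracks = simulate_ssdna(
            minimal_genome, params, 30.0, 1, np.random.default_rng(0),
            probe_positions=probes,
        )
        sm = smooth_to_grid(tracks, window_bp=6000)
        mx = [m for m in _local_maxima(sm["chr1"]) if m[1] > 1.01]
        assert len(mx) == 1
        assert abs(mx[0][0] - 100_000) <= 500

    def test_far_travel_splits_peak(self, minimal_genome):
        # travel 3 kb = 3x the footprint sd: two resolved fork signals
        probes = {"chr1": np.arange(80_000, 120_001, 100, dtype=np.int64)}
        params = SimParams(hu_mode=True, fork_speed=1.0, dntp_budget=6.0,
                           ssdna_footprint_sd=1000.0)
        tracks = simulate_ssdna(
            minimal_genome, params, 30.0, 1, np.random.default_rng(0),
            probe_positions=probes,
        )
        sm = smooth_to_grid(tracks, window_bp=6000)
        mx = [m for m in _local_maxima(sm["chr1"]) if m[1] > 1.01]
        assert len(mx) == 2
        assert sorted(abs(m[0] - 100_000) for m in mx) == pytest.approx(
            [3000, 3000], abs=500
        )


class TestRdnaArray:
    def test_expected_spacing_45kb_at_one_in_five_firing(self):
        s = simulate_rdna_array(
            150, 9000, 0.2, 1.5, 60.0, 10_000, np.random.default_rng(0)
        )
        assert s.spacing_analytic == pytest.approx(45_000)
        assert s.spacing_empirical == pytest.approx(45_000, rel=0.05)

    def test_full_firing_with_time_completes(self):
        s = simulate_rdna_array(50, 9000, 1.0, 1.5, 10.0, 200, np.random.default_rng(1))
        # 9 kb at 1.5 kb/min needs 6 min < 10 min budget
        assert s.p_complete == 1.0
        assert np.allclose(s.frac_replicated, 1.0)

    def test_probability_no_initiation_matches_closed_form(self):
        p = 0.05
        n_rep = 90
        expected = (1 - p) ** n_rep  # ~0.0099
        s = simulate_rdna_array(
            n_rep, 9000, p, 1.5, 60.0, 30_000, np.random.default_rng(2)
        )
        p_zero = float((s.frac_replicated == 0).mean())
        assert p_zero == pytest.approx(expected, abs=3 * np.sqrt(expected / 30_000) + 1e-4)

    def test_zero_firing_is_valid_and_incomplete(self):
        s = simulate_rdna_array(50, 9000, 0.0, 1.5, 60.0, 100, np.random.default_rng(3))
        assert s.p_complete == 0.0
        assert np.isnan(s.spacing_empirical)

    def test_bad_p_fire_rejected(self):
        with pytest.raises(ValueError):
            simulate_rdna_array(50, 9000, 1.5, 1.5, 60.0, 10, np.random.default_rng(0))


class TestNoiseLayers:
    def test_poisson_counts_mean_and_determinism(self):
        from orifire.genome import BinnedTrack

        flat = BinnedTrack("c", 1, 1000, np.ones(2000))
        rng = np.random.default_rng(5)
        counts = add_poisson_reads(flat, 100.0, rng)
        se = np.sqrt(100.0 / 2000)
        assert counts.values.mean() == pytest.approx(100.0, abs=3 * se)
        again = add_poisson_reads(flat, 100.0, np.random.default_rng(5))
        assert np.array_equal(counts.values, again.values)

    def test_poisson_tracks_copy_number(self):
        from orifire.genome import BinnedTrack

        twofold = BinnedTrack("c", 1, 1000, np.concatenate([np.ones(3000), 2 * np.ones(3000)]))
        counts = add_poisson_reads(twofold, 200.0, np.random.default_rng(6))
        lo = counts.values[:3000].mean()
        hi = counts.values[3000:].mean()
        assert hi / lo == pytest.approx(2.0, rel=0.05)

    def test_array_noise_identity_and_spike_rate(self):
        from orifire.genome import ProbeTrack

        t = ProbeTrack("c", np.arange(1, 10_001) * 10, np.ones(10_000))
        same = add_array_noise(t, 0.0, 0.0, np.random.default_rng(0))
        assert np.array_equal(same.values, t.values)
        noisy = add_array_noise(t, 0.0, 0.001, np.random.default_rng(1))
        n_spikes = int((noisy.values > 10).sum())
        assert 2 <= n_spikes <= 25  # ~Binomial(10000, 1e-3)
        again = add_array_noise(t, 0.0, 0.001, np.random.default_rng(1))
        assert np.array_equal(noisy.values, again.values)

    def test_probe_positions_mean_spacing(self):
        g = make_demo_genome("five_origin")
        probes = make_probe_positions(g, np.random.default_rng(0))
        gaps = np.diff(probes["chrS"])
        assert gaps.mean() == pytest.approx(1000, rel=0.1)
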