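import numpy as np
import pytest

from orifire.genome import BinnedTrack, ProbeTrack
from orifire.ssdna import (
    call_peaks,
    filter_outliers,
    form_ratio,
    peak_area,
    rescale_track,
    smooth_to_grid,
)


def probe(chrom, positions, values):
    return ProbeTrack(chrom, np.asarray(positions), np.asarray(values, float))


class TestFormRatio:
    def test_identical_channels_give_unity(self):
        s = {"c": probe("c", [10, 20], [2.0, 3.0])}
        g = {"c": probe("c", [10, 20], [2.0, 3.0])}
        out = form_ratio(s, g)
        assert np.allclose(out["c"].values, 1.0)

    def test_ratio_value(self):
        out = form_ratio(
            {"c": probe("c", [10], [3.0])}, {"c": probe("c", [10], [1.5])}
        )
        assert out["c"].values[0] == 2.0

    def test_zero_g1_probe_dropped(self):
        out = form_ratio(
            {"c": probe("c", [10, 20], [3.0, 3.0])},
            {"c": probe("c", [10, 20], [1.5, 0.0])},
        )
        assert len(out["c"]) == 1
        assert out["c"].positions[0] == 10

    def test_position_mismatch_rejected(self):
        with pytest.raises(ValueError):
            form_ratio(
                {"c": probe("c", [10], [1.0])}, {"c": probe("c", [11], [1.0])}
            )


class TestOutlierFilter:
    def test_uniform_values_all_retained(self):
        t = {"c": probe("c", np.arange(1, 11) * 100, np.ones(10))}
        out = filter_outliers(t)
        assert len(out["c"]) == 10

    def test_extreme_high_value_removed(self):
        # 1000 ones plus 1e6: mean+8SD ~ 2.5e5 < 1e6
        pos = np.arange(1, 1002) * 100
        vals = np.ones(1001)
        vals[-1] = 1e6
        out = filter_outliers({"c": probe("c", pos, vals)})
        assert len(out["c"]) == 1000
        assert out["c"].values.max() == 1.0

    def test_low_value_removed_at_two_sd(self):
        # 100 ones plus -5: mean ~0.94, SD ~0.60, lower bound ~ -0.25
        pos = np.arange(1, 102) * 100
        vals = np.ones(101)
        vals[-1] = -5.0
        out = filter_outliers({"c": probe("c", pos, vals)})
        assert len(out["c"]) == 100
        assert out["c"].values.min() == 1.0

    def test_statistics_are_genome_wide(self):
        # the spike on c2 is judged against the pooled mean/SD
        t = {
            "c1": probe("c1", np.arange(1, 501) * 100, np.ones(500)),
            "c2": probe("c2", np.arange(1, 502) * 100, np.append(np.ones(500), 1e6)),
        }
        out = filter_outliers(t)
        assert len(out["c1"]) == 500
        assert len(out["c2"]) == 500

    def test_second_pass_removes_little(self):
        rng = np.random.default_rng(0)
        vals = np.exp(rng.normal(0, 0.2, 5000))
        t = {"c": probe("c", np.arange(1, 5001) * 100, vals)}
        once = filter_outliers(t)
        twice = filter_outliers(once)
        assert len(twice["c"]) >= 0.99 * len(once["c"])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            filter_outliers({"c": probe("c", [1], [1.0])})


class TestSmoothToGrid:
    def test_constant_probes_give_constant_grid(self):
        t = {"c": probe("c", np.arange(1, 101) * 1000, np.full(100, 2.0))}
        out = smooth_to_grid(t)
        assert out["c"].step == 250
        v = out["c"].values
        assert np.allclose(v[np.isfinite(v)], 2.0, atol=1e-12)

    def test_linear_probes_give_linear_grid(self):
        pos = np.arange(1, 101) * 1000
        t = {"c": probe("c", pos, 1.0 + pos * 1e-5)}
        out = smooth_to_grid(t)
        expect = 1.0 + out["c"].positions * 1e-5
        inner = slice(40, -40)
        assert np.allclose(out["c"].values[inner], expect[inner], atol=1e-9)

    def test_empty_chromosome_warns_and_returns_empty(self, caplog):
        out = smooth_to_grid({"c": probe("c", [], [])})
        assert len(out["c"]) == 0


class TestRescale:
    def make_tracks(self):
        rng = np.random.default_rng(1)
        base = rng.normal(1.0, 0.02, 4000)
        base[1000] = 4.0  # the genome-wide max
        return {"c": BinnedTrack("c", 1, 250, base)}

    def test_max_maps_to_two_and_baseline_to_one(self):
        out, info = rescale_track(self.make_tracks())
        v = out["c"].values
        assert v.max() == pytest.approx(2.0, abs=1e-12)
        # a value equal to the baseline maps exactly to 1.0
        assert (info.baseline - info.baseline) / (info.vmax - info.baseline) + 1 == 1.0

    def test_midpoint_maps_to_one_and_a_half(self):
        tracks = self.make_tracks()
        out, info = rescale_track(tracks)
        mid = (info.baseline + info.vmax) / 2
        got = (mid - info.baseline) / (info.vmax - info.baseline) + 1
        assert got == pytest.approx(1.5)

    def test_order_preserved(self):
        tracks = self.make_tracks()
        out, _ = rescale_track(tracks)
        assert np.array_equal(
            np.argsort(tracks["c"].values), np.argsort(out["c"].values)
        )

    def test_flat_genome_rejected(self):
        with pytest.raises(ValueError):
            rescale_track({"c": BinnedTrack("c", 1, 250, np.full(100, 1.0))})


def bump(center, grid, height, sd=1500.0):
    return height * np.exp(-0.5 * ((grid - center) / sd) ** 2)


class TestCallPeaks:
    def test_monotone_track_has_no_peaks(self):
        t = {"c": BinnedTrack("c", 1, 250, np.linspace(1, 2, 500))}
        ps = call_peaks(t)
        assert ps.n_raw == 0

    def test_two_bumps_among_noise_are_the_significant_peaks(self):
        grid = 1 + 250 * np.arange(400)  # 100 kb
        # ~40 baseline "noise" maxima of continuously varying height
        ripple = 0.002 * np.sin(grid / 400.0) * (1.5 + np.sin(grid / 9000.0))
        v = 1.0 + ripple + bump(30_000, grid, 1.0) + bump(80_000, grid, 0.8)
        ps = call_peaks({"c": BinnedTrack("c", 1, 250, v)})
        # oracle: enumerate maxima directly
        raw = [
            i
            for i in range(1, len(v) - 1)
            if v[i] > v[i - 1] and v[i] > v[i + 1]
        ]
        assert ps.n_raw == len(raw)
        sig = sorted(ps.significant, key=lambda p: p.position)
        assert len(sig) == 2
        assert abs(sig[0].position - 30_001) <= 250
        assert abs(sig[1].position - 80_001) <= 250

    def test_threshold_is_95th_percentile_of_raw_heights(self):
        grid = 1 + 250 * np.arange(800)
        v = 1.0 + 0.002 * np.sin(grid / 450.0) + bump(50_000, grid, 1.0)
        ps = call_peaks({"c": BinnedTrack("c", 1, 250, v)})
        heights = [p.height for p in ps.peaks]
        assert ps.threshold == pytest.approx(np.quantile(heights, 0.95))

    def test_shoulder_peak_within_5kb_merged_into_taller(self):
        grid = 1 + 250 * np.arange(800)
        v = (
            1.0
            + 0.002 * np.sin(grid / 450.0)
            + bump(50_000, grid, 1.0, sd=800.0)
            + bump(53_000, grid, 0.6, sd=800.0)
            + bump(150_000, grid, 0.9, sd=800.0)
        )
        ps = call_peaks({"c": BinnedTrack("c", 1, 250, v)})
        sig_pos = sorted(p.position for p in ps.significant)
        # the 53 kb shoulder is gone from the significant set ...
        assert all(abs(p - 53_001) > 500 for p in sig_pos)
        assert any(abs(p - 50_001) <= 250 for p in sig_pos)
        assert any(abs(p - 150_001) <= 250 for p in sig_pos)
        # ... and is recorded as merged into the taller 50 kb peak
        merged = {
            p.position: p.merged_into.position
            for p in ps.peaks
            if p.merged_into is not None
        }
        shoulder = [p for p in merged if abs(p - 53_001) <= 500]
        assert len(shoulder) == 1
        assert abs(merged[shoulder[0]] - 50_001) <= 250

    def test_significant_peaks_at_least_merge_distance_apart(self):
        rng = np.random.default_rng(0)
        v = 1.0 + np.cumsum(rng.normal(0, 0.01, 4000))
        ps = call_peaks({"c": BinnedTrack("c", 1, 250, v)})
        pos = sorted(p.position for p in ps.significant)
        assert all(b - a >= 5000 for a, b in zip(pos, pos[1:]))


class TestPeakArea:
    def test_flat_baseline_10kb_window_sums_to_41(self):
        t = BinnedTrack("c", 1, 250, np.ones(800))
        assert peak_area(t, 100_001, 5000) == pytest.approx(41.0)

    def test_flat_baseline_16kb_window_sums_to_65(self):
        t = BinnedTrack("c", 1, 250, np.ones(800))
        assert peak_area(t, 100_001, 8000) == pytest.approx(65.0)

    def test_bump_mass_matches_direct_summation(self):
        grid = 1 + 250 * np.arange(800)
        v = 1.0 + bump(100_001, grid, 0.7, sd=1000.0)
        t = BinnedTrack("c", 1, 250, v)
        lo = np.searchsorted(grid, 100_001 - 5000)
        hi = np.searchsorted(grid, 100_001 + 5000, side="right")
        assert peak_area(t, 100_001, 5000) == pytest.approx(float(v[lo:hi].sum()))

    def test_missing_points_filled_with_baseline(self):
        v = np.ones(800)
        v[395:405] = np.nan
        t = BinnedTrack("c", 1, 250, v)
        assert peak_area(t, 99_001, 5000) == pytest.approx(41.0)

    def test_off_chromosome_origin_rejected(self):
        t = BinnedTrack("c", 1, 250, np.ones(100))
        with pytest.raises(ValueError):
            peak_area(t, 10**7, 5000)
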