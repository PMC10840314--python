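"""LC-series analysis: scattergrams, peaks, validity, searches, baselines."""

import numpy as np
import pytest

from saskit.exceptions import ValidationError
from saskit.sasdata import FrameRange, Profile, Series
from saskit.series_lc import (SeriesConfig, apply_baseline, baseline_integral,
                              baseline_linear, final_profile, find_buffer_range,
                              find_peaks, find_sample_range, scattergram,
                              significant_svs, sliding_rg_mw, series_scale_trim,
                              subtract_series, subtracted_matrices,
                              validate_buffer_range, validate_sample_range)
from saskit.synthetic import (ComponentSpec, SecSpec, simulate_preset,
                              simulate_sec, inject_drift)

from conftest import RG_SPHERE_40


@pytest.fixture(scope="module")
def single_series():
    series, truth = simulate_preset("single", seed=0)
    return series, truth


@pytest.fixture(scope="module")
def processed_single():
    """Single-species series after subtraction and traces (module-shared)."""
    series, truth = simulate_preset("single", seed=0)
    subtract_series(series, [FrameRange(0, 19)])
    traces = sliding_rg_mw(series)
    return series, truth, traces


class TestScattergram:
    def test_total_of_tiny_profile(self):
        q = np.array([0.1, 0.2, 0.3])
        profiles = [Profile(q, [1, 3, 0], [1, 1, 1]),
                    Profile(q, [2, 2, 2], [1, 1, 1])]
        s = Series(profiles)
        assert scattergram(s, "total").tolist() == [4, 6]
        assert scattergram(s, "mean").tolist() == [4 / 3, 2]

    def test_qrange_covering_grid_equals_total(self, single_series):
        series, _ = single_series
        full = scattergram(series, "qrange", qrange=(0.0, 1.0))
        assert np.allclose(full, scattergram(series, "total"))

    def test_flat_buffer_constant_within_noise(self, single_series):
        series, truth = single_series
        tr = scattergram(series, "total")[truth.buffer_frames[:20]]
        assert tr.std() / tr.mean() < 0.01

    def test_bad_modes_rejected(self, single_series):
        series, _ = single_series
        with pytest.raises(ValidationError):
            scattergram(series, "qrange", qrange=(0.9, 1.0))
        with pytest.raises(ValidationError):
            scattergram(series, "nope")


class TestFindPeaks:
    def test_single_gaussian_apex_located(self, single_series):
        series, _ = single_series
        peaks = find_peaks(scattergram(series, "total"))
        assert len(peaks) == 1
        assert abs(peaks[0].apex - 60) <= 2
        assert peaks[0].left_base < 60 < peaks[0].right_base

    def test_flat_noise_rarely_peaks(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            tr = rng.normal(100.0, 1.0, 80)
            hits += len(find_peaks(tr)) > 0
        assert hits <= 0.05 * n_rep

    def test_two_gaussians_ordered_by_height(self):
        f = np.arange(120)
        tr = (1000 * np.exp(-0.5 * ((f - 40) / 4) ** 2)
              + 400 * np.exp(-0.5 * ((f - 85) / 4) ** 2) + 50)
        peaks = find_peaks(tr)
        assert len(peaks) == 2
        assert abs(peaks[0].apex - 40) <= 2
        assert abs(peaks[1].apex - 85) <= 2


class TestSignificantSVs:
    def test_buffer_only_is_rank_one(self, single_series):
        series, truth = single_series
        sel = truth.buffer_frames[:20]
        assert significant_svs(series.intensity_matrix()[sel],
                               series.sigma_matrix()[sel]) == 1

    def test_noise_only_is_rank_zero(self):
        rng = np.random.default_rng(3)
        hits = sum(
            significant_svs(rng.normal(0, 1, (12, 150)), np.ones((12, 150))) == 0
            for _ in range(20))
        assert hits >= 18  # >= 90% of replicates

    def test_two_shape_stack_is_rank_two(self):
        q = np.linspace(0.01, 0.3, 150)
        rng = np.random.default_rng(1)
        a = np.exp(-q * 5)
        b = np.exp(-((q - 0.1) / 0.1) ** 2)
        frames = np.arange(20)
        c1 = np.exp(-0.5 * ((frames - 8) / 4) ** 2)
        c2 = np.exp(-0.5 * ((frames - 12) / 4) ** 2)
        i_mat = np.outer(c1, a) + np.outer(c2, b)
        i_mat += rng.normal(0, 1e-3, i_mat.shape)
        assert significant_svs(i_mat, np.full(i_mat.shape, 1e-3)) == 2

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValidationError):
            significant_svs(np.ones((2, 50)))


class TestBufferValidation:
    def test_flat_buffer_range_valid(self, single_series):
        series, _ = single_series
        rep = validate_buffer_range(series, [FrameRange(0, 19)])
        assert rep.valid
        assert [t.name for t in rep.tests] == [
            "intensity-correlation", "similarity", "svd-rank"]

    def test_elution_tail_rejected_with_short_circuit(self, single_series):
        series, _ = single_series
        rep = validate_buffer_range(series, [FrameRange(40, 60)])
        assert not rep.valid
        # later tests must be absent after the first failure
        failed_at = next(i for i, t in enumerate(rep.tests) if not t.passed)
        assert failed_at == len(rep.tests) - 1

    def test_step_background_rejected(self):
        """Two different static backgrounds in one range are not a valid
        buffer, whichever test catches it first."""
        q = np.linspace(0.01, 0.3, 150)
        rng = np.random.default_rng(0)
        shape1 = 100 * np.exp(-q * 3)
        shape2 = shape1 + 5 * np.sin(q * 40)  # equal scale, different shape
        profiles = []
        for k in range(20):
            base = shape1 if k < 10 else shape2
            sig = np.full_like(q, 1.0)
            profiles.append(Profile(q, base + rng.normal(0, 1, len(q)), sig))
        rep = validate_buffer_range(Series(profiles), [FrameRange(0, 19)])
        assert not rep.valid


class TestBufferSearch:
    def test_single_preset_range_in_true_buffer(self, single_series):
        series, truth = single_series
        ranges, rep = find_buffer_range(series)
        assert ranges and rep.valid
        sel = set(range(ranges[0].start, ranges[0].end + 1))
        assert sel <= set(truth.buffer_frames.tolist())

    def test_contaminant_mostly_avoided(self):
        hits = 0
        n_rep = 15
        for s in range(n_rep):
            series, truth = simulate_preset("contaminant", seed=s)
            ranges, _ = find_buffer_range(series)
            if not ranges:
                continue
            sel = np.arange(ranges[0].start, ranges[0].end + 1)
            conc = truth.concentrations[1]  # contaminant species
            if conc[sel].max() < 0.01 * conc.max():
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_all_elution_series_yields_empty(self):
        spec = SecSpec(components=[ComponentSpec("sphere", 40.0, 100.0,
                                                 center=50, width=40.0)],
                       n_frames=100)
        series, _ = simulate_sec(spec, seed=0)
        ranges, rep = find_buffer_range(series)
        assert ranges == []
        assert not rep.valid


class TestSubtraction:
    def test_buffer_only_series_subtracts_to_zero_mean(self, single_series):
        series, truth = single_series
        s = series.shallow_copy()
        subtract_series(s, [FrameRange(0, 19)])
        sel = truth.buffer_frames[truth.buffer_frames > 25][:10]
        i_sub, s_sub = subtracted_matrices(s)
        pulls = i_sub[sel] / s_sub[sel]
        assert abs(np.mean(pulls)) < 0.1

    def test_apex_profile_matches_component_within_noise(self, single_series):
        series, truth = single_series
        s = series.shallow_copy()
        subtract_series(s, [FrameRange(0, 19)])
        i_sub, s_sub = subtracted_matrices(s)
        apex = 60
        expected = truth.concentrations[0, apex] * truth.component_intensity[0]
        pulls = (i_sub[apex] - expected) / s_sub[apex]
        assert np.mean(np.abs(pulls) < 3) > 0.99

    def test_resubtraction_is_idempotent(self, single_series):
        series, _ = single_series
        s = series.shallow_copy()
        subtract_series(s, [FrameRange(0, 19)])
        first = s.subtracted_i.copy()
        subtract_series(s, [FrameRange(0, 19)])
        assert np.array_equal(first, s.subtracted_i)


class TestTraces:
    def test_rg_plateau_across_peak(self, processed_single):
        series, truth, traces = processed_single
        tr = traces.scattergram
        half = np.flatnonzero(tr > 0.5 * tr.max())
        plateau = traces.rg[half]
        assert np.all(np.isfinite(plateau))
        assert np.nanmedian(np.abs(plateau / RG_SPHERE_40 - 1)) < 0.03

    def test_buffer_frames_are_gaps(self, processed_single):
        series, truth, traces = processed_single
        early = truth.buffer_frames[truth.buffer_frames < 30][5:15]
        assert np.all(np.isnan(traces.rg[early]))

    def test_window_one_equals_per_frame(self):
        from saskit.guinier import auto_guinier
        series, _ = simulate_preset("single", seed=3)
        subtract_series(series, [FrameRange(0, 19)])
        traces = sliding_rg_mw(series, window=1)
        i_sub, s_sub = subtracted_matrices(series)
        f = 60
        res = auto_guinier(Profile(series.q, i_sub[f], s_sub[f]))
        assert traces.rg[f] == pytest.approx(res.rg, rel=1e-12)

    def test_even_window_rejected(self, processed_single):
        series, _, _ = processed_single
        with pytest.raises(ValidationError):
            sliding_rg_mw(series, window=4)


class TestSampleValidation:
    def test_apex_region_valid_with_all_five_tests(self, processed_single):
        """An apex-centered range found by the search revalidates cleanly
        and the report lists all five tests in order."""
        series, _, _ = processed_single
        ranges, _ = find_sample_range(series)
        assert ranges
        rep = validate_sample_range(series, ranges)
        assert rep.valid
        assert [t.name for t in rep.tests] == [
            "rg-mw-presence", "rg-mw-correlation", "similarity", "svd-rank",
            "sn-improvement"]

    def test_range_with_gaps_fails_presence(self, processed_single):
        series, _, _ = processed_single
        rep = validate_sample_range(series, [FrameRange(5, 15)])
        assert not rep.valid
        assert rep.tests[0].name == "rg-mw-presence"
        assert len(rep.tests) == 1  # short-circuited

    def test_two_species_range_fails_trend_or_rank(self):
        series, _ = simulate_preset("overlap", seed=0)
        subtract_series(series, [FrameRange(0, 19)])
        sliding_rg_mw(series)
        rep = validate_sample_range(series, [FrameRange(50, 70)])
        assert not rep.valid
        failed = {t.name for t in rep.tests if not t.passed}
        assert failed & {"rg-mw-correlation", "svd-rank", "similarity"}

    def test_deep_tail_fails_sn_improvement(self, processed_single):
        """Frames far into the noise floor should not improve the average."""
        series, _, _ = processed_single
        from saskit.series_lc import _sn_improvement_test
        i_sub, s_sub = subtracted_matrices(series)
        sel = np.concatenate([np.arange(55, 66), np.arange(5, 15)])
        rec = _sn_improvement_test(i_sub[sel], s_sub[sel], SeriesConfig())
        assert not rec.passed


class TestSampleSearch:
    def test_single_preset_range_is_pure(self, processed_single):
        series, truth, _ = processed_single
        ranges, rep = find_sample_range(series)
        assert ranges and rep.valid
        sel = set(range(ranges[0].start, ranges[0].end + 1))
        assert sel <= set(truth.pure_sample_frames.tolist())

    def test_overlap_preset_lands_in_high_purity_frames(self):
        series, truth = simulate_preset("overlap", seed=0)
        subtract_series(series, [FrameRange(0, 19)])
        sliding_rg_mw(series)
        ranges, rep = find_sample_range(series)
        assert ranges
        sel = np.arange(ranges[0].start, ranges[0].end + 1)
        fwd = truth.component_intensity[:, 0]
        sig = truth.concentrations.T @ fwd
        purity = (truth.concentrations.T * fwd).max(axis=1) / sig
        assert purity[sel].min() >= 0.95

    def test_peakless_series_yields_empty(self):
        q = np.linspace(0.01, 0.3, 60)
        rng = np.random.default_rng(0)
        profiles = [Profile(q, rng.normal(100, 1, 60) * np.exp(-q),
                            np.full(60, 1.0)) for _ in range(30)]
        s = Series(profiles)
        s.subtracted_i = s.intensity_matrix() - 100 * np.exp(-q)[None, :]
        s.subtracted_sigma = s.sigma_matrix()
        s.analysis["traces"] = {"rg": [np.nan] * 30, "mw": [np.nan] * 30}
        ranges, rep = find_sample_range(s)
        assert ranges == []


class TestFinalProfile:
    def test_matches_component_within_two_sigma(self, single_series):
        series, truth = single_series
        s = series.shallow_copy()
        subtract_series(s, [FrameRange(0, 19)])
        out = final_profile(s, sample_ranges=[FrameRange(57, 63)])
        sel = np.arange(57, 64)
        expected = (truth.concentrations[0, sel].mean()
                    * truth.component_intensity[0])
        pulls = (out.intensity - expected) / out.sigma
        assert np.mean(np.abs(pulls) < 2) >= 0.95

    def test_sigma_honest_versus_naive_subtracted_average(self, single_series):
        """Averaging already-subtracted frames treats the shared buffer noise
        as independent and underestimates sigma by construction; the
        subtract-after-averaging profile reports the honest, larger value."""
        series, _ = single_series
        s = series.shallow_copy()
        subtract_series(s, [FrameRange(0, 19)])
        out = final_profile(s, sample_ranges=[FrameRange(57, 63)])
        i_sub, s_sub = subtracted_matrices(s)
        naive = np.sqrt((s_sub[57:64] ** 2).sum(axis=0)) / 7
        assert np.all(out.sigma > naive)
        # and the exact algebra: sigma^2 = sum(sigma_frame^2)/k^2 + sigma_buf^2
        k = 7
        want = np.sqrt((s.sigma_matrix()[57:64] ** 2).sum(axis=0) / k ** 2
                       + s.buffer_profile.sigma ** 2)
        assert np.allclose(out.sigma, want, rtol=1e-12)

    def test_missing_ranges_rejected(self, single_series):
        series, _ = single_series
        s = series.shallow_copy()
        with pytest.raises(ValidationError):
            final_profile(s)


class TestBaselines:
    def _drifted(self, kind, magnitude, seed=0):
        series, truth = simulate_preset("single", seed=seed)
        drifted = inject_drift(series, kind, magnitude)
        subtract_series(drifted, [FrameRange(0, 9)])
        return series, drifted

    def test_linear_slope_recovered_within_five_percent(self):
        m = 0.1  # drift per frame at g(q) = 1
        _, drifted = self._drifted("linear", m * 99)
        bl = baseline_linear(drifted, FrameRange(0, 9), FrameRange(90, 99),
                             extrapolate_all=True)
        g = np.exp(-drifted.q / 0.1)
        slope_rec = (bl.baseline[-1] - bl.baseline[0]) / 99
        mask = g > 0.05
        assert np.median(slope_rec[mask] / (m * g[mask])) == pytest.approx(
            1.0, abs=0.05)

    def test_zero_drift_baseline_is_null(self):
        series, _ = simulate_preset("single", seed=2)
        subtract_series(series, [FrameRange(0, 9)])
        bl = baseline_linear(series, FrameRange(0, 9), FrameRange(90, 99))
        i_sub, s_sub = subtracted_matrices(series)
        assert np.all(np.abs(bl.baseline) < 3 * s_sub.max())

    def test_start_range_mean_zero_after_correction(self):
        _, drifted = self._drifted("linear", 10.0)
        bl = baseline_linear(drifted, FrameRange(0, 9), FrameRange(90, 99))
        apply_baseline(drifted, bl)
        i_corr, s_sub = subtracted_matrices(drifted)
        start_mean = i_corr[0:10].mean(axis=0)
        noise = s_sub[0:10].mean(axis=0) / np.sqrt(10)
        assert np.mean(np.abs(start_mean) < 3 * noise) > 0.99

    def test_integral_correction_restores_end_to_start(self):
        _, drifted = self._drifted("integral", 8.0, seed=1)
        bl = baseline_integral(drifted, FrameRange(0, 9), FrameRange(90, 99))
        assert bl.converged
        apply_baseline(drifted, bl)
        i_corr, s_sub = subtracted_matrices(drifted)
        diff = i_corr[90:100].mean(axis=0) - i_corr[0:10].mean(axis=0)
        noise = np.hypot(s_sub[90:100].mean(axis=0),
                         s_sub[0:10].mean(axis=0)) / np.sqrt(10)
        assert np.mean(np.abs(diff) < 3 * noise) > 0.99

    def test_integral_baseline_monotone_non_negative(self):
        _, drifted = self._drifted("integral", 8.0)
        bl = baseline_integral(drifted, FrameRange(0, 9), FrameRange(90, 99))
        assert np.all(bl.baseline >= 0)
        assert np.all(np.diff(bl.baseline, axis=0) >= -1e-12)

    def test_zero_difference_gives_zero_baseline(self):
        series, _ = simulate_preset("single", seed=3)
        subtract_series(series, [FrameRange(0, 9)])
        # start and end in statistically identical buffer: d(q) clipped at 0
        bl = baseline_integral(series, FrameRange(0, 4), FrameRange(95, 99))
        assert bl.baseline.max() <= np.max(
            np.clip(series.subtracted_i[95:100].mean(axis=0)
                    - series.subtracted_i[0:5].mean(axis=0), 0, None)) + 1e-9

    def test_baselines_do_not_touch_raw_data(self):
        series, drifted = self._drifted("linear", 10.0)
        snap = drifted.intensity_matrix().copy()
        bl = baseline_linear(drifted, FrameRange(0, 9), FrameRange(90, 99))
        apply_baseline(drifted, bl)
        assert np.array_equal(drifted.intensity_matrix(), snap)

    def test_overlapping_ranges_rejected(self):
        _, drifted = self._drifted("linear", 10.0)
        with pytest.raises(ValidationError):
            baseline_linear(drifted, FrameRange(0, 50), FrameRange(40, 99))


class TestScaleTrim:
    def test_scale_round_trip_identity(self, single_series):
        series, _ = single_series
        out = series_scale_trim(series_scale_trim(series, "scale", factor=2.0),
                                "scale", factor=0.5)
        assert np.allclose(out.intensity_matrix(), series.intensity_matrix(),
                           rtol=1e-12)

    def test_scattergram_linearity(self, single_series):
        series, _ = single_series
        doubled = series_scale_trim(series, "scale", factor=2.0)
        assert np.allclose(scattergram(doubled, "total"),
                           2 * scattergram(series, "total"))

    def test_trim_keeps_shared_grid(self, single_series):
        series, _ = single_series
        out = series_scale_trim(series, "trim", qmin=0.02, qmax=0.2)
        assert all(np.array_equal(p.q, out.q) for p in out.profiles)
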