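import numpy as np
import pytest

from wavetrace import tracking as trk
from wavetrace._loess import loess_smooth
from wavetrace.errors import ConfigError, DataError
from wavetrace.scan import ProfileSet


def make_profiles(intensity, pixel=1.0, dt=2.0):
    intensity = np.asarray(intensity, dtype=float)
    nd, nt = intensity.shape
    return ProfileSet(distances=np.arange(nd) * pixel,
                      times=np.arange(nt) * dt,
                      intensity=intensity, pixel_size=pixel)


class TestLoess:
    def test_reproduces_linear_data(self):
        x = np.linspace(0, 10, 40)
        y = 3.0 * x - 2.0
        out = loess_smooth(x, y, span=0.5)
        np.testing.assert_allclose(out, y, rtol=1e-6, atol=1e-6)

    def test_span_one_on_quadratic(self):
        x = np.linspace(-5, 5, 60)
        y = 2 * x ** 2 - x + 1
        out = loess_smooth(x, y, span=1.0)
        np.testing.assert_allclose(out, y, rtol=1e-6, atol=1e-6)

    def test_noise_around_constant_stays_in_band(self):
        rng = np.random.default_rng(77)
        x = np.linspace(0, 100, 200)
        y = 5.0 + rng.normal(0, 1.0, x.size)
        out = loess_smooth(x, y, span=0.5)
        # smoothed curve stays well inside the raw noise band around c
        assert np.abs(out - 5.0).max() < 1.96

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            loess_smooth(np.arange(5.0), np.arange(5.0))

    def test_bad_span_rejected(self):
        x = np.arange(20.0)
        with pytest.raises(DataError):
            loess_smooth(x, x, span=0.0)
        with pytest.raises(DataError):
            loess_smooth(x, x, span=1.5)

    def test_smooth_profile_span_zero_is_identity(self):
        y = np.arange(15.0)
        np.testing.assert_array_equal(
            trk.smooth_profile(np.arange(15.0), y, span=0), y)


class TestBaselineModel:
    def test_stated_formulas(self):
        bl = trk.BaselineModel(baseline=100.0, sd_bar=5.0)
        assert bl.noise_upper == pytest.approx(109.8)
        assert bl.noise_lower == pytest.approx(90.2)
        assert bl.front_threshold == pytest.approx(105.0)

    def test_zero_noise_band_collapses(self):
        bl = trk.BaselineModel(baseline=42.0, sd_bar=0.0)
        assert bl.noise_upper == bl.noise_lower == bl.front_threshold == 42.0

    def test_json_round_trip(self, tmp_path):
        bl = trk.BaselineModel(10.0, 2.0)
        bl.to_json(tmp_path / "b.json")
        back = trk.BaselineModel.from_json(tmp_path / "b.json")
        assert back == bl


class TestEstimateBaseline:
    def test_constant_field(self):
        ps = make_profiles(np.full((20, 5), 100.0))
        bl = trk.estimate_baseline(ps, pre_frames=[0, 1])
        assert bl.baseline == 100.0 and bl.sd_bar == 0.0

    def test_sd_bar_is_mean_of_per_time_sds(self):
        rng = np.random.default_rng(3)
        data = 50.0 + rng.normal(0, 4.0, (200, 6))
        ps = make_profiles(data)
        bl = trk.estimate_baseline(ps, pre_frames=np.arange(6))
        expected_sd = data.std(axis=0, ddof=1).mean()
        assert bl.sd_bar == pytest.approx(expected_sd)
        assert bl.baseline == pytest.approx(data.mean())

    def test_recovers_generator_baseline(self, small_local_wave):
        params, _, _, profiles = small_local_wave
        bl = trk.estimate_baseline(profiles, pre_frames=list(range(5)))
        assert bl.baseline == pytest.approx(params.baseline, rel=0.01)

    def test_sd_floor(self):
        ps = make_profiles(np.full((20, 5), 10.0))
        bl = trk.estimate_baseline(ps, pre_frames=[0], sd_floor=2.5)
        assert bl.sd_bar == 2.5

    def test_empty_region_rejected(self):
        ps = make_profiles(np.zeros((10, 3)))
        with pytest.raises(ConfigError):
            trk.estimate_baseline(ps)
        with pytest.raises(ConfigError):
            trk.estimate_baseline(ps, pre_frames=[])


class TestFindLocalMaxima:
    def test_single_gaussian_bump(self):
        d = np.arange(0.0, 400.0, 2.0)
        v = np.exp(-((d - 200.0) / 30.0) ** 2)
        out = trk.find_local_maxima(v, window=5, distances=d)
        assert len(out) == 1
        assert out[0][0] == pytest.approx(200.0, abs=2.0)

    def test_monotone_decreasing_empty(self):
        assert trk.find_local_maxima(np.linspace(5, 0, 50)).size == 0

    def test_two_equal_bumps_both_returned(self):
        d = np.arange(0.0, 100.0)
        v = np.exp(-((d - 25) / 5.0) ** 2) + np.exp(-((d - 75) / 5.0) ** 2)
        idx = trk.find_local_maxima(v, window=5)
        assert list(idx) == [25, 75]

    def test_boundaries_never_maxima(self):
        idx = trk.find_local_maxima(np.linspace(0, 5, 30), window=3)
        assert idx.size == 0  # global max sits on the boundary

    def test_window_validation(self):
        with pytest.raises(ConfigError):
            trk.find_local_maxima(np.zeros(5), window=0)


def bump(d, center, width, height):
    return height * np.exp(-((d - center) / width) ** 2)


class TestTrackPeak:
    def test_constant_stack_empty_track(self):
        ps = make_profiles(np.full((50, 4), 10.0))
        bl = trk.BaselineModel(10.0, 1.0)
        with pytest.warns(UserWarning, match="no frame"):
            track = trk.track_peak(ps, bl, span=0.3)
        assert np.all(np.isnan(track.peak_distance))

    def test_monotonicity_constraint_dominates_intensity(self):
        # frame 0: single bump at 60; frame 1: bright bump at 30 (behind) and
        # dimmer bump at 80 (ahead) -> the outer, dimmer one is selected
        d = np.arange(0.0, 120.0)
        f0 = bump(d, 60, 8, 50)
        f1 = bump(d, 30, 8, 80) + bump(d, 80, 8, 40)
        ps = make_profiles(np.stack([f0, f1], axis=1))
        bl = trk.BaselineModel(0.0, 1.0)
        track = trk.track_peak(ps, bl, span=0.15)
        assert track.peak_distance[0] == pytest.approx(60, abs=2)
        assert track.peak_distance[1] == pytest.approx(80, abs=2)

    def test_snr_is_peak_over_noise_upper(self):
        d = np.arange(0.0, 120.0)
        ps = make_profiles(bump(d, 50, 10, 100)[:, None])
        bl = trk.BaselineModel(0.0, 10.0)
        track = trk.track_peak(ps, bl, span=0.15)
        assert track.snr[0] == pytest.approx(track.peak_intensity[0]
                                             / bl.noise_upper)

    def test_tracks_synthetic_peak_law(self, small_local_wave):
        params, stack, truth, profiles = small_local_wave
        bl = trk.estimate_baseline(profiles, pre_frames=list(range(5)),
                                   sd_floor=0.01 * params.amplitude)
        track = trk.track_wave(profiles, bl, span=0.06)
        track = trk.set_time_zero(track, "stimulus_frame", stimulus_frame=5)
        sel = track.t > 0
        err = np.abs(track.peak_distance[sel] - truth.peak(track.t[sel]))
        assert np.nanmax(err) < 2 * params.pixel_size


class TestTrackFront:
    def test_step_profile_crossing(self):
        d = np.arange(0.0, 400.0)
        v = np.where(d <= 300.0, 100.0, 0.0)
        ps = make_profiles(v[:, None])
        bl = trk.BaselineModel(0.0, 10.0)  # threshold 10 = 10% of step
        front = trk.track_front(ps, bl, span=0)
        assert front[0] == pytest.approx(300.0, abs=1.0)

    def test_all_below_threshold_missing(self):
        ps = make_profiles(np.full((50, 2), 1.0))
        bl = trk.BaselineModel(5.0, 1.0)
        front = trk.track_front(ps, bl, span=0)
        assert np.all(np.isnan(front))

    def test_outermost_crossing_wins(self):
        # interior dip below threshold must not truncate the front
        d = np.arange(0.0, 200.0)
        v = bump(d, 50, 15, 100) + bump(d, 120, 15, 100)
        ps = make_profiles(v[:, None])
        bl = trk.BaselineModel(0.0, 20.0)
        front = trk.track_front(ps, bl, span=0)
        assert front[0] > 120.0

    def test_min_run_filters_isolated_bumps(self):
        d = np.arange(0.0, 200.0)
        v = np.where(d <= 100, 50.0, 0.0)
        v[180] = 50.0  # isolated spurious point far out
        ps = make_profiles(v[:, None])
        bl = trk.BaselineModel(0.0, 5.0)
        assert trk.track_front(ps, bl, span=0)[0] > 150
        assert trk.track_front(ps, bl, span=0, min_run=3)[0] == \
            pytest.approx(100.0, abs=1.0)

    def test_front_matches_ground_truth(self, small_local_wave):
        params, stack, truth, profiles = small_local_wave
        bl = trk.estimate_baseline(profiles, pre_frames=list(range(5)),
                                   sd_floor=0.01 * params.amplitude)
        track = trk.track_wave(profiles, bl, span=0.06)
        track = trk.set_time_zero(track, "stimulus_frame", stimulus_frame=5)
        sel = track.t > 0
        err = np.abs(track.front_distance[sel] - truth.front(track.t[sel]))
        assert np.nanmax(err) < 2 * params.pixel_size


@pytest.fixture(scope="module")
def tracked(small_local_wave):
    params, stack, truth, profiles = small_local_wave
    bl = trk.estimate_baseline(profiles, pre_frames=list(range(5)),
                               sd_floor=0.01 * params.amplitude)
    return params, trk.track_wave(profiles, bl, span=0.06), profiles, bl


class TestTrackInvariants:

    def test_peak_distance_nondecreasing(self, tracked):
        _, track, _, _ = tracked
        d = track.peak_distance[np.isfinite(track.peak_distance)]
        assert np.all(np.diff(d) >= -1e-9)

    def test_front_at_or_beyond_peak(self, tracked):
        _, track, _, _ = tracked
        both = np.isfinite(track.peak_distance) & np.isfinite(track.front_distance)
        assert np.all(track.front_distance[both] >= track.peak_distance[both] - 1e-9)

    def test_einstein_smoluchowski_scaling(self, tracked):
        params, track, _, _ = tracked
        track = trk.set_time_zero(track, "stimulus_frame", stimulus_frame=5)
        ok = (track.t > 0) & np.isfinite(track.front_distance)
        slope = np.polyfit(np.log(track.t[ok]),
                           np.log(track.front_distance[ok]), 1)[0]
        assert 0.45 <= slope <= 0.55

    def test_intensity_shift_invariance(self, tracked):
        params, track, profiles, _ = tracked
        shifted = ProfileSet(distances=profiles.distances,
                             times=profiles.times,
                             intensity=profiles.intensity + 500.0,
                             pixel_size=profiles.pixel_size)
        bl2 = trk.estimate_baseline(shifted, pre_frames=list(range(5)),
                                    sd_floor=0.01 * params.amplitude)
        track2 = trk.track_wave(shifted, bl2, span=0.06)
        np.testing.assert_allclose(track2.peak_distance, track.peak_distance,
                                   equal_nan=True, atol=1e-6)
        np.testing.assert_allclose(track2.front_distance, track.front_distance,
                                   equal_nan=True, atol=1e-6)


class TestSetTimeZero:
    def make_track(self, peaks):
        peaks = np.asarray(peaks, dtype=float)
        n = peaks.size
        return trk.WaveTrack(np.arange(n) * 2.0, peaks, np.ones(n),
                             np.ones(n), peaks + 5)

    def test_stimulus_frame_zero_is_identity(self):
        track = self.make_track([0, 1, 2, 3])
        out = trk.set_time_zero(track, "stimulus_frame", stimulus_frame=0)
        np.testing.assert_array_equal(out.t, track.t)

    def test_first_progression(self):
        track = self.make_track([10, 10, 10, 10, 10, 12, 14])
        out = trk.set_time_zero(track, "first_progression")
        assert out.t[0] == 0.0
        assert len(out) == 2  # frames 5 and 6 remain
        assert out.peak_distance[0] == 12

    def test_never_advances_rejected(self):
        with pytest.raises(DataError):
            trk.set_time_zero(self.make_track([5, 5, 5]), "first_progression")

    def test_stimulus_frame_out_of_range(self):
        with pytest.raises(ConfigError):
            trk.set_time_zero(self.make_track([1, 2]), "stimulus_frame",
                              stimulus_frame=10)

    def test_entries_before_zero_dropped(self):
        track = self.make_track([0, 1, 2, 3, 4])
        out = trk.set_time_zero(track, "stimulus_frame", stimulus_frame=2)
        assert len(out) == 3 and out.t[0] == 0.0


class TestWaveTrackIO:
    def test_csv_round_trip(self, tmp_path):
        track = trk.WaveTrack(np.array([0.0, 2.0]), np.array([1.0, np.nan]),
                              np.array([5.0, np.nan]), np.array([2.0, np.nan]),
                              np.array([3.0, 4.0]))
        track.to_csv(tmp_path / "t.csv")
        back = trk.WaveTrack.from_csv(tmp_path / "t.csv")
        np.testing.assert_allclose(back.peak_distance, track.peak_distance,
                                   equal_nan=True)
        np.testing.assert_allclose(back.front_distance, track.front_distance)
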