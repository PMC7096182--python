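import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ripplemap.core import ImageStack, TimeSeries, grid_atlas
from ripplemap.perievent import (
    asymmetry_index,
    extract_windows,
    fwhm_amplitude,
    peak_time_map,
    peri_peak_ripple_power,
    quartile_partition,
    shuffle_event_times,
    sign_match_proportion,
    zscore_by_shuffled_null,
)


def lag_axis(rate=100.0, half_win=1.0):
    half = int(round(half_win * rate))
    return (np.arange(2 * half + 1) - half) / rate


class TestExtractWindows:
    def test_single_event_center_sample(self):
        x = np.arange(1000, dtype=float)
        ts = TimeSeries(x, rate=100.0)
        ens = extract_windows(ts, [5.0], half_win=1.0)
        assert ens.n_events == 1
        assert ens.windows[0][100] == 500.0  # value at the center sample
        assert ens.lags[100] == 0.0

    def test_boundary_event_excluded(self):
        ts = TimeSeries(np.zeros(1000), rate=100.0)
        ens = extract_windows(ts, [0.5, 5.0], half_win=1.0)
        assert list(ens.event_ids) == [1]

    def test_nearest_frame_alignment(self):
        stack = ImageStack(np.arange(2000)[:, None, None] * np.ones((1, 2, 2)),
                           rate=100.0)
        ens = extract_windows(stack, [10.004], half_win=0.1)
        # 10.004 s at 100 Hz snaps to frame 1000 (10.00 s)
        assert ens.windows[0, ens.lags == 0.0, 0, 0] == 1000.0

    def test_no_valid_windows_rejected(self):
        ts = TimeSeries(np.zeros(100), rate=100.0)
        with pytest.raises(ValueError):
            extract_windows(ts, [0.1], half_win=1.0)


class TestZscoreByShuffledNull:
    def test_white_noise_calibration(self, rng):
        stack = ImageStack(rng.standard_normal((2000, 8, 8)), rate=100.0)
        centers = np.sort(rng.uniform(2.0, 18.0, 40))
        z = zscore_by_shuffled_null(stack, centers, n_perm=40, seed=2)
        mean_map = z.mean()
        # entries of the event-mean map concentrate near 0 with SD ~ 1/sqrt(n)
        assert abs(mean_map.mean()) < 0.1
        assert mean_map.std() == pytest.approx(1 / np.sqrt(40), rel=0.25)
        # individual z-scored samples are standard normal: ~5% beyond 1.96
        tail = np.mean(np.abs(z.windows) > 1.96)
        assert tail == pytest.approx(0.05, abs=0.02)

    def test_event_locked_transient_scales_to_null_sd(self, rng):
        noise_sd = 0.5
        frames = rng.standard_normal((4000, 4, 4)) * noise_sd
        centers = np.sort(rng.uniform(2.0, 38.0, 30))
        for c in centers:
            frames[int(round(c * 100))] += 5 * noise_sd
        stack = ImageStack(frames, rate=100.0)
        z = zscore_by_shuffled_null(stack, centers, n_perm=40, seed=3)
        peak = z.mean()[z.lags == 0.0].mean()
        assert peak == pytest.approx(5.0, abs=1.0)

    def test_shuffle_preserves_count_and_span(self, rng):
        centers = np.sort(rng.uniform(0, 100, 25))
        surrogate = shuffle_event_times(centers, rng)
        assert surrogate.size == centers.size
        assert surrogate[0] == centers[0]
        assert surrogate[-1] == pytest.approx(centers[-1])

    def test_too_few_events_rejected(self):
        stack = ImageStack(np.zeros((100, 2, 2)), rate=100.0)
        with pytest.raises(ValueError):
            zscore_by_shuffled_null(stack, [0.5], n_perm=5)


class TestFwhmAmplitude:
    def test_triangle_amplitude(self):
        lags = lag_axis()
        tri = np.clip(1.0 - np.abs(lags) / 0.5, 0.0, None)
        res = fwhm_amplitude(tri, lags)
        # mean of a unit triangle across its FWHM is 3/4
        assert res.valid
        assert res.amplitude == pytest.approx(0.75, abs=0.01)
        assert res.peak_time == 0.0
        assert res.t1 == pytest.approx(-0.25, abs=0.01)
        assert res.t2 == pytest.approx(0.25, abs=0.01)

    def test_rectangular_pulse_amplitude_equals_height(self):
        lags = lag_axis()
        pulse = np.where(np.abs(lags) <= 0.2, 4.0, 0.0)
        res = fwhm_amplitude(pulse, lags)
        assert res.amplitude == pytest.approx(4.0, rel=0.02)

    def test_flat_trace_invalid(self):
        lags = lag_axis()
        assert not fwhm_amplitude(np.zeros_like(lags), lags).valid

    def test_deactivation_mode_rectifies(self):
        lags = lag_axis()
        dip = -np.clip(1.0 - np.abs(lags) / 0.5, 0.0, None)
        res = fwhm_amplitude(dip, lags, mode="deactivation")
        assert res.valid
        assert res.amplitude == pytest.approx(0.75, abs=0.01)

    def test_no_crossing_in_window_invalid(self):
        lags = lag_axis()
        assert not fwhm_amplitude(np.ones_like(lags), lags).valid


class TestAsymmetryIndex:
    def test_all_mass_after_center(self):
        lags = lag_axis()
        trace = np.where((lags > 0) & (lags <= 0.2), 1.0, 0.0)
        assert asymmetry_index(trace, lags).ai == pytest.approx(1.0)

    def test_all_mass_before_center(self):
        lags = lag_axis()
        trace = np.where((lags >= -0.2) & (lags < 0), 1.0, 0.0)
        assert asymmetry_index(trace, lags).ai == pytest.approx(-1.0)

    def test_three_to_one_ratio(self):
        lags = lag_axis()
        trace = np.where(lags < 0, 1.0, 3.0)
        assert asymmetry_index(trace, lags).ai == pytest.approx(0.5)

    def test_zero_trace_invalid(self):
        lags = lag_axis()
        res = asymmetry_index(np.zeros_like(lags), lags)
        assert not res.valid

    def test_short_window_rejected(self):
        lags = lag_axis(half_win=0.1)
        with pytest.raises(ValueError):
            asymmetry_index(np.ones_like(lags), lags)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_and_antisymmetric(self, seed):
        rng = np.random.default_rng(seed)
        lags = lag_axis()
        trace = rng.uniform(0.0, 1.0, lags.size)
        res = asymmetry_index(trace, lags)
        if res.valid:
            assert -1.0 <= res.ai <= 1.0
            rev = asymmetry_index(trace[::-1], lags)
            assert rev.ai == pytest.approx(-res.ai, abs=1e-9)


class TestQuartilePartition:
    def test_quarter_in_each_tail(self, rng):
        vals = rng.permutation(100).astype(float)
        labels = quartile_partition(vals)
        assert labels.count("QR1") == 25
        assert labels.count("QR4") == 25

    def test_all_equal_values_empty_tails(self):
        labels = quartile_partition(np.ones(10))
        assert "QR1" not in labels and "QR4" not in labels

    def test_interpolated_quartiles_on_1_to_8(self):
        # brute-force oracle: linear-interpolation Q1 of 1..8 is 2.75,
        # Q3 is 6.25, so QR1={1,2} and QR4={7,8}
        labels = quartile_partition(np.arange(1.0, 9.0))
        assert [l == "QR1" for l in labels] == [True, True] + [False] * 6
        assert [l == "QR4" for l in labels] == [False] * 6 + [True, True]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            quartile_partition(np.array([0.1, 0.2, np.nan, np.nan]))

    def test_tail_sizes_bounded(self, rng):
        # with linear-interpolation quantiles at most ceil(n/4) values can
        # fall strictly outside [Q1, Q3] on each side; exactly n/4 when n
        # is divisible by 4 and values are distinct
        for n in (17, 23, 40):
            labels = quartile_partition(rng.standard_normal(n))
            assert labels.count("QR1") <= np.ceil(n / 4)
            assert labels.count("QR4") <= np.ceil(n / 4)
        labels = quartile_partition(rng.standard_normal(40))
        assert labels.count("QR1") == 10
        assert labels.count("QR4") == 10


class TestSignMatch:
    def test_identical_vectors(self, rng):
        x = rng.standard_normal(50)
        assert sign_match_proportion(x, x) == 1.0

    def test_negated_vectors(self, rng):
        x = rng.standard_normal(50) + 2.0
        assert sign_match_proportion(x, -x) == 0.0

    def test_independent_signs_near_half(self, rng):
        a = rng.choice([-1.0, 1.0], 10000)
        b = rng.choice([-1.0, 1.0], 10000)
        assert sign_match_proportion(a, b) == pytest.approx(0.5, abs=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sign_match_proportion([1.0], [1.0, 2.0])


class TestPeriPeakRipplePower:
    def test_bumps_at_peaks_average_to_bump(self, rng):
        x = 0.01 * np.abs(rng.standard_normal(20000))
        peaks = np.arange(2.0, 18.0, 1.0)
        for t in peaks:
            i = int(t * 1000)
            x[i - 50:i + 50] += np.hanning(100)
        power = TimeSeries(x, rate=1000.0)
        lags, mean_trace, fw = peri_peak_ripple_power(power, peaks)
        assert fw.valid
        assert abs(fw.peak_time) < 0.01
        assert fw.amplitude == pytest.approx(np.hanning(100)[25:75].mean(),
                                             rel=0.2)

    def test_random_peaks_give_flat_average(self, rng):
        x = 1.0 + 0.0 * np.zeros(20000)
        power = TimeSeries(x + 0.001 * rng.standard_normal(20000), rate=1000.0)
        peaks = rng.uniform(2.0, 18.0, 10)
        _, mean_trace, _ = peri_peak_ripple_power(power, peaks)
        assert mean_trace.std() < 0.001

    def test_single_peak_returns_its_window(self):
        x = np.arange(2000, dtype=float)
        power = TimeSeries(x, rate=100.0)
        lags, mean_trace, _ = peri_peak_ripple_power(power, [10.0])
        assert np.array_equal(mean_trace, x[900:1101])


class TestPeakTimeMap:
    def _mean_stack(self, lag_list, atlas, rate=100.0):
        lags = lag_axis(rate)
        z = np.zeros((lags.size, *atlas.labels.shape))
        for region, lag in lag_list.items():
            profile = np.exp(-0.5 * ((lags - lag) / 0.05) ** 2)
            z[:, atlas.mask(region)] += profile[:, None]
        return z, lags

    def test_ordering_recovered(self, three_region_atlas):
        z, lags = self._mean_stack(
            {"RSC": 0.0, "PtA": 0.010, "V1": 0.020}, three_region_atlas
        )
        tp, order, missing = peak_time_map(z, lags, three_region_atlas)
        assert order == ["RSC", "PtA", "V1"]
        assert missing == []
        for r, lag in {"RSC": 0.0, "PtA": 0.010, "V1": 0.020}.items():
            assert abs(tp[r] - lag) <= 0.010

    def test_equal_lags_report_equal_times(self, three_region_atlas):
        z, lags = self._mean_stack(
            {"RSC": 0.01, "PtA": 0.01, "V1": 0.01}, three_region_atlas
        )
        tp, _, _ = peak_time_map(z, lags, three_region_atlas)
        assert len(set(tp.values())) == 1

    def test_flat_region_reported_missing(self, three_region_atlas):
        z, lags = self._mean_stack({"RSC": 0.0, "PtA": 0.01},
                                   three_region_atlas)
        tp, _, missing = peak_time_map(z, lags, three_region_atlas)
        assert "V1" in missing and "V1" not in tp

    def test_all_flat_rejected(self, three_region_atlas):
        lags = lag_axis()
        z = np.zeros((lags.size, *three_region_atlas.labels.shape))
        with pytest.raises(ValueError):
            peak_time_map(z, lags, three_region_atlas)
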