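"""Ratio images, well time series, single-cell fold changes, peaks."""

import numpy as np
import pytest

from optofret import (CorrectionSet, DualChannelStack, ResponseWindows,
                      StimulusEvent, WellSeries, compute_ratio_image,
                      population_timeseries, response_histograms,
                      second_peak_ratio, single_cell_fold_change)
from optofret.kinetics import (REASON_DIM, REASON_LOW_RATIO,
                               REASON_SATURATED, FilterParams)

from conftest import disk_mask


def _filters():
    return FilterParams(saturation=65535.0)


class TestRatioImage:
    def test_direct_quotient_inside_mask(self):
        mask = disk_mask((48, 48), (24, 24), 12)
        donor = np.full((48, 48), 5000.0)
        acceptor = 1.2 * donor
        rf = compute_ratio_image(donor, acceptor, mask, filters=_filters(),
                                 smooth_sigma=0.0)
        assert np.allclose(rf.ratio[mask], 1.2, rtol=1e-12)
        assert np.all(np.isnan(rf.ratio[~mask]))

    def test_low_ratio_pixels_invalidated_as_dead(self):
        mask = disk_mask((32, 32), (16, 16), 8)
        donor = np.full((32, 32), 5000.0)
        acceptor = 0.7 * donor  # below the 0.8 dead-cell cutoff
        rf = compute_ratio_image(donor, acceptor, mask, filters=_filters(),
                                 smooth_sigma=0.0)
        assert np.all(np.isnan(rf.ratio[mask]))
        assert np.all(rf.reasons[mask] == REASON_LOW_RATIO)

    def test_zero_donor_marked_dim_never_infinite(self):
        mask = np.ones((8, 8), bool)
        donor = np.full((8, 8), 5000.0)
        donor[3, 3] = 0.0
        acceptor = np.full((8, 8), 6000.0)
        rf = compute_ratio_image(donor, acceptor, mask, filters=_filters(),
                                 smooth_sigma=0.0)
        assert rf.reasons[3, 3] == REASON_DIM
        assert not np.any(np.isinf(rf.ratio[np.isfinite(rf.ratio)]))

    def test_saturated_pixel_invalid_neighbors_locally_unaffected(self):
        mask = np.ones((64, 64), bool)
        donor = np.full((64, 64), 5000.0)
        acceptor = np.full((64, 64), 6000.0)
        raw_a = acceptor.copy()
        raw_a[30, 30] = 65535.0
        rf = compute_ratio_image(donor, acceptor, mask, filters=_filters(),
                                 smooth_sigma=1.0, raw_acceptor=raw_a)
        assert rf.reasons[30, 30] == REASON_SATURATED
        # beyond the sigma-1 smoothing support the ratio is untouched
        assert rf.ratio[30, 40] == pytest.approx(1.2, rel=1e-9)

    def test_ratio_correction_divides_result(self):
        mask = np.ones((16, 16), bool)
        cs = CorrectionSet.identity((16, 16))
        cs.ratio_correction = np.full((16, 16), 1.25)
        rf = compute_ratio_image(np.full((16, 16), 5000.0),
                                 np.full((16, 16), 6000.0), mask,
                                 corrections=cs, filters=_filters(),
                                 smooth_sigma=0.0)
        assert np.allclose(rf.ratio, 1.2 / 1.25)


def _well_stack(ratio_per_frame, brightness=None, n_px=32,
                stim_time=None, dead_ratio_fraction=0.0):
    """Tiny synthetic well: uniform donor, acceptor = ratio * donor."""
    T = len(ratio_per_frame)
    donor = np.full((T, n_px, n_px), 5000.0)
    if brightness is not None:
        donor *= brightness
    acceptor = donor * np.asarray(ratio_per_frame)[:, None, None]
    if dead_ratio_fraction > 0:
        k = int(dead_ratio_fraction * n_px)
        acceptor[:, :k] = donor[:, :k] * 0.6  # dead-cell pixels
    stimuli = ([StimulusEvent(time=stim_time)] if stim_time else [])
    return DualChannelStack(donor=donor, acceptor=acceptor, pixel_size=0.65,
                            frame_interval=1.5, stimuli=stimuli,
                            meta={"saturation": 65535})


class TestPopulationSeries:
    def test_constant_well_normalizes_to_one(self):
        stack = _well_stack([1.3] * 8, stim_time=6.1)
        s = population_timeseries(stack)
        assert np.allclose(s.value, 1.0, atol=1e-12)

    def test_step_response_measured_at_programmed_size(self):
        ratios = [1.3] * 5 + [1.43] * 5  # +10% at the stimulus
        stack = _well_stack(ratios, stim_time=6.9)
        s = population_timeseries(stack)
        assert np.allclose(s.value[:5], 1.0, atol=1e-9)
        assert np.allclose(s.value[5:], 1.10, atol=1e-9)
        # time axis relative to the last pre-stimulus frame
        assert s.time[4] == 0.0

    def test_dead_cell_pixels_do_not_shift_series(self):
        clean = population_timeseries(_well_stack([1.3] * 6, stim_time=3.1))
        dirty = population_timeseries(
            _well_stack([1.3] * 6, stim_time=3.1, dead_ratio_fraction=0.3))
        assert np.nanmax(np.abs(clean.value - dirty.value)) < 0.005

    def test_ratio_of_means_not_mean_of_ratios(self):
        """Heterogeneous brightness: must match the ratio-of-means oracle."""
        rng = np.random.default_rng(0)
        T, n = 4, 24
        donor = rng.uniform(2000, 20000, (T, n, n))
        acceptor = donor * rng.uniform(1.0, 1.6, (T, n, n))
        stack = DualChannelStack(donor=donor, acceptor=acceptor,
                                 pixel_size=0.65, frame_interval=1.5,
                                 meta={"saturation": 65535})
        s = population_timeseries(stack)
        f = FilterParams()
        oracle = []
        for t in range(T):
            ok = ((donor[t] > f.dim_level) & (acceptor[t] > f.dim_level)
                  & (donor[t] < f.saturate_level)
                  & (acceptor[t] < f.saturate_level)
                  & (acceptor[t] / donor[t] >= 0.8))
            oracle.append(acceptor[t][ok].mean() / donor[t][ok].mean())
        oracle = np.asarray(oracle)
        assert np.allclose(s.value, oracle / oracle.mean(), rtol=1e-12)

    def test_prestim_window_averages_to_exactly_one(self, rng):
        ratios = 1.3 + 0.02 * rng.standard_normal(12)
        stack = _well_stack(ratios.tolist(), stim_time=8.3)
        s = population_timeseries(stack)
        assert np.nanmean(s.value[:s.n_prestim]) == pytest.approx(1.0,
                                                                  abs=1e-12)

    def test_no_valid_pixels_gives_nan_not_zero(self):
        ratios = [1.3] * 4
        stack = _well_stack(ratios, stim_time=3.1)
        stack.acceptor[2] = 0.0  # everything dim in frame 2
        s = population_timeseries(stack)
        assert np.isnan(s.value[2])


class TestSingleCellFoldChange:
    def _times(self, n=30, stim_frame=12):
        return (np.arange(n) - stim_frame) * 1.5

    def test_flat_series_gives_unit_fold_changes(self):
        t = self._times()
        p_c2, c1_c2 = single_cell_fold_change(np.full(30, 1.2), t)
        assert p_c2 == pytest.approx(1.0)
        assert c1_c2 == pytest.approx(1.0)

    def test_programmed_responder_recovered(self):
        t = self._times()
        series = np.full(30, 1.0)
        series[(t >= 4.5) & (t <= 10.5)] = 1.08
        p_c2, c1_c2 = single_cell_fold_change(series, t)
        assert p_c2 == pytest.approx(1.08)
        assert c1_c2 == pytest.approx(1.0)

    def test_low_baseline_excluded_as_dead(self):
        t = self._times()
        out = single_cell_fold_change(np.full(30, 0.90), t)
        assert out == (None, "low-baseline")

    def test_saturated_cell_excluded(self):
        t = self._times()
        out = single_cell_fold_change(np.full(30, 1.2), t,
                                      has_saturated_pixels=True)
        assert out == (None, "saturated")

    def test_missing_window_frames_excluded_with_reason(self):
        t = self._times(n=14)  # ends before the peak window
        out = single_cell_fold_change(np.full(14, 1.2), t)
        assert out[0] is None
        assert out[1].startswith("missing-frames")

    def test_windows_hold_five_frames_at_assay_cadence(self):
        w = ResponseWindows()
        t = self._times()
        for lo, hi in (w.c1, w.c2, w.peak):
            assert np.sum((t >= lo) & (t <= hi)) == 5


class TestHistograms:
    def test_single_bin_degenerate_histogram(self):
        edges, mean, sem = response_histograms(
            {"e1": np.full(10, 1.07)}, bin_edges=np.linspace(0.9, 1.4, 6))
        assert mean.sum() == pytest.approx(1.0)
        assert mean[1] == pytest.approx(1.0)  # 1.07 in [1.0, 1.1)

    def test_identical_groups_have_zero_sem(self, rng):
        vals = rng.uniform(1.0, 1.2, 50)
        _, mean, sem = response_histograms({"a": vals, "b": vals.copy()})
        assert np.all(sem == 0.0)

    def test_bimodal_mixture_modes_recovered(self, rng):
        lo = rng.normal(1.0, 0.005, 300)
        hi = rng.normal(1.10, 0.005, 300)
        edges, mean, _ = response_histograms(
            {"a": np.concatenate([lo, hi]),
             "b": np.concatenate([lo, hi]) + rng.normal(0, 0.002, 600)})
        centers = (edges[:-1] + edges[1:]) / 2
        # two local modes, near 1.0 and near the programmed amplitude
        top2 = centers[np.argsort(mean)[-2:]]
        assert min(abs(top2 - 1.0)) < 0.0126
        assert min(abs(top2 - 1.10)) < 0.0126

    def test_empty_group_dropped_with_warning(self, rng):
        with pytest.warns(UserWarning, match="no cells"):
            _, mean, _ = response_histograms(
                {"a": rng.uniform(1, 1.2, 20), "b": np.array([])})
        assert np.isfinite(mean).all()


def _series(times, values):
    return WellSeries(time=np.asarray(times, float),
                      value=np.asarray(values, float))


class TestSecondPeak:
    def _double_pulse(self, amp2, delay=30.0, tau=4.0):
        t = np.arange(0, 90, 1.5)
        y = 1.0 + 0.1 * np.exp(-np.clip(t - 1.5, 0, None) / tau) \
            * (t >= 1.5)
        y += amp2 * np.exp(-np.clip(t - delay - 1.5, 0, None) / tau) \
            * (t >= delay + 1.5)
        return _series(t, y), (0.0, delay)

    def test_identical_responses_give_unity(self):
        s, stims = self._double_pulse(0.1)
        assert second_peak_ratio(s, stims) == pytest.approx(1.0, abs=0.05)

    def test_half_amplitude_second_response(self):
        s, stims = self._double_pulse(0.05)
        assert second_peak_ratio(s, stims) == pytest.approx(0.5, abs=0.06)

    def test_short_delay_unresolvable(self):
        # overlapping slow responses: no real dip between the pulses
        s, stims = self._double_pulse(0.1, delay=7.0, tau=60.0)
        assert second_peak_ratio(s, stims) is None

    def test_non_responding_well_raises(self):
        t = np.arange(0, 60, 1.5)
        s = _series(t, np.ones_like(t))
        with pytest.raises(ValueError, match="non-responding"):
            second_peak_ratio(s, (0.0, 30.0))
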