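import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import transloquant as tq
from transloquant.quant import (
    RatioTimeSeries,
    RoiSet,
    background_level,
    change_in_ratio,
    footprint_from_min_projection,
    localization_ratio,
    replicate_summary,
    response_auc,
    tirf_normalize,
)


def make_series(values, stim_index=2, interval=60.0):
    values = np.asarray(values, dtype=float)
    return RatioTimeSeries(
        cell_id=1,
        times=np.arange(values.size) * interval,
        values=values,
        stim_index=stim_index,
        replicate_id=1,
    )


class TestBackgroundLevel:
    def test_uniform_frame(self):
        roi = np.zeros((8, 8), dtype=bool)
        roi[:2, :2] = True
        assert background_level(np.full((8, 8), 7.0), roi) == 7.0

    def test_mean_of_mixed_region(self):
        frame = np.zeros((4, 4))
        frame[0, :2] = 10.0
        roi = np.zeros((4, 4), dtype=bool)
        roi[0, :4] = True
        assert background_level(frame, roi) == 5.0

    def test_empty_or_mismatched_roi_rejected(self):
        with pytest.raises(ValueError):
            background_level(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValueError):
            background_level(np.ones((4, 4)), np.zeros((5, 5), dtype=bool))


class TestLocalizationRatio:
    def setup_method(self):
        self.frame = np.full((10, 10), 100.0)
        self.mask = np.zeros((10, 10), dtype=bool)
        self.mask[0, :] = True
        self.frame[self.mask] = 200.0
        self.denom = np.zeros((10, 10), dtype=bool)
        self.denom[5:, :] = True

    def test_arithmetic(self):
        r = localization_ratio(self.frame, self.mask, self.denom, bg=10.0)
        assert r == pytest.approx(190.0 / 90.0)

    def test_uniform_sensor_gives_unity(self):
        frame = np.full((10, 10), 80.0)
        assert localization_ratio(frame, self.mask, self.denom, bg=30.0) == pytest.approx(1.0)

    def test_empty_mask_and_low_signal_give_nan(self):
        empty = np.zeros((10, 10), dtype=bool)
        assert np.isnan(localization_ratio(self.frame, empty, self.denom, bg=10.0))
        assert np.isnan(localization_ratio(self.frame, self.mask, self.denom, bg=150.0))

    def test_mask_pixels_excluded_from_denominator(self):
        overlap = self.denom | self.mask
        r_excl = localization_ratio(self.frame, self.mask, overlap, bg=0.0)
        r_incl = localization_ratio(
            self.frame, self.mask, overlap, bg=0.0, exclude_mask_from_denominator=False
        )
        assert r_excl == pytest.approx(2.0)
        assert r_incl < r_excl

    @given(gain=st.floats(0.01, 1e3), offset=st.floats(0, 1e3))
    @settings(max_examples=40, deadline=None)
    def test_gain_and_offset_invariance(self, gain, offset):
        base = localization_ratio(self.frame, self.mask, self.denom, bg=10.0)
        scaled = localization_ratio(self.frame * gain, self.mask, self.denom, bg=10.0 * gain)
        shifted = localization_ratio(self.frame + offset, self.mask, self.denom, bg=10.0 + offset)
        assert scaled == pytest.approx(base, rel=1e-9)
        assert shifted == pytest.approx(base, rel=1e-9)


class TestRoiSet:
    def test_background_overlap_rejected(self):
        bgr = np.zeros((6, 6), dtype=bool)
        bgr[0] = True
        cell = np.zeros((6, 6), dtype=bool)
        cell[0, 0] = True
        with pytest.raises(ValueError):
            RoiSet(background=bgr, cells={1: cell})

    def test_cytosol_outside_cell_rejected(self):
        bgr = np.zeros((6, 6), dtype=bool)
        bgr[0] = True
        cell = np.zeros((6, 6), dtype=bool)
        cell[3:5, 3:5] = True
        cyt = np.zeros((6, 6), dtype=bool)
        cyt[5, 5] = True
        with pytest.raises(ValueError):
            RoiSet(background=bgr, cells={1: cell}, cytosol={1: cyt})


class TestRatioTimeseries:
    def test_flat_kinetics_give_flat_series(self):
        scene = tq.simulate_cell_scene(
            tq.SceneParams(seed=11, n_frames=10), tq.TranslocationKinetics(0.15, 0.15)
        )
        from transloquant.io import scene_roi_set

        series = tq.ratio_timeseries(
            scene.stack, "marker", "sensor", scene_roi_set(scene),
            tq.DEFAULT_PROFILES["plasma_membrane"],
        )[1]
        pre = series.values[: scene.params.stim_frame]
        post = series.values[scene.params.stim_frame:]
        assert abs(post.mean() - pre.mean()) < 0.05 * pre.mean()

    def test_rising_kinetics_rise_only_after_stimulation(self, pm_scene, pm_rois):
        series = tq.ratio_timeseries(
            pm_scene.stack, "marker", "sensor", pm_rois,
            tq.DEFAULT_PROFILES["plasma_membrane"],
        )[1]
        stim = pm_scene.params.stim_frame
        pre = series.values[:stim]
        assert np.ptp(pre) < 0.1 * pre.mean()
        assert series.values[-1] > pre.mean() * 1.5

    def test_auc_ordering_follows_plateau_fraction(self):
        from transloquant.io import scene_roi_set

        aucs = {}
        for fmax in (0.2, 0.8):
            scene = tq.simulate_cell_scene(
                tq.SceneParams(seed=12, n_frames=12), tq.TranslocationKinetics(0.1, fmax)
            )
            series = tq.ratio_timeseries(
                scene.stack, "marker", "sensor", scene_roi_set(scene),
                tq.DEFAULT_PROFILES["plasma_membrane"],
            )[1]
            aucs[fmax] = response_auc(series).auc
        assert aucs[0.8] > aucs[0.2] > 0


class TestTirfNormalize:
    def test_constant_trace_normalizes_to_one(self):
        s = tirf_normalize(np.full(10, 50.0), pre_frames=3, bg=10.0)
        assert np.allclose(s.values, 1.0)

    def test_halving_trace(self):
        trace = np.array([110.0] * 4 + [60.0] * 4)
        s = tirf_normalize(trace, pre_frames=4, bg=10.0)
        assert np.allclose(s.values[4:], 0.5)

    def test_unusable_cell_flagged(self):
        with pytest.raises(ValueError):
            tirf_normalize(np.full(6, 5.0), pre_frames=3, bg=10.0)

    def test_closed_loop_against_generator_truth(self):
        stack, truth = tq.simulate_tirf_scene(
            tq.SceneParams(seed=5, n_frames=16), tq.TranslocationKinetics(0.2, 0.6)
        )
        sub = stack.data[:, 0]
        fp, _ = footprint_from_min_projection(sub)
        from scipy import ndimage

        bgr = ~ndimage.binary_dilation(fp, iterations=8)
        trace = np.array([f[fp].mean() for f in sub])
        bgs = np.array([background_level(f, bgr) for f in sub])
        series = tirf_normalize(trace, stack.stim_frame, bgs, times=stack.times_s)
        rel = (series.values - truth["normalized_trace"]) / truth["normalized_trace"]
        assert np.sqrt(np.mean(rel**2)) < 0.05


class TestFootprint:
    def test_static_disk_recovered(self):
        yy, xx = np.ogrid[:64, :64]
        disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
        stack = np.where(disk, 100.0, 5.0)[None].repeat(4, axis=0)
        fp, proj = footprint_from_min_projection(stack)
        iou = (fp & disk).sum() / (fp | disk).sum()
        assert iou >= 0.9

    def test_jittering_disk_yields_intersection(self):
        yy, xx = np.ogrid[:64, :64]
        frames = []
        for dx in (-3, 0, 3):
            frames.append(np.where((yy - 32) ** 2 + (xx - 32 - dx) ** 2 <= 20**2, 100.0, 5.0))
        fp, _ = footprint_from_min_projection(np.stack(frames))
        single = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
        assert fp.sum() < single.sum()
        assert not (fp & ~np.pad(single, 0)).sum() > single.sum()

    def test_constant_stack_rejected(self):
        with pytest.raises(ValueError):
            footprint_from_min_projection(np.ones((3, 16, 16)))


class TestResponseStatistics:
    def test_constant_series_has_zero_auc_and_delta(self):
        s = make_series([1.5] * 10)
        summ = response_auc(s, delta_times=(120.0,))
        assert summ.auc == 0.0
        assert summ.delta_at[120.0] == 0.0

    def test_step_response_area_is_rectangle(self):
        # step of +1 from the stimulation frame, lasting 10 minutes
        s = make_series([1.0, 1.0] + [2.0] * 11, stim_index=2, interval=60.0)
        assert response_auc(s).auc == pytest.approx(10.0)

    def test_trapezoid_matches_refined_riemann_oracle(self):
        interval, stim = 30.0, 4
        times = np.arange(40) * interval

        def f(t):
            return 1.0 + np.where(t >= times[stim], 1 - np.exp(-(t - times[stim]) / 120.0), 0.0)

        s = make_series(f(times), stim_index=stim, interval=interval)
        auc = response_auc(s).auc
        # independent oracle: midpoint Riemann sum of the smooth trace at 100x
        # finer sampling, over the same [stim, end] window, in minutes
        fine = np.linspace(times[stim], times[-1], 100 * (40 - stim) + 1)
        mid = 0.5 * (fine[1:] + fine[:-1])
        oracle = np.sum((f(mid) - 1.0) * np.diff(fine)) / 60.0
        assert auc == pytest.approx(oracle, rel=0.01)

    def test_linear_ramp_delta(self):
        interval, stim, m = 30.0, 3, 0.01
        times = np.arange(20) * interval
        values = 1.0 + np.where(times >= times[stim], m * (times - times[stim]), 0.0)
        s = make_series(values, stim_index=stim, interval=interval)
        assert change_in_ratio(s, 150.0) == pytest.approx(m * 150.0)

    def test_step_delta(self):
        s = make_series([1.0, 1.0, 1.5, 1.5, 1.5], stim_index=2)
        assert change_in_ratio(s, 60.0) == pytest.approx(0.5)

    def test_pre_stimulation_queries_rejected(self):
        s = make_series([1.0] * 6)
        with pytest.raises(ValueError):
            change_in_ratio(s, -30.0)
        with pytest.raises(ValueError):
            response_auc(make_series([1.0] * 6, stim_index=0))


class TestReplicateSummary:
    def _summaries(self, groups):
        out = []
        i = 0
        for rid, values in groups.items():
            for v in values:
                out.append(tq.ResponseSummary(cell_id=i, replicate_id=rid, auc=v, baseline=1.0))
                i += 1
        return out

    def test_balanced_two_replicates(self):
        agg = replicate_summary(self._summaries({"a": [1, 1], "b": [3, 3]}))
        assert sorted(agg["replicate_table"]["auc_mean"]) == [1.0, 3.0]
        assert agg["grand_mean"] == 2.0
        assert agg["sem"] == pytest.approx(1.0)

    def test_single_replicate_sem_missing(self):
        agg = replicate_summary(self._summaries({"a": [1.0, 2.0]}))
        assert np.isnan(agg["sem"])

    def test_unbalanced_replicates_vote_equally(self):
        agg = replicate_summary(self._summaries({"a": [0, 0, 0, 0], "b": [2]}))
        assert agg["grand_mean"] == 1.0  # mean of replicate means, not of cells

    def test_relabeling_equivariance(self):
        a = replicate_summary(self._summaries({"r1": [1, 2], "r2": [5, 7]}))
        b = replicate_summary(self._summaries({"x9": [1, 2], "q0": [5, 7]}))
        assert a["grand_mean"] == b["grand_mean"]
        assert a["sem"] == b["sem"]

    def test_missing_replicate_id_rejected(self):
        df = pd.DataFrame({"cell_id": [1], "auc": [2.0], "replicate_id": [None]})
        with pytest.raises(ValueError):
            replicate_summary(df)
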