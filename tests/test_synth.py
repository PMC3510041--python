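"""Synthetic-data generator: determinism, realized truth, rendering consistency."""

import numpy as np
import pytest

from flyheart.beatmetrics import DIASTOLE, SYSTOLE
from flyheart.synth import (
    AgingModel,
    BeatTrainParams,
    GeometryParams,
    render_cardiogram,
    render_video,
    simulate_beat_train,
    simulate_cohort,
    simulate_gene_lists,
)


class TestBeatTrain:
    def test_degenerate_cv_gives_constant_intervals_and_zero_ai(self):
        truth = simulate_beat_train(
            BeatTrainParams(mean_period_ms=150, cv_period=0.0, n_beats=20), seed=0
        )
        assert np.allclose(truth.intervals_ms, 150.0)
        assert truth.ai_true == 0.0
        assert truth.hp_true_ms == 150.0

    @pytest.mark.parametrize("distribution", ["gamma", "lognormal"])
    def test_realized_cv_matches_nominal_at_large_n(self, distribution):
        truth = simulate_beat_train(
            BeatTrainParams(150, 0.2, 2000, distribution=distribution), seed=1
        )
        iv = truth.intervals_ms
        cv_real = iv.std(ddof=1) / iv.mean()
        assert abs(cv_real - 0.2) < 0.02
        assert abs(iv.mean() - 150) / 150 < 0.03

    def test_same_seed_reproduces_identical_events(self):
        p = BeatTrainParams(150, 0.3, 50)
        t1 = simulate_beat_train(p, seed=42)
        t2 = simulate_beat_train(p, seed=42)
        np.testing.assert_array_equal(t1.event_times_ms, t2.event_times_ms)
        np.testing.assert_array_equal(t1.event_types, t2.event_types)

    def test_events_alternate_and_truth_is_realized_statistic(self):
        truth = simulate_beat_train(BeatTrainParams(150, 0.25, 40), seed=3)
        types = truth.event_types
        assert all(a != b for a, b in zip(types, types[1:]))
        iv = truth.intervals_ms
        assert truth.hp_true_ms == pytest.approx(iv.mean())
        assert truth.ai_true == pytest.approx(iv.std(ddof=1) / np.median(iv))

    @pytest.mark.parametrize(
        "kwargs", [dict(n_beats=1), dict(distribution="weibull"), dict(mean_period_ms=0)]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BeatTrainParams(**{"mean_period_ms": 150, "cv_period": 0.1, "n_beats": 10, **kwargs})


class TestRenderCardiogram:
    def test_noiseless_regular_trace_peaks_at_edd(self, regular_truth, fast_geom):
        cg, truth = render_cardiogram(regular_truth, fast_geom, seed=0)
        assert cg.diameter_um.max() == pytest.approx(fast_geom.edd_um)
        assert cg.diameter_um.min() == pytest.approx(fast_geom.esd_um)

    def test_trace_extrema_times_match_truth_events(self, arrhythmic_truth, fast_geom):
        cg, truth = render_cardiogram(arrhythmic_truth, fast_geom, seed=0)
        d = cg.diameter_um
        dt_ms = 1000.0 / fast_geom.frame_rate_hz
        # every interior truth event is within one frame of a trace extremum
        interior = (truth.event_times_ms > dt_ms) & (
            truth.event_times_ms < truth.event_times_ms[-1] - dt_ms
        )
        for t_ms, kind in zip(truth.event_times_ms[interior], truth.event_types[interior]):
            frame = int(round(t_ms / dt_ms))
            lo, hi = max(0, frame - 1), min(d.size, frame + 2)
            window = d[lo:hi]
            if kind == DIASTOLE:
                assert window.max() >= d[max(0, lo - 2) : hi + 2].max() - 1e-9
            else:
                assert window.min() <= d[max(0, lo - 2) : hi + 2].min() + 1e-9

    def test_equal_diameters_render_constant_trace(self, regular_truth):
        geom = GeometryParams(edd_um=60.0, esd_um=60.0, frame_rate_hz=200.0)
        cg, _ = render_cardiogram(regular_truth, geom, seed=0)
        assert np.allclose(cg.diameter_um, 60.0)

    def test_low_frame_rate_rejected(self, regular_truth):
        # 150 ms period with systole 60 ms after diastole needs > ~16 fps
        geom = GeometryParams(frame_rate_hz=5.0)
        with pytest.raises(ValueError, match="frame rate"):
            render_cardiogram(regular_truth, geom, seed=0)


class TestRenderVideo:
    def test_static_heart_renders_identical_frames(self, regular_truth):
        geom = GeometryParams(edd_um=60.0, esd_um=60.0, frame_rate_hz=200.0)
        stack = render_video(regular_truth, geom, seed=0)
        assert np.all(stack.frames == stack.frames[0])

    def test_wall_centres_recoverable_by_argmax_scan(self, regular_truth, fast_geom):
        """Brute-force per-frame bilateral argmax recovers midline +- d/2 within 1 px."""
        stack = render_video(regular_truth, fast_geom, seed=1)
        d_px = regular_truth.diameter_trace_um / fast_geom.pixel_size_um
        mid = fast_geom.midline_row
        mid_i = int(round(mid))
        col = stack.frames[:, :, 0]
        upper = np.argmax(col[:, :mid_i], axis=1)
        lower = mid_i + np.argmax(col[:, mid_i:], axis=1)
        np.testing.assert_allclose(upper, mid - d_px / 2, atol=1.0)
        np.testing.assert_allclose(lower, mid + d_px / 2, atol=1.0)

    def test_paper_recording_duration(self):
        """1000 frames at 32 fps span 31.25 s."""
        truth = simulate_beat_train(BeatTrainParams(150, 0.0, 220), seed=0)
        geom = GeometryParams(frame_rate_hz=32.0)
        stack = render_video(truth, geom, seed=0)
        frames_1000 = stack.frames[:1000]
        assert frames_1000.shape[0] == 1000
        assert 1000 / stack.frame_rate_hz == pytest.approx(31.25)

    def test_out_of_bounds_geometry_rejected(self, regular_truth):
        geom = GeometryParams(midline_row=10.0, image_height_px=40, frame_rate_hz=200.0)
        with pytest.raises(ValueError, match="out of bounds"):
            render_video(regular_truth, geom, seed=0)

    def test_same_seed_renders_identical_noisy_stacks(self, regular_truth):
        geom = GeometryParams(frame_rate_hz=200.0, noise_sigma=20.0)
        import copy

        s1 = render_video(copy.deepcopy(regular_truth), geom, seed=5)
        s2 = render_video(copy.deepcopy(regular_truth), geom, seed=5)
        np.testing.assert_array_equal(s1.frames, s2.frames)

    def test_bleaching_decays_intensity(self, regular_truth):
        import dataclasses

        geom = GeometryParams(frame_rate_hz=200.0, bleach_tau_frames=100.0)
        stack = render_video(regular_truth, geom, seed=0)
        totals = stack.frames.sum(axis=(1, 2))
        assert totals[-1] < totals[0] * 0.5


class TestCohort:
    def test_zero_noise_group_means_lie_on_planted_lines(self):
        model = AgingModel(
            conditions=(("ctl", (("hp_ms", (100.0, 2.0)),)),),
            noise_sd=(("hp_ms", 0.0),),
        )
        df = simulate_cohort(model, n_per_group=5, ages=(10, 30, 45), seed=0)
        for age, grp in df.groupby("age_days"):
            assert grp["hp_ms"].mean() == pytest.approx(100.0 + 2.0 * age)

    def test_planted_slope_recovered_within_3_se(self):
        from flyheart.cohortstats import fit_age_trend

        model = AgingModel(
            conditions=(("ctl", (("hp_ms", (100.0, 5.0)),)),),
            noise_sd=(("hp_ms", 30.0),),
        )
        df = simulate_cohort(model, n_per_group=30, ages=(10, 30, 45, 60), seed=1)
        fit = fit_age_trend(df, "hp_ms", condition="ctl")
        assert abs(fit.slope - 5.0) < 3 * fit.slope_se

    def test_planted_slopes_recorded(self):
        df = simulate_cohort(seed=2)
        assert df.attrs["planted_slopes"]["control"]["hp_ms"] == 2.4


class TestGeneLists:
    def test_zero_planted_overlap_is_disjoint(self):
        q, r, _ = simulate_gene_lists(500, (50, 40), 0, seed=0)
        assert not (q.ids & r.ids)

    def test_planted_overlap_exact(self):
        q, r, u = simulate_gene_lists(13500, (635, 133), 29, seed=1)
        assert len(q.ids & r.ids) == 29
        assert len(q) == 635 and len(r) == 133 and len(u) == 13500
        assert q.ids <= u.ids and r.ids <= u.ids

    def test_overlap_equal_to_smaller_set_is_subset(self):
        q, r, _ = simulate_gene_lists(500, (100, 30), 30, seed=2)
        assert r.ids <= q.ids

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_lists(100, (80, 80), 10, seed=0)  # 150 distinct ids needed
        with pytest.raises(ValueError):
            simulate_gene_lists(100, (10, 20), 15, seed=0)
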