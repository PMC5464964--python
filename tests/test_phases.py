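"""Feature extraction and event detection: G1/S, S/G2, NEBD, quiescence."""

import numpy as np
import pytest

from pcnacycle.phases import (PhaseAnnotation, PhaseParams, TrackFeatureSeries,
                              align_tracks, assign_phases, classify_quiescence,
                              compute_feature_series, detect_g1s,
                              detect_mitosis_events, detect_sg2)
from pcnacycle.segment import LabelMap
from pcnacycle.simulate import NoiseModel, SimulationParams, render_frame, \
    simulate_movie
from pcnacycle.track import CellTrack
from conftest import truth_track_pairs

DT = 1 / 6  # hours per frame at 10-min interval


def make_series(mean, sd=None, dt=DT, chromatin_sd=None, w=3):
    mean = np.asarray(mean, dtype=float)
    n = len(mean)
    return TrackFeatureSeries(
        track_id=1, frames=np.arange(n), times_h=np.arange(n) * dt,
        nuclear_mean=mean,
        nuclear_sd=np.asarray(sd if sd is not None else np.zeros(n), float),
        area=np.full(n, 400.0),
        chromatin_sd=None if chromatin_sd is None else np.asarray(chromatin_sd, float),
        smooth_window=w)


def ramp_series(n=120, onset=60, base=100.0, slope_per_frame=1.7, noise=0.0,
                rng=None):
    y = np.full(n, base)
    y[onset:] += slope_per_frame * np.arange(n - onset)
    if noise:
        y = y + (rng or np.random.default_rng(0)).normal(0, noise, n)
    return y


class TestFeatureSeries:
    def test_nuclear_sd_matches_injected_noise(self):
        sigma = 5.0
        params = SimulationParams(image_size=(128, 128),
                                  noise=NoiseModel(gaussian_sd=sigma,
                                                   poisson_scale=0.0))
        from pcnacycle.simulate import build_cell_program
        rng = np.random.default_rng(8)
        prog = build_cell_program(params, rng, cell_id=1, center=(64, 64),
                                  pcna_base=100.0)
        raster, labels = render_frame([prog], 1.0, params, rng=rng)
        track = CellTrack(1)
        lm = LabelMap(0, labels.astype(np.int32))
        track.append(0, 1, lm.centroids[1], lm.areas[1])
        fs = compute_feature_series(track, raster[None, 0], [lm], dt_hours=DT)
        assert fs.nuclear_sd[0] == pytest.approx(sigma, rel=0.10)

    def test_constant_raster_gives_zero_sd(self):
        labels = np.zeros((32, 32), np.int32)
        labels[10:20, 10:20] = 1
        raster = np.full((1, 32, 32), 50.0)
        track = CellTrack(1)
        lm = LabelMap(0, labels)
        track.append(0, 1, lm.centroids[1], lm.areas[1])
        fs = compute_feature_series(track, raster, [lm], dt_hours=DT)
        assert fs.nuclear_sd[0] == pytest.approx(0.0, abs=1e-9)

    def test_s_phase_width_exceeds_g1(self, small_movie, small_analysis):
        _params, stack, truth = small_movie
        result, _, _ = small_analysis
        pairs = truth_track_pairs(result, truth)
        dt = stack.dt_hours
        checked = 0
        for cell, tid in pairs.items():
            ev = truth.events.set_index("cell").loc[cell]
            fs = result.features[tid]
            g1_frame = int(ev.g1s_frame) - 6  # 1 h before S entry
            late_s = int(ev.s_end_frame) - 2
            if g1_frame < 3:
                continue
            assert fs.nuclear_sd[late_s] > fs.nuclear_sd[g1_frame]
            checked += 1
        assert checked >= 3

    def test_missing_mask_frame_flagged_nan(self):
        labels = np.zeros((32, 32), np.int32)
        labels[8:18, 8:18] = 1
        lm0, lm2 = LabelMap(0, labels), LabelMap(2, labels)
        track = CellTrack(1)
        track.append(0, 1, lm0.centroids[1], lm0.areas[1])
        track.append(2, 1, lm2.centroids[1], lm2.areas[1])
        rasters = np.full((3, 32, 32), 60.0)
        fs = compute_feature_series(track, rasters, [lm0, lm2], dt_hours=DT)
        assert np.isnan(fs.nuclear_mean[1])
        assert np.isfinite(fs.nuclear_mean[[0, 2]]).all()


class TestMitosisDetection:
    def test_synthetic_nebd_detected_within_one_frame(self, small_movie,
                                                      small_analysis):
        _params, _stack, truth = small_movie
        result, _, _ = small_analysis
        pairs = truth_track_pairs(result, truth)
        for cell, tid in pairs.items():
            true_nebd = int(truth.events.set_index("cell").loc[cell, "nebd_frame"])
            ann = result.annotations[tid]
            assert ann.nebd_frame is not None
            assert abs(ann.nebd_frame - true_nebd) <= 1

    def test_monotone_series_has_no_events(self):
        fs = make_series(np.linspace(100, 200, 50))
        assert detect_mitosis_events(fs) == []

    def test_drop_without_chromatin_peak_rejected(self):
        mean = np.r_[np.full(20, 100.0), np.full(10, 50.0)]
        chrom = np.r_[np.full(14, 10.0), [40.0], np.full(15, 10.0)]  # peak at 14
        fs = make_series(mean, chromatin_sd=chrom)
        assert detect_mitosis_events(fs, require_chromatin_peak=True) == []
        chrom2 = np.full(30, 10.0)
        chrom2[20] = 40.0  # peak aligned with the drop
        fs2 = make_series(mean, chromatin_sd=chrom2)
        assert detect_mitosis_events(fs2, require_chromatin_peak=True) == [20]


class TestG1SDetection:
    def test_known_changepoint_recovered(self):
        rng = np.random.default_rng(1)
        for onset in (40, 60, 75):
            y = ramp_series(n=110, onset=onset, noise=0.5, rng=rng)
            fs = make_series(y)
            est, flag = detect_g1s(fs, birth_frame=0)
            assert flag is None
            assert abs(est - onset) <= 2

    def test_flat_track_has_no_onset(self):
        rng = np.random.default_rng(2)
        y = 100 + rng.normal(0, 0.5, 120)
        est, _flag = detect_g1s(make_series(y), birth_frame=0)
        assert est is None

    def test_scale_invariance(self):
        y = ramp_series(n=100, onset=55, noise=0.4)
        for c in (0.01, 3.0, 1e4):
            a, _ = detect_g1s(make_series(y), 0)
            b, _ = detect_g1s(make_series(c * y), 0)
            assert a == b

    def test_short_track_flagged(self):
        y = ramp_series(n=10, onset=5)
        est, flag = detect_g1s(make_series(y), birth_frame=0)
        assert est is None and flag is not None


class TestSG2Detection:
    def test_peak_at_end_of_s(self):
        sd = np.r_[np.full(30, 5.0), np.linspace(5, 40, 50), np.full(30, 6.0)]
        fs = make_series(np.full(110, 100.0), sd=sd)
        est, flag = detect_sg2(fs, g1s_frame=30, nebd_frame=100)
        assert flag is None
        assert abs(est - 79) <= 2

    def test_tie_breaks_to_latest_frame(self):
        sd = np.full(60, 5.0)
        sd[30:40] = 20.0  # plateau of equal maxima
        fs = make_series(np.full(60, 100.0), sd=sd, w=1)
        est, _ = detect_sg2(fs, g1s_frame=10, nebd_frame=55)
        assert est == 39

    def test_constant_width_flagged_undefined(self):
        fs = make_series(np.full(60, 100.0), sd=np.full(60, 7.0))
        est, flag = detect_sg2(fs, 10, 50)
        assert est is None and flag == "width_constant"

    def test_offset_invariance_of_width(self):
        """Adding a constant to every pixel leaves the S/G2 estimate unchanged."""
        rng = np.random.default_rng(3)
        labels = np.zeros((40, 40), np.int32)
        labels[5:25, 5:25] = 1
        lm = [LabelMap(k, labels) for k in range(5)]
        rasters = 50 + rng.normal(0, 5, (5, 40, 40))
        track = CellTrack(1)
        for k in range(5):
            track.append(k, 1, lm[k].centroids[1], lm[k].areas[1])
        a = compute_feature_series(track, rasters, lm, dt_hours=DT)
        b = compute_feature_series(track, rasters + 123.0, lm, dt_hours=DT)
        assert np.allclose(a.nuclear_sd, b.nuclear_sd, rtol=1e-6)

    def test_interval_too_short_flagged(self):
        fs = make_series(np.full(20, 1.0), sd=np.arange(20.0))
        est, flag = detect_sg2(fs, 5, 8)
        assert est is None and flag == "interval_too_short"


class TestQuiescence:
    def test_starvation_movie_all_flagged(self, starvation_movie,
                                          starvation_analysis):
        _params, stack, truth = starvation_movie
        result = starvation_analysis
        pairs = truth_track_pairs(result, truth)
        assert len(pairs) == 6
        dt = stack.dt_hours
        for cell, tid in pairs.items():
            ann = result.annotations[tid]
            assert ann.quiescent
            assert ann.g1s_frame is None
            true_onset = truth.events.set_index("cell").loc[cell, "decline_onset_h"]
            est_h = ann.decline_onset_frame * dt
            assert abs(est_h - true_onset) <= 2.0

    def test_proliferating_track_not_quiescent(self, small_analysis):
        result, _, _ = small_analysis
        for tid, ann in result.annotations.items():
            if ann.birth_frame == 0:
                assert not ann.quiescent

    def test_short_track_unknown(self):
        y = np.linspace(100, 50, 30)  # only 5 h long
        q, onset, flag = classify_quiescence(make_series(y), 0)
        assert q is None and flag == "track_shorter_than_Tq"


class TestAssignPhases:
    def test_full_cycle_durations_match_truth(self, small_movie, small_analysis):
        _params, stack, truth = small_movie
        result, _, _ = small_analysis
        pairs = truth_track_pairs(result, truth)
        ev = truth.events.set_index("cell")
        for cell, tid in pairs.items():
            ann = result.annotations[tid]
            assert ann.events_ordered()
            assert ann.phases is not None
            for event, col in (("g1s_frame", "g1s_frame"),
                               ("sg2_frame", "s_end_frame"),
                               ("nebd_frame", "nebd_frame"),
                               ("division_frame", "division_frame")):
                est = getattr(ann, event)
                assert est is not None
                assert abs(est - int(ev.loc[cell, col])) <= 2

    def test_phases_partition_track_span(self, small_analysis):
        result, _, _ = small_analysis
        for tid, ann in result.annotations.items():
            if ann.phases is None:
                continue
            tr = result.tracks[tid]
            assert len(ann.phases) == tr.end - tr.start + 1
            if ann.division_frame is not None and ann.g1s_frame is not None:
                labels = set(ann.phases)
                assert {"G1", "S", "G2", "M"} <= labels

    def test_ordering_violation_flags_inconsistent(self):
        ann = PhaseAnnotation(track_id=1, birth_frame=0, g1s_frame=50,
                              sg2_frame=30, nebd_frame=80)
        out = assign_phases(ann, (0, 100))
        assert out is None
        assert ann.flags["events"] == "inconsistent_ordering"

    def test_quiescent_track_is_g0_after_onset(self):
        ann = PhaseAnnotation(track_id=1, birth_frame=0, quiescent=True,
                              decline_onset_frame=10)
        labels = assign_phases(ann, (0, 30))
        assert all(p == "G0" for p in labels[10:])
        assert all(p == "unknown" for p in labels[:10])


class TestAlignTracks:
    def test_value_at_zero_equals_event_value(self):
        s = np.arange(50, dtype=float)
        mat, grid, idx = align_tracks([s], [20], window_h=1.0, dt_hours=DT)
        assert mat[0, len(grid) // 2] == s[20]
        assert grid[len(grid) // 2] == 0.0

    def test_column_mean_is_arithmetic_mean(self):
        rng = np.random.default_rng(4)
        series = [rng.normal(size=60) for _ in range(5)]
        mat, _grid, _ = align_tracks(series, [30] * 5, 2.0, DT)
        col = len(_grid) // 2 + 3
        expected = np.mean([s[33] for s in series])
        assert np.nanmean(mat[:, col]) == pytest.approx(expected)

    def test_no_extrapolation_beyond_span(self):
        s = np.arange(20, dtype=float)
        mat, grid, _ = align_tracks([s], [10], window_h=5.0, dt_hours=DT)
        k = len(grid) // 2
        assert np.isnan(mat[0, :k - 10]).all()
        assert np.isnan(mat[0, k + 10:]).all()

    def test_tracks_without_event_excluded(self):
        s = np.arange(20, dtype=float)
        mat, _grid, idx = align_tracks([s, s], [5, None], 1.0, DT)
        assert mat.shape[0] == 1 and idx == [0]
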