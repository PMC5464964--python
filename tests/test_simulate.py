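"""Generator contracts: determinism, event ordering, rendered intensities."""

import numpy as np
import pytest

from pcnacycle.simulate import (CellProgram, NoiseModel, SimulationError,
                                SimulationParams, build_cell_program,
                                render_frame, simulate_movie)

NOISELESS = NoiseModel(gaussian_sd=0.0, poisson_scale=0.0)


def _program(**kw):
    params = SimulationParams(seed=3)
    rng = np.random.default_rng(3)
    prog = build_cell_program(params, rng, cell_id=1, birth_time=0.0,
                              center=(60.0, 60.0), pcna_base=100.0)
    for k, v in kw.items():
        setattr(prog, k, v)
    return prog


class TestCellProgram:
    def test_event_ordering_and_durations(self):
        params = SimulationParams(seed=5)
        rng = np.random.default_rng(5)
        for i in range(20):
            p = build_cell_program(params, rng, cell_id=i + 1)
            assert p.birth_time < p.ramp_onset_time < p.nebd_time < p.division_time
            assert p.g1_duration + p.s_duration + p.g2_duration == pytest.approx(
                p.nebd_time - p.birth_time)
            assert min(p.g1_duration, p.s_duration, p.g2_duration) > 0
            assert p.g1_duration >= params.g1_floor

    def test_ramp_defaults_reach_twofold_plateau(self):
        p = _program()
        assert p.ramp_duration == pytest.approx(10.0)
        assert p.pcna_level(p.birth_time) == pytest.approx(p.pcna_base)
        # halfway through the ramp: halfway to the plateau
        mid = p.ramp_onset_time + 0.5 * p.ramp_duration
        assert p.pcna_level(mid) == pytest.approx(1.5 * p.pcna_base)
        # plateau holds through G2 at 2x the baseline
        assert p.pcna_level(p.nebd_time - 0.01) == pytest.approx(2.0 * p.pcna_base)

    def test_zero_ramp_duration_is_step(self):
        p = _program(ramp_duration=0.0)
        eps = 1e-6
        assert p.pcna_level(p.ramp_onset_time - eps) == pytest.approx(p.pcna_base)
        assert p.pcna_level(p.ramp_onset_time) == pytest.approx(2 * p.pcna_base)

    def test_foci_schedule_spans_s_phase_and_is_monotone(self):
        p = _program()
        times = [e[0] for e in p.foci_schedule]
        assert times[0] == pytest.approx(p.s_begin_time)
        assert times[-1] == pytest.approx(p.s_end_time)
        counts = [e[1] for e in p.foci_schedule]
        radii = [e[2] for e in p.foci_schedule]
        amps = [e[3] for e in p.foci_schedule]
        for seq in (counts, radii, amps):
            assert all(a <= b for a, b in zip(seq, seq[1:]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(SimulationError):
            SimulationParams(g1_mean=-1.0).validate()
        with pytest.raises(SimulationError):
            _program().__class__(cell_id=1, birth_time=0, g1_duration=-1,
                                 s_duration=10, g2_duration=4, m_duration=0.5,
                                 pcna_base=100)
        with pytest.raises(SimulationError):
            SimulationParams(pcna_plateau_fold=0.5).validate()


class TestRenderFrame:
    def test_zero_cells_background_only(self):
        params = SimulationParams(n_cells=0, image_size=(64, 64), noise=NOISELESS)
        raster, labels = render_frame([], 0.0, params)
        assert labels.max() == 0
        assert np.allclose(raster, params.background_level)

    def test_noise_free_g1_mean_equals_base(self):
        params = SimulationParams(image_size=(128, 128), noise=NOISELESS)
        prog = _program()
        raster, labels = render_frame([prog], 1.0, params)  # t=1 h: G1
        inside = raster[0][labels == 1]
        assert inside.size > 200
        expected = prog.pcna_base + params.background_level
        assert np.allclose(inside, expected)

    def test_foci_amplitude_increases_within_nucleus_sd(self):
        params = SimulationParams(image_size=(128, 128), noise=NOISELESS)
        t_mid_s = None
        sds = []
        for amp in (0.0, 30.0, 60.0, 120.0):
            prog = _program()
            t_mid_s = prog.s_begin_time + 0.5 * prog.s_duration
            prog.foci_schedule = [(prog.s_begin_time, 15, 1.5, amp)]
            raster, labels = render_frame([prog], t_mid_s, params)
            sds.append(raster[0][labels == 1].std())
        assert all(a < b for a, b in zip(sds, sds[1:]))
        assert sds[0] == pytest.approx(0.0, abs=1e-6)


class TestSimulateMovie:
    def test_same_seed_bit_identical(self):
        params = SimulationParams(n_cells=3, n_frames=15, seed=42)
        s1, t1 = simulate_movie(params)
        s2, t2 = simulate_movie(params)
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(t1.labels, t2.labels)
        assert t1.events.equals(t2.events)

    def test_single_frame_movie(self):
        params = SimulationParams(n_cells=4, n_frames=1, seed=0)
        stack, truth = simulate_movie(params)
        assert stack.n_frames == 1
        assert truth.lineage == {}
        assert truth.labels.shape[0] == 1

    def test_division_count_matches_programs(self, small_movie):
        params, stack, truth = small_movie
        movie_end = stack.n_frames * stack.dt_hours
        expected = sum(1 for p in truth.programs
                       if not p.quiescent and p.division_time < movie_end - stack.dt_hours)
        assert truth.n_divisions == expected
        for mother, (da, db) in truth.lineage.items():
            assert truth.program(da).parent == mother
            assert truth.program(db).parent == mother

    def test_truth_labels_disjoint_and_events_ordered(self, small_movie):
        _params, stack, truth = small_movie
        # labels cover less than the image, one label per pixel by dtype
        areas = truth.labels[0][truth.labels[0] > 0].size
        assert 0 < areas < truth.labels[0].size
        ev = truth.events.dropna(subset=["g1s_h"])
        assert (ev.birth_h < ev.g1s_h).all()
        assert (ev.g1s_h < ev.s_end_h).all()
        assert (ev.s_end_h < ev.nebd_h).all()
        assert (ev.nebd_h < ev.division_h).all()

    def test_quiescence_mode_declines(self, starvation_movie):
        _params, stack, truth = starvation_movie
        assert truth.n_divisions == 0
        for p in truth.programs:
            assert p.quiescent
            start = p.pcna_level(0.0)
            end = p.pcna_level(stack.n_frames * stack.dt_hours)
            assert end < 0.5 * start

    def test_placement_failure_raises(self):
        params = SimulationParams(n_cells=30, image_size=(64, 64), seed=0,
                                  n_frames=2)
        with pytest.raises(SimulationError, match="retry budget|too small"):
            simulate_movie(params)
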