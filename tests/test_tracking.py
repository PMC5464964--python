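"""Linking, gap closing, division detection and lineage invariants."""

import numpy as np
import pytest

from pcnacycle.pipeline import match_tracks_to_truth
from pcnacycle.segment import LabelMap, segment_nuclei
from pcnacycle.simulate import SimulationParams, simulate_movie
from pcnacycle.track import (LinkParams, close_gaps, detect_divisions,
                             link_frames)
from conftest import truth_track_pairs


def _labelmaps_from(stack):
    pc = stack.channel("pcna")
    return [segment_nuclei(pc[k], frame_index=k) for k in range(stack.n_frames)]


@pytest.fixture(scope="module")
def static_movie():
    params = SimulationParams(n_cells=4, n_frames=12, seed=5, motion_sd=0.0)
    return simulate_movie(params)


class TestLinkFrames:
    def test_static_nuclei_one_track_each(self, static_movie):
        stack, truth = static_movie
        tracks = link_frames(_labelmaps_from(stack))
        assert len(tracks) == 4
        for tr in tracks.values():
            assert len(tr) == stack.n_frames
            assert list(tr.frames) == list(range(stack.n_frames))

    def test_single_frame_gives_length_one_tracks(self, static_movie):
        stack, _ = static_movie
        tracks = link_frames(_labelmaps_from(stack)[:1])
        assert all(len(tr) == 1 for tr in tracks.values())
        assert len(tracks) == 4

    def test_moving_nuclei_unbroken(self):
        params = SimulationParams(n_cells=4, n_frames=30, seed=9)
        stack, truth = simulate_movie(params)
        tracks = link_frames(_labelmaps_from(stack))
        assert len(tracks) == 4
        assert all(len(tr) == 30 for tr in tracks.values())

    def test_no_label_claimed_twice_per_frame(self, small_analysis):
        result, _, _ = small_analysis
        seen = set()
        for tid, tr in result.tracks.items():
            for f, lab in zip(tr.frames, tr.labels):
                assert (f, lab) not in seen
                seen.add((f, lab))


class TestCloseGaps:
    def _with_dropout(self, stack, frame):
        lms = _labelmaps_from(stack)
        victim = sorted(lms[frame].label_ids)[0]
        labels = lms[frame].labels.copy()
        labels[labels == victim] = 0
        lms[frame] = LabelMap(frame, labels)
        return lms

    def test_one_frame_dropout_merged(self, static_movie):
        stack, _ = static_movie
        lms = self._with_dropout(stack, 6)
        tracks = close_gaps(link_frames(lms), LinkParams(max_gap=2))
        assert len(tracks) == 4
        merged = [tr for tr in tracks.values() if len(tr) == stack.n_frames - 1]
        assert len(merged) == 1
        assert 6 not in merged[0].frames

    def test_max_gap_zero_is_identity(self, static_movie):
        stack, _ = static_movie
        lms = self._with_dropout(stack, 6)
        tracks = link_frames(lms)
        n_before = len(tracks)
        after = close_gaps(tracks, LinkParams(max_gap=0))
        assert len(after) == n_before == 5

    def test_gap_beyond_limit_stays_split(self, static_movie):
        stack, _ = static_movie
        lms = self._with_dropout(stack, 5)
        lms = [lm if lm.frame_index != 6 else
               LabelMap(6, np.where(lms[6].labels == sorted(lms[6].label_ids)[0],
                                    0, lms[6].labels))
               for lm in lms]
        # two consecutive dropped frames of the same nucleus: gap = 2
        tracks = close_gaps(link_frames(lms), LinkParams(max_gap=1))
        assert len(tracks) == 5


class TestDivisions:
    def test_all_divisions_recovered_two_daughters(self, small_analysis,
                                                   small_movie):
        _params, _stack, truth = small_movie
        result, assignment, _ = small_analysis
        assert len(result.lineage.divisions) == truth.n_divisions
        true_pairs = {tuple(sorted(v)) for v in truth.lineage.values()}
        for mother, _f, da, db in result.lineage.divisions:
            assert result.tracks[mother].daughter_tracks == (da, db)
            assert result.tracks[da].parent_track == mother
            assert result.tracks[db].parent_track == mother
            pair = tuple(sorted((assignment[da], assignment[db])))
            assert pair in true_pairs

    def test_lineage_depth_matches_two_generations(self, small_analysis):
        result, _, _ = small_analysis
        assert result.lineage.max_depth() == 1  # founders + daughters

    def test_track_purity_is_one(self, small_analysis):
        _result, _assignment, purity = small_analysis
        assert min(purity.values()) == 1.0

    def test_no_divisions_in_short_movie(self):
        params = SimulationParams(n_cells=3, n_frames=20, seed=4)
        stack, truth = simulate_movie(params)
        lms = _labelmaps_from(stack)
        tracks = link_frames(lms)
        means = {tid: np.full(len(tr), 100.0) for tid, tr in tracks.items()}
        lineage = detect_divisions(tracks, means, n_frames=stack.n_frames)
        assert lineage.divisions == []
        assert all(tr.parent_track is None for tr in tracks.values())

    def test_channel_equivalence_one_to_one(self, small_movie):
        """PCNA- and chromatin-based tracking find the same founders."""
        from pcnacycle import AnalysisConfig, analyze_stack
        _params, stack, truth = small_movie
        res_h = analyze_stack(stack, AnalysisConfig(seg_channel="chromatin"))
        res_p = analyze_stack(stack, AnalysisConfig(seg_channel="pcna"))
        map_p = truth_track_pairs(res_p, truth)
        map_h = truth_track_pairs(res_h, truth)
        assert set(map_p) == set(map_h)
        assert len(map_p) == 5
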