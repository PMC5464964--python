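"""High-level orchestration: stack -> tracks -> annotations -> measurements.

`analyze_stack` runs the complete proliferation analysis on an
in-memory :class:`~pcnacycle.simulate.FrameStack` using any channel for
segmentation (PCNA by default, chromatin as the classical reference);
all intensity features always come from the PCNA channel, so the two
segmentation routes are directly comparable cell by cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .phases import (PhaseAnnotation, PhaseParams, TrackFeatureSeries,
                     assign_phases, classify_quiescence, compute_feature_series,
                     detect_g1s, detect_mitosis_events, detect_sg2)
from .segment import LabelMap, SegParams, segment_nuclei
from .simulate import FrameStack, GroundTruth
from .track import (CellTrack, Lineage, LinkParams, close_gaps,
                    detect_divisions, link_frames, refine_tracks)

__all__ = ["AnalysisConfig", "AnalysisResult", "analyze_stack",
           "match_tracks_to_truth"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameter blocks for every pipeline stage."""

    seg: SegParams = field(default_factory=SegParams)
    link: LinkParams = field(default_factory=LinkParams)
    phase: PhaseParams = field(default_factory=PhaseParams)
    seg_channel: str = "pcna"
    use_chromatin_confirmation: bool = True


@dataclass
class AnalysisResult:
    """Everything the pipeline derives from one movie."""

    config: AnalysisConfig
    labelmaps: list[LabelMap]
    tracks: dict[int, CellTrack]
    lineage: Lineage
    features: dict[int, TrackFeatureSeries]
    annotations: dict[int, PhaseAnnotation]
    reporter_series: dict[str, dict[int, np.ndarray]]  # channel -> track -> nuclear mean
    dt_hours: float

    def annotated_tracks(self) -> list[int]:
        return [t for t, a in self.annotations.items()
                if a.birth_frame is not None]


def _birth_frame(track: CellTrack, lineage: Lineage) -> int | None:
    """Birth is known for tracks present at movie start or born by division."""
    if track.parent_track is not None:
        return track.start
    if track.start == 0:
        return 0
    return None


def analyze_stack(stack: FrameStack, config: AnalysisConfig = AnalysisConfig(),
                  ) -> AnalysisResult:
    """Segment, track, re-segment locally, and classify every track."""
    seg_rasters = stack.channel(config.seg_channel)
    pcna_rasters = stack.channel("pcna")
    chromatin = None
    if config.use_chromatin_confirmation and "chromatin" in stack.channel_names:
        chromatin = stack.channel("chromatin")

    labelmaps = [segment_nuclei(seg_rasters[k], config.seg, frame_index=k)
                 for k in range(stack.n_frames)]

    tracks = link_frames(labelmaps, config.link)
    tracks = close_gaps(tracks, config.link)
    refine_tracks(tracks, labelmaps, seg_rasters, config.seg, config.link)

    dt = stack.dt_hours
    features: dict[int, TrackFeatureSeries] = {}
    for tid, tr in tracks.items():
        fs = compute_feature_series(
            tr, pcna_rasters, labelmaps, w=config.phase.smooth_window,
            chromatin_rasters=chromatin, dt_hours=dt,
            width_statistic=config.phase.width_statistic)
        features[tid] = fs

    pcna_means = {tid: fs.nuclear_mean_smooth for tid, fs in features.items()}
    lineage = detect_divisions(tracks, pcna_means, config.link,
                               n_frames=stack.n_frames)

    # nuclear mean series of every non-segmentation reporter channel
    reporter_series: dict[str, dict[int, np.ndarray]] = {}
    for name in stack.channel_names:
        if name in ("pcna", "chromatin", config.seg_channel):
            continue
        rasters = stack.channel(name)
        per_track = {}
        for tid, tr in tracks.items():
            fs = compute_feature_series(tr, rasters, labelmaps,
                                        w=config.phase.smooth_window, dt_hours=dt)
            per_track[tid] = fs.nuclear_mean
        reporter_series[name] = per_track

    annotations: dict[int, PhaseAnnotation] = {}
    pp = config.phase
    for tid, tr in tracks.items():
        ann = PhaseAnnotation(track_id=tid)
        fs = features[tid]
        ann.birth_frame = _birth_frame(tr, lineage)
        if ann.birth_frame is None:
            ann.flags["birth"] = "unknown_origin"
            annotations[tid] = ann
            continue

        nebd_events = detect_mitosis_events(
            fs, d_min=pp.nebd_drop,
            require_chromatin_peak=chromatin is not None)
        if nebd_events:
            ann.nebd_frame = nebd_events[-1]
        if tr.daughter_tracks is not None:
            ann.division_frame = tr.end

        g1s, flag = detect_g1s(fs, ann.birth_frame, pp)
        if flag:
            ann.flags["g1s"] = flag
        # an onset found at/after NEBD is spurious (mitotic redistribution)
        if g1s is not None and ann.nebd_frame is not None and g1s >= ann.nebd_frame:
            g1s = None
        ann.g1s_frame = g1s

        if ann.g1s_frame is not None and ann.nebd_frame is not None:
            sg2, flag = detect_sg2(fs, ann.g1s_frame, ann.nebd_frame)
            if flag:
                ann.flags["sg2"] = flag
            ann.sg2_frame = sg2

        if ann.g1s_frame is None:
            quiescent, onset, flag = classify_quiescence(
                fs, ann.birth_frame, pp, g1s_frame=None)
            if flag:
                ann.flags["quiescence"] = flag
            if quiescent:
                ann.quiescent = True
                ann.decline_onset_frame = onset

        assign_phases(ann, (tr.start, tr.end))
        annotations[tid] = ann

    return AnalysisResult(config=config, labelmaps=labelmaps, tracks=tracks,
                          lineage=lineage, features=features,
                          annotations=annotations,
                          reporter_series=reporter_series, dt_hours=dt)


# ---------------------------------------------------------------------------
# truth matching (evaluation harness)
# ---------------------------------------------------------------------------

def match_tracks_to_truth(result: AnalysisResult, truth: GroundTruth,
                          ) -> tuple[dict[int, int], dict[int, float]]:
    """Majority-overlap assignment of tracks to true cells.

    Returns (track_id -> true cell id, track_id -> purity) where purity
    is the fraction of the track's detections whose per-frame majority
    truth label equals the track's overall majority.
    """
    frame_of = {lm.frame_index: lm for lm in result.labelmaps}
    assignment: dict[int, int] = {}
    purity: dict[int, float] = {}
    for tid, tr in result.tracks.items():
        votes: dict[int, int] = {}
        per_frame: list[int] = []
        for f, lab in zip(tr.frames, tr.labels):
            mask = frame_of[f].labels == lab
            ids = truth.labels[f][mask]
            ids = ids[ids > 0]
            if ids.size == 0:
                per_frame.append(0)
                continue
            counts = np.bincount(ids)
            best = int(np.argmax(counts))
            per_frame.append(best)
            votes[best] = votes.get(best, 0) + 1
        if not votes:
            continue
        majority = max(votes, key=lambda k: (votes[k], -k))
        assignment[tid] = majority
        valid = [p for p in per_frame if p > 0]
        purity[tid] = (sum(p == majority for p in valid) / len(valid)
                       if valid else 0.0)
    return assignment, purity
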