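"""Frame-to-frame linking, gap closing, division detection and lineage.

Linking is greedy on the Jaccard overlap between consecutive label
maps, with a nearest-centroid fallback for labels left unmatched (small
masks can lose all overlap in one frame of fast motion). A terminated
track and a later-born one are merged across short detection gaps.
Divisions are recognised after linking: a mother that terminates with a
preceding NEBD-like intensity drop is joined to exactly two tracks born
shortly after within a distance budget. The result is an acyclic
lineage forest in which every division has exactly two daughters.

Tie-breaks are deterministic throughout: larger overlap first, then
smaller centroid distance, then lower label id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .segment import LabelMap, SegParams, local_resegment

__all__ = ["CellTrack", "Lineage", "LinkParams", "link_frames", "close_gaps",
           "detect_divisions", "refine_tracks"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinkParams:
    """Linking and division-detection parameters (pixels, frames)."""

    min_jaccard: float = 0.15
    area_ratio_bounds: tuple[float, float] = (0.33, 3.0)  # next/prev area gate

    def __post_init__(self) -> None:
        # YAML round trips deliver lists; keep the field hashable
        object.__setattr__(self, "area_ratio_bounds",
                           tuple(self.area_ratio_bounds))
    max_displacement: float = 12.0  # px/frame, centroid fallback + gap closing
    max_gap: int = 2  # frames a detection may drop out
    division_window: int = 3  # frames between mother end and daughter birth
    division_radius: float = 42.0  # px, ~3 nucleus radii
    nebd_lookback: int = 5  # frames before mother end to search for the drop
    nebd_drop: float = 0.3  # fractional one-frame intensity drop
    area_drop_resegment: float = 0.3  # rolling-median area drop triggering reseg


@dataclass
class CellTrack:
    """One cell's trajectory: per-frame (frame, label, centroid, area)."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    areas: list[int] = field(default_factory=list)
    parent_track: int | None = None
    daughter_tracks: tuple[int, int] | None = None

    def append(self, frame: int, label: int, centroid: tuple[float, float],
               area: int) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("frames must be strictly increasing")
        self.frames.append(frame)
        self.labels.append(label)
        self.centroids.append(centroid)
        self.areas.append(area)

    @property
    def start(self) -> int:
        return self.frames[0]

    @property
    def end(self) -> int:
        return self.frames[-1]

    def __len__(self) -> int:
        return len(self.frames)

    def label_at(self, frame: int) -> int | None:
        try:
            return self.labels[self.frames.index(frame)]
        except ValueError:
            return None


@dataclass
class Lineage:
    """Forest of tracks plus explicit division events."""

    tracks: dict[int, CellTrack]
    divisions: list[tuple[int, int, int, int]] = field(default_factory=list)
    # (mother_track, frame_of_mother_end, daughter_a, daughter_b)

    def roots(self) -> list[int]:
        return [t for t, tr in self.tracks.items() if tr.parent_track is None]

    def depth(self, track_id: int) -> int:
        d = 0
        t = self.tracks[track_id]
        while t.parent_track is not None:
            d += 1
            t = self.tracks[t.parent_track]
        return d

    def max_depth(self) -> int:
        return max((self.depth(t) for t in self.tracks), default=0)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def _overlap_table(a: np.ndarray, b: np.ndarray) -> dict[tuple[int, int], int]:
    """Pixel overlap counts between labels of two frames."""
    both = (a > 0) & (b > 0)
    if not both.any():
        return {}
    pairs = a[both].astype(np.int64) * (b.max() + 1) + b[both]
    uniq, counts = np.unique(pairs, return_counts=True)
    k = int(b.max() + 1)
    return {(int(p // k), int(p % k)): int(n) for p, n in zip(uniq, counts)}


def link_frames(labelmaps: list[LabelMap],
                params: LinkParams = LinkParams()) -> dict[int, CellTrack]:
    """Greedy overlap linking of consecutive frames into tracks."""
    if not labelmaps:
        raise ValueError("need at least one frame")
    tracks: dict[int, CellTrack] = {}
    next_id = 1
    # active: label in previous frame -> track_id
    active: dict[int, int] = {}
    prev = labelmaps[0]
    for lab in prev.label_ids:
        tr = CellTrack(next_id)
        tr.append(prev.frame_index, int(lab), prev.centroids[int(lab)],
                  prev.areas[int(lab)])
        tracks[next_id] = tr
        active[int(lab)] = next_id
        next_id += 1

    for cur in labelmaps[1:]:
        overlaps = _overlap_table(prev.labels, cur.labels)
        candidates = []
        lo_ratio, hi_ratio = params.area_ratio_bounds
        for (la, lb), inter in overlaps.items():
            union = prev.areas[la] + cur.areas[lb] - inter
            jac = inter / union if union else 0.0
            ratio = cur.areas[lb] / max(prev.areas[la], 1)
            # the area gate keeps a large mitotic blob from linking onto a
            # half-size daughter; normal growth never moves this fast
            if jac >= params.min_jaccard and lo_ratio <= ratio <= hi_ratio:
                d = float(np.hypot(
                    prev.centroids[la][0] - cur.centroids[lb][0],
                    prev.centroids[la][1] - cur.centroids[lb][1]))
                candidates.append((-jac, d, la, lb))
        candidates.sort()
        matched_prev: set[int] = set()
        matched_cur: set[int] = set()
        assignment: dict[int, int] = {}
        for _negjac, _d, la, lb in candidates:
            if la in matched_prev or lb in matched_cur:
                continue
            matched_prev.add(la)
            matched_cur.add(lb)
            assignment[lb] = active[la]

        # nearest-centroid fallback for labels without overlap
        free_prev = [la for la in active if la not in matched_prev]
        free_cur = [int(l) for l in cur.label_ids if int(l) not in matched_cur]
        fallback = []
        for la in free_prev:
            for lb in free_cur:
                d = float(np.hypot(
                    prev.centroids[la][0] - cur.centroids[lb][0],
                    prev.centroids[la][1] - cur.centroids[lb][1]))
                if d <= params.max_displacement:
                    fallback.append((d, la, lb))
        fallback.sort()
        for d, la, lb in fallback:
            if la in matched_prev or lb in matched_cur:
                continue
            matched_prev.add(la)
            matched_cur.add(lb)
            assignment[lb] = active[la]

        new_active: dict[int, int] = {}
        for lb in sorted(int(l) for l in cur.label_ids):
            if lb in assignment:
                tid = assignment[lb]
            else:
                tid = next_id
                tracks[tid] = CellTrack(tid)
                next_id += 1
            tracks[tid].append(cur.frame_index, lb, cur.centroids[lb],
                               cur.areas[lb])
            new_active[lb] = tid
        active = new_active
        prev = cur
    return tracks


def close_gaps(tracks: dict[int, CellTrack],
               params: LinkParams = LinkParams()) -> dict[int, CellTrack]:
    """Merge a terminated track with a compatible later-born track.

    A merge requires 1 <= gap <= max_gap missing frames, a centroid jump
    within ``max_displacement * (gap + 1)``, and an area ratio in
    [0.5, 2]. ``max_gap = 0`` is the identity. The merged track keeps
    the earlier id; missing frames stay missing (features flag them).
    """
    if params.max_gap <= 0:
        return tracks
    ends = sorted(tracks.values(), key=lambda t: (t.end, t.track_id))
    merged_into: dict[int, int] = {}
    candidates = []
    for a in ends:
        for b in tracks.values():
            if b.track_id == a.track_id:
                continue
            gap = b.start - a.end - 1
            if not (1 <= gap <= params.max_gap):
                continue
            d = float(np.hypot(a.centroids[-1][0] - b.centroids[0][0],
                               a.centroids[-1][1] - b.centroids[0][1]))
            if d > params.max_displacement * (gap + 1):
                continue
            ratio = b.areas[0] / max(a.areas[-1], 1)
            if not (0.5 <= ratio <= 2.0):
                continue
            candidates.append((d, a.track_id, b.track_id))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = {t: tr for t, tr in tracks.items()}
    for d, ta, tb in candidates:
        while ta in merged_into:
            ta = merged_into[ta]
        if ta in used_a or tb in used_b or ta == tb:
            continue
        a, b = out[ta], out[tb]
        if b.start <= a.end:
            continue
        for i in range(len(b)):
            a.append(b.frames[i], b.labels[i], b.centroids[i], b.areas[i])
        a.daughter_tracks = b.daughter_tracks
        used_a.add(ta)
        used_b.add(tb)
        merged_into[tb] = ta
        del out[tb]
    # repair parent pointers of daughters of merged tracks
    for tr in out.values():
        if tr.parent_track in merged_into:
            tr.parent_track = merged_into[tr.parent_track]
    return out


# ---------------------------------------------------------------------------
# division detection
# ---------------------------------------------------------------------------

def _has_nebd_drop(values: np.ndarray, lookback: int, drop: float) -> bool:
    """One-frame fractional drop >= ``drop`` within the trailing window."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        return False
    tail = v[-(lookback + 1):]
    for i in range(len(tail) - 1):
        if tail[i] > 0 and tail[i + 1] <= (1 - drop) * tail[i]:
            return True
    return False


def detect_divisions(tracks: dict[int, CellTrack],
                     pcna_means: dict[int, np.ndarray],
                     params: LinkParams = LinkParams(),
                     n_frames: int | None = None) -> Lineage:
    """Assemble a lineage by pairing terminated mothers with daughters.

    ``pcna_means`` maps track_id -> per-entry nuclear PCNA mean (aligned
    with the track's frames); the mother must show the NEBD drop
    signature within the lookback window. A mother with a single
    plausible daughter is left unlinked (termination), logged.
    """
    if n_frames is None:
        n_frames = max((t.end for t in tracks.values()), default=0) + 1
    lineage = Lineage(tracks={t: tr for t, tr in tracks.items()})
    by_start: dict[int, list[CellTrack]] = {}
    for tr in tracks.values():
        by_start.setdefault(tr.start, []).append(tr)

    for mother in sorted(tracks.values(), key=lambda t: (t.end, t.track_id)):
        if mother.end >= n_frames - 1:
            continue  # survives to movie end
        if mother.daughter_tracks is not None:
            continue
        means = pcna_means.get(mother.track_id)
        if means is None or not _has_nebd_drop(
                np.asarray(means), params.nebd_lookback, params.nebd_drop):
            continue
        mc = mother.centroids[-1]
        cands = []
        for f in range(mother.end + 1, mother.end + params.division_window + 1):
            for tr in by_start.get(f, []):
                if tr.parent_track is not None or tr.track_id == mother.track_id:
                    continue
                d = float(np.hypot(tr.centroids[0][0] - mc[0],
                                   tr.centroids[0][1] - mc[1]))
                if d <= params.division_radius:
                    cands.append((d, tr))
        if len(cands) < 2:
            if len(cands) == 1:
                log.info("track %d: single division candidate, leaving as "
                         "termination", mother.track_id)
            continue
        # prefer the pair whose summed area best matches the mother's
        # typical (pre-mitotic) area, then the closest pair
        ref_area = float(np.median(mother.areas[:max(1, len(mother) - params.nebd_lookback)]))
        best = min(
            combinations(sorted(cands, key=lambda c: (c[0], c[1].track_id)), 2),
            key=lambda pair: (
                abs(pair[0][1].areas[0] + pair[1][1].areas[0] - ref_area),
                pair[0][0] + pair[1][0],
                pair[0][1].track_id, pair[1][1].track_id))
        (da_d, da), (db_d, db) = best
        da, db = sorted((da, db), key=lambda t: t.track_id)
        mother.daughter_tracks = (da.track_id, db.track_id)
        da.parent_track = mother.track_id
        db.parent_track = mother.track_id
        lineage.divisions.append(
            (mother.track_id, mother.end, da.track_id, db.track_id))
    return lineage


# ---------------------------------------------------------------------------
# post-tracking local re-segmentation
# ---------------------------------------------------------------------------

def refine_tracks(tracks: dict[int, CellTrack], labelmaps: list[LabelMap],
                  rasters: np.ndarray, seg_params: SegParams = SegParams(),
                  link_params: LinkParams = LinkParams(),
                  window: int = 7) -> None:
    """Local re-segmentation for frames where a track's mask collapsed.

    For every track entry whose area falls more than
    ``area_drop_resegment`` below the rolling median of the track's
    areas, re-threshold locally seeded by the previous frame's mask and
    replace the entry's pixels (only pixels not claimed by other labels
    are taken). Mutates ``labelmaps`` and the track records in place.
    """
    frame_of = {lm.frame_index: lm for lm in labelmaps}
    for tr in tracks.values():
        if len(tr) < 3:
            continue
        areas = np.asarray(tr.areas, dtype=float)
        k = min(window, len(areas) if len(areas) % 2 else len(areas) - 1)
        med = np.array([
            np.median(areas[max(0, i - k // 2):i + k // 2 + 1])
            for i in range(len(areas))])
        for i in range(1, len(tr)):
            if areas[i] >= (1 - link_params.area_drop_resegment) * med[i]:
                continue
            frame = tr.frames[i]
            prev_frame = tr.frames[i - 1]
            if frame not in frame_of or prev_frame not in frame_of:
                continue
            prior = frame_of[prev_frame].labels == tr.labels[i - 1]
            refined = local_resegment(rasters[frame], prior, seg_params)
            if not refined.any():
                continue
            lm = frame_of[frame]
            lab = tr.labels[i]
            takeable = refined & ((lm.labels == 0) | (lm.labels == lab))
            if takeable.sum() <= areas[i]:
                continue
            lm.labels[lm.labels == lab] = 0
            lm.labels[takeable] = lab
            lm._areas = None
            lm._centroids = None
            tr.areas[i] = int(takeable.sum())
            rr, cc = np.nonzero(takeable)
            tr.centroids[i] = (float(rr.mean()), float(cc.mean()))
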