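"""Cell-cycle phase classification from PCNA abundance and localization.

All phases are derived from two per-frame features of the tracked
nucleus mask on the PCNA channel:

* ``nuclear_mean`` — background-subtracted mean intensity; its onset of
  increase marks G1/S, its abrupt (>30%) one-frame drop marks nuclear
  envelope breakdown (NEBD), and its gradual loss marks quiescence;
* ``nuclear_sd`` — the within-mask pixel standard deviation ("intensity
  distribution width"), a proxy for replication-focus granularity whose
  maximum marks the S/G2 transition.

An optional chromatin-channel distribution width confirms NEBD (the
condensing chromosomes strongly widen the histone intensity spread).

Event detectors operate on running-median-smoothed series and are
invariant under global positive scaling of the intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import LabelMap
from .track import CellTrack

__all__ = [
    "TrackFeatureSeries", "PhaseAnnotation", "PhaseParams",
    "compute_feature_series", "detect_mitosis_events", "detect_g1s",
    "detect_sg2", "classify_quiescence", "assign_phases", "align_tracks",
    "running_median",
]

PHASES = ("G1", "S", "G2", "M", "G0", "unknown")


@dataclass(frozen=True)
class PhaseParams:
    """Event-detector parameters (defaults per the pipeline contract)."""

    smooth_window: int = 3  # frames, running median
    baseline_window_h: float = 4.0  # G1/S baseline after birth
    rise_fraction: float = 0.10  # epsilon above baseline
    persistence: int = 3  # frames a rise must persist
    nebd_drop: float = 0.3  # d_min
    q_frac: float = 0.4  # quiescence: fractional loss vs birth level
    q_span_h: float = 24.0  # T_q: minimal non-increasing span
    q_tolerance: float = 0.05  # allowed uptick within a declining run
    width_statistic: str = "sd"  # "sd" | "iqr"


@dataclass
class TrackFeatureSeries:
    """Per-frame feature series of one track (NaN = missing frame)."""

    track_id: int
    frames: np.ndarray  # int, strictly increasing, contiguous over span
    times_h: np.ndarray
    nuclear_mean: np.ndarray
    nuclear_sd: np.ndarray
    area: np.ndarray
    chromatin_sd: np.ndarray | None = None
    smooth_window: int = 3

    nuclear_mean_smooth: np.ndarray = field(init=False)
    nuclear_sd_smooth: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.frames)
        for name in ("times_h", "nuclear_mean", "nuclear_sd", "area"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != track length")
        if np.any(self.nuclear_sd[np.isfinite(self.nuclear_sd)] < 0):
            raise ValueError("nuclear_sd must be >= 0")
        self.nuclear_mean_smooth = running_median(self.nuclear_mean,
                                                  self.smooth_window)
        self.nuclear_sd_smooth = running_median(self.nuclear_sd,
                                                self.smooth_window)

    @property
    def dt_hours(self) -> float:
        if len(self.times_h) > 1:
            return float(self.times_h[1] - self.times_h[0])
        return 1.0

    def index_of(self, frame: int) -> int:
        return int(frame - self.frames[0])


@dataclass
class PhaseAnnotation:
    """Event frames and per-frame phase labels of one track."""

    track_id: int
    birth_frame: int | None = None
    g1s_frame: int | None = None
    sg2_frame: int | None = None
    nebd_frame: int | None = None
    division_frame: int | None = None
    quiescent: bool = False
    decline_onset_frame: int | None = None
    phases: np.ndarray | None = None  # per-frame labels over the track span
    flags: dict[str, str] = field(default_factory=dict)

    def events_ordered(self) -> bool:
        ev = [self.birth_frame, self.g1s_frame, self.sg2_frame, self.nebd_frame]
        present = [e for e in ev if e is not None]
        ordered = all(a < b for a, b in zip(present, present[1:]))
        if self.nebd_frame is not None and self.division_frame is not None:
            ordered &= self.nebd_frame <= self.division_frame
        return ordered


def running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median, NaN-aware, min_periods=1."""
    if window <= 1:
        return np.asarray(x, dtype=float).copy()
    s = pd.Series(np.asarray(x, dtype=float))
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def compute_feature_series(track: CellTrack, rasters: np.ndarray,
                           labelmaps: list[LabelMap], w: int = 3,
                           chromatin_rasters: np.ndarray | None = None,
                           background_percentile: float = 5.0,
                           width_statistic: str = "sd",
                           dt_hours: float = 1.0,
                           ) -> TrackFeatureSeries:
    """Per-frame nuclear mean and distribution width of one track.

    Intensities are background-subtracted per frame (percentile of the
    out-of-mask pixels). Frames inside the track span without a mask
    (closed gaps) are marked NaN, never interpolated.
    """
    frame_of = {lm.frame_index: lm for lm in labelmaps}
    span = np.arange(track.start, track.end + 1)
    nuc_mean = np.full(len(span), np.nan)
    nuc_sd = np.full(len(span), np.nan)
    area = np.full(len(span), np.nan)
    chrom_sd = (np.full(len(span), np.nan)
                if chromatin_rasters is not None else None)
    track_frames = dict(zip(track.frames, track.labels))
    for i, f in enumerate(span):
        lab = track_frames.get(int(f))
        if lab is None or f not in frame_of:
            continue
        mask = frame_of[f].labels == lab
        if not mask.any():
            continue
        raster = rasters[f]
        bg = np.percentile(raster[frame_of[f].labels == 0],
                           background_percentile)
        vals = raster[mask] - bg
        nuc_mean[i] = float(vals.mean())
        if width_statistic == "iqr":
            nuc_sd[i] = float(np.subtract(*np.percentile(vals, [75, 25])))
        else:
            nuc_sd[i] = float(vals.std())
        area[i] = int(mask.sum())
        if chrom_sd is not None:
            cvals = chromatin_rasters[f][mask]
            chrom_sd[i] = float(cvals.std())
    return TrackFeatureSeries(
        track_id=track.track_id, frames=span,
        times_h=span.astype(float) * dt_hours,
        nuclear_mean=nuc_mean, nuclear_sd=nuc_sd, area=area,
        chromatin_sd=chrom_sd, smooth_window=w)


# ---------------------------------------------------------------------------
# event detectors
# ---------------------------------------------------------------------------

def detect_mitosis_events(series: TrackFeatureSeries,
                          d_min: float = 0.3,
                          require_chromatin_peak: bool = True) -> list[int]:
    """NEBD events: one-frame drops of the smoothed nuclear PCNA mean.

    A drop between indices f and f+1 reports event frame f+1 (the first
    frame at the redistributed level). When a chromatin distribution
    width is available, the drop must coincide with a local maximum of
    that width within +/-2 frames — the condensed-chromosome signature.
    """
    sm = series.nuclear_mean_smooth
    if len(sm) < 3:
        return []
    events = []
    for i in range(len(sm) - 1):
        a, b = sm[i], sm[i + 1]
        if not (np.isfinite(a) and np.isfinite(b)) or a <= 0:
            continue
        if b <= (1 - d_min) * a:
            if require_chromatin_peak and series.chromatin_sd is not None:
                # raw width: the condensation peak may last a single frame
                # and would not survive the running median
                cs = np.asarray(series.chromatin_sd, dtype=float)
                lo, hi = max(0, i - 1), min(len(cs), i + 4)
                window = cs[lo:hi]
                rest = np.concatenate([cs[:lo], cs[hi:]])
                rest = rest[np.isfinite(rest)]
                if rest.size and np.nanmax(window) < np.nanmax(rest) * 0.9:
                    continue
            events.append(int(series.frames[i + 1]))
    return events


def _two_segment_changepoint(t: np.ndarray, y: np.ndarray,
                             slope_sign: float = 1.0) -> int | None:
    """Index minimizing SSE of a flat-then-ramp least-squares fit.

    Model: y = mu for t < t_c, y = mu + s*(t - t_c) afterwards, with the
    slope constrained to ``slope_sign``. Ties resolve to the earliest
    candidate. Returns the index into ``t``/``y``.
    """
    good = np.isfinite(y)
    if good.sum() < 4:
        return None
    best, best_sse = None, np.inf
    for ci in range(1, len(t) - 1):
        ramp = np.clip(t - t[ci], 0, None)
        X = np.column_stack([np.ones(len(t)), ramp])[good]
        yy = y[good]
        coef, *_ = np.linalg.lstsq(X, yy, rcond=None)
        if coef[1] * slope_sign < 0:
            coef = np.array([yy.mean(), 0.0])
        resid = yy - X @ coef
        sse = float(resid @ resid)
        if sse < best_sse - 1e-12:
            best_sse = sse
            best = ci
    return best


def detect_g1s(series: TrackFeatureSeries, birth_frame: int,
               params: PhaseParams = PhaseParams(),
               signal: np.ndarray | None = None,
               ) -> tuple[int | None, str | None]:
    """Onset of increasing nuclear PCNA expression (S-phase entry).

    Baseline = median of the smoothed series over the first
    ``baseline_window_h`` hours after birth; the candidate onset is the
    first frame exceeding ``baseline + max(eps*baseline, 4*MAD)`` that
    stays there for ``persistence`` frames, refined by a two-segment
    flat-then-ramp least-squares changepoint fit over [birth,
    candidate + persistence]. Returns (frame or None, quality flag).
    The estimate is invariant under global positive scaling. The same
    rule serves co-reporter onset detection via ``signal``.
    """
    sm = (running_median(signal, series.smooth_window)
          if signal is not None else series.nuclear_mean_smooth)
    dt = series.dt_hours
    b = series.index_of(birth_frame)
    if b < 0 or b >= len(sm):
        return None, "birth_outside_track"
    w = max(2, int(round(params.baseline_window_h / dt)))
    if len(sm) - b < w:
        return None, "track_shorter_than_baseline_window"
    base_win = sm[b:b + w]
    base_win = base_win[np.isfinite(base_win)]
    if base_win.size < 2:
        return None, "baseline_missing"
    baseline = float(np.median(base_win))
    mad = float(np.median(np.abs(base_win - baseline))) * 1.4826
    thr = baseline + max(params.rise_fraction * abs(baseline), 4.0 * mad)

    m = params.persistence
    cand = None
    for i in range(b, len(sm) - m + 1):
        window = sm[i:i + m]
        if np.all(np.isfinite(window)) and np.all(window >= thr) and sm[i] >= thr:
            cand = i
            break
    if cand is None:
        return None, "no_rise"
    hi = min(len(sm), cand + m + 1)
    t = series.times_h[b:hi]
    y = sm[b:hi]
    ci = _two_segment_changepoint(t, y, slope_sign=1.0)
    if ci is None:
        return int(series.frames[cand]), "changepoint_degenerate"
    return int(series.frames[b + ci]), None


def detect_sg2(series: TrackFeatureSeries, g1s_frame: int, nebd_frame: int,
               ) -> tuple[int | None, str | None]:
    """S/G2 transition: argmax of the smoothed distribution width.

    Searched over the open interval (g1s, nebd); ties resolve to the
    latest frame (the width maximum sits at the end of S phase). A
    constant width over the interval is flagged undefined.
    """
    if not g1s_frame < nebd_frame:
        raise ValueError("g1s_frame must precede nebd_frame")
    i0 = series.index_of(g1s_frame) + 1
    i1 = series.index_of(nebd_frame)  # exclusive
    if i1 - i0 < 3:
        return None, "interval_too_short"
    x = series.nuclear_sd_smooth[i0:i1]
    good = np.isfinite(x)
    if good.sum() < 3:
        return None, "interval_missing"
    rng = np.nanmax(x) - np.nanmin(x)
    if not np.isfinite(rng) or rng <= 1e-9 * max(abs(np.nanmax(x)), 1e-30):
        return None, "width_constant"
    best = np.nanmax(x)
    idx = np.nonzero(good & (x >= best - 1e-12 * abs(best)))[0][-1]
    return int(series.frames[i0 + idx]), None


def classify_quiescence(series: TrackFeatureSeries, birth_frame: int,
                        params: PhaseParams = PhaseParams(),
                        g1s_frame: int | None = None,
                        ) -> tuple[bool | None, int | None, str | None]:
    """Quiescence call plus decline-onset estimate.

    Quiescent iff no G1/S onset was found, the smoothed nuclear PCNA
    falls below ``(1 - q_frac)`` of the birth-window level, and the
    series is non-increasing (within ``q_tolerance``) over at least
    ``q_span_h`` hours. The decline onset is refined by a
    flat-then-linear changepoint fit on the log intensities. Returns
    (quiescent | None, onset frame | None, flag).
    """
    sm = series.nuclear_mean_smooth
    dt = series.dt_hours
    span_h = (len(sm) - 1) * dt
    if span_h < params.q_span_h:
        return None, None, "track_shorter_than_Tq"
    if g1s_frame is not None:
        return False, None, None
    b = max(0, series.index_of(birth_frame))
    birth_win = sm[b:b + max(2, int(round(2.0 / dt)))]
    birth_level = float(np.nanmedian(birth_win))
    if not np.isfinite(birth_level) or birth_level <= 0:
        return None, None, "birth_level_undefined"

    # longest tolerant non-increasing run reaching the loss threshold
    need = int(round(params.q_span_h / dt))
    qualifying_start = None
    i = b
    while i < len(sm):
        if not np.isfinite(sm[i]):
            i += 1
            continue
        run_min = sm[i]
        j = i
        while j + 1 < len(sm):
            v = sm[j + 1]
            if np.isfinite(v) and v > (1 + params.q_tolerance) * run_min:
                break
            if np.isfinite(v):
                run_min = min(run_min, v)
            j += 1
        if j - i >= need and run_min < (1 - params.q_frac) * birth_level:
            qualifying_start = i
            break
        i = max(j, i + 1)
    if qualifying_start is None:
        return False, None, None

    # refine the onset: flat-then-declining-ramp fit on log intensities
    pos = sm > 0
    y = np.where(pos, np.log(np.where(pos, sm, 1.0)), np.nan)
    ci = _two_segment_changepoint(series.times_h, y, slope_sign=-1.0)
    onset_idx = ci if ci is not None else qualifying_start
    return True, int(series.frames[onset_idx]), None


def assign_phases(annotation: PhaseAnnotation, span: tuple[int, int],
                  ) -> np.ndarray | None:
    """Per-frame phase labels over ``span`` = (first_frame, last_frame).

    G1 = [birth, g1s), S = [g1s, sg2), G2 = [sg2, nebd), M = [nebd,
    division]; G0 from the quiescence-decline onset onward; frames
    outside resolvable events are "unknown". Ordering violations yield
    None and flag the track inconsistent.
    """
    if not annotation.events_ordered():
        annotation.flags["events"] = "inconsistent_ordering"
        annotation.phases = None
        return None
    first, last = span
    labels = np.array(["unknown"] * (last - first + 1), dtype=object)

    def fill(a: int | None, b: int | None, phase: str, inclusive: bool = False) -> None:
        if a is None:
            return
        stop = (b + 1 if (b is not None and inclusive) else b)
        if stop is None:
            stop = last + 1
        lo = max(first, a) - first
        hi = min(last + 1, stop) - first
        if hi > lo:
            labels[lo:hi] = phase

    a = annotation
    if a.quiescent:
        fill(a.decline_onset_frame, None, "G0")
    else:
        fill(a.birth_frame, a.g1s_frame, "G1")
        fill(a.g1s_frame, a.sg2_frame, "S")
        fill(a.sg2_frame, a.nebd_frame, "G2")
        if a.nebd_frame is not None:
            fill(a.nebd_frame, a.division_frame, "M", inclusive=True)
    annotation.phases = labels
    return labels


def align_tracks(series_list: list[np.ndarray], event_indices: list[int | None],
                 window_h: float, dt_hours: float,
                 ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Resample tracks on a common grid with t = 0 at a chosen event.

    All series share the acquisition grid, so alignment is an index
    shift; positions outside a track's span are NaN (no extrapolation).
    Tracks lacking the event are excluded. Returns (matrix, time grid in
    hours, indices of the included tracks).
    """
    k = int(round(window_h / dt_hours))
    grid = np.arange(-k, k + 1) * dt_hours
    rows, included = [], []
    for i, (series, ev) in enumerate(zip(series_list, event_indices)):
        if ev is None:
            continue
        row = np.full(2 * k + 1, np.nan)
        for j, off in enumerate(range(-k, k + 1)):
            idx = ev + off
            if 0 <= idx < len(series):
                row[j] = series[idx]
        rows.append(row)
        included.append(i)
    matrix = np.vstack(rows) if rows else np.empty((0, 2 * k + 1))
    return matrix, grid, included
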