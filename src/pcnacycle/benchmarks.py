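"""End-to-end accuracy benchmarks on ground-truthed synthetic movies.

One default proliferation movie (>= 36 founder cells, 10-min frames,
default noise, PCNA + chromatin + cyclin A2-like channels) is analysed
twice — once segmenting on the PCNA channel, once on the chromatin
channel — and the two runs are compared per cell against each other and
against the generator's ground truth:

* G1/S agreement between the two segmentation routes (hours, per cell);
* relative deviation of co-reporter nuclear intensities extracted with
  the two mask sets (percent, per time point with positive signal);
* recovered nuclear PCNA plateau-to-baseline fold change;
* recovered lag between the PCNA expression onset and the onset of a
  co-reporter programmed to switch on 45 min later;
* tracking purity and division recovery.

All quantities are recomputed from scratch for a given seed; nothing is
cached or tabulated.
"""

from __future__ import annotations


import numpy as np

from .phases import detect_g1s
from .pipeline import (AnalysisConfig, AnalysisResult, analyze_stack,
                       match_tracks_to_truth)
from .simulate import GroundTruth, SimulationParams, simulate_movie

__all__ = ["run_paired_benchmark", "acceptance_targets"]


def _first_generation_map(result: AnalysisResult, truth: GroundTruth,
                          ) -> dict[int, int]:
    """true founder cell id -> track id (founders are born at frame 0)."""
    assignment, _purity = match_tracks_to_truth(result, truth)
    out: dict[int, int] = {}
    founders = set(truth.events.loc[truth.events.parent.isna(), "cell"].astype(int))
    for tid, cell in assignment.items():
        if cell in founders and result.tracks[tid].start == 0:
            # keep the longest track mapped to this founder
            if cell not in out or len(result.tracks[tid]) > len(result.tracks[out[cell]]):
                out[cell] = tid
    return out


def run_paired_benchmark(seed: int, n_cells: int = 50,
                         frame_interval: float = 10.0) -> dict:
    """Simulate one default movie and analyse it on both channels.

    Returns a dict with the raw per-cell measurements and the summary
    quantities listed in the module docstring.
    """
    params = SimulationParams(n_cells=n_cells, frame_interval=frame_interval,
                              seed=seed)
    stack, truth = simulate_movie(params)
    res_p = analyze_stack(stack, AnalysisConfig(seg_channel="pcna"))
    res_h = analyze_stack(stack, AnalysisConfig(seg_channel="chromatin"))

    map_p = _first_generation_map(res_p, truth)
    map_h = _first_generation_map(res_h, truth)
    dt = stack.dt_hours

    # --- per-founder G1/S estimates from both segmentation routes
    g1s_diffs_h: list[float] = []
    per_cell: dict[int, dict] = {}
    for cell in sorted(set(map_p) & set(map_h)):
        ap = res_p.annotations[map_p[cell]]
        ah = res_h.annotations[map_h[cell]]
        rec = {"track_pcna": map_p[cell], "track_chromatin": map_h[cell],
               "g1s_pcna": ap.g1s_frame, "g1s_chromatin": ah.g1s_frame}
        per_cell[cell] = rec
        if ap.g1s_frame is not None and ah.g1s_frame is not None:
            rec["g1s_diff_h"] = abs(ap.g1s_frame - ah.g1s_frame) * dt
            g1s_diffs_h.append(rec["g1s_diff_h"])

    # --- co-reporter quantification deviation between the two mask sets
    reporter = next((n for n in stack.channel_names
                     if n not in ("pcna", "chromatin")), None)
    rel_dev_pct: list[float] = []
    if reporter is not None:
        ser_p = res_p.reporter_series[reporter]
        ser_h = res_h.reporter_series[reporter]
        for cell, rec in per_cell.items():
            tp, th = rec["track_pcna"], rec["track_chromatin"]
            if rec.get("g1s_chromatin") is None:
                continue
            trp, trh = res_p.tracks[tp], res_h.tracks[th]
            onset = rec["g1s_chromatin"]
            lo = max(trp.start, trh.start, onset)
            hi = min(trp.end, trh.end)
            for f in range(lo, hi + 1):
                a = ser_p[tp][f - trp.start]
                b = ser_h[th][f - trh.start]
                if np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0:
                    rel_dev_pct.append(100.0 * abs(a - b) / b)

    # --- plateau fold change (PCNA route)
    k3 = max(1, int(round(3.0 / dt)))
    fold_ratios: list[float] = []
    for cell, tid in map_p.items():
        ann = res_p.annotations[tid]
        fs = res_p.features[tid]
        if ann.g1s_frame is None or ann.nebd_frame is None:
            continue
        tr = res_p.tracks[tid]
        birth_i = 0
        nebd_i = ann.nebd_frame - tr.start
        init = fs.nuclear_mean[birth_i:birth_i + k3]
        plateau = fs.nuclear_mean[max(0, nebd_i - k3):nebd_i]
        if np.isfinite(init).sum() < 2 or np.isfinite(plateau).sum() < 2:
            continue
        fold_ratios.append(float(np.nanmean(plateau) / np.nanmean(init)))

    # --- co-reporter onset lag vs PCNA onset (same changepoint rule)
    lags_min: list[float] = []
    if reporter is not None:
        for cell, tid in map_p.items():
            ann = res_p.annotations[tid]
            if ann.g1s_frame is None:
                continue
            fs = res_p.features[tid]
            sig = res_p.reporter_series[reporter][tid]
            onset, _flag = detect_g1s(fs, ann.birth_frame, res_p.config.phase,
                                      signal=sig)
            if onset is not None:
                lags_min.append((onset - ann.g1s_frame) * dt * 60.0)

    # --- tracking quality on the PCNA route
    _assignment, purity = match_tracks_to_truth(res_p, truth)
    n_true_div = int(truth.n_divisions)
    recovered = 0
    track_to_cell, _ = match_tracks_to_truth(res_p, truth)
    true_daughters = {tuple(sorted(v)) for v in truth.lineage.values()}
    for mother, _f, da, db in res_p.lineage.divisions:
        pair = tuple(sorted((track_to_cell.get(da, -1), track_to_cell.get(db, -1))))
        if pair in true_daughters:
            recovered += 1

    return {
        "params": params,
        "stack": stack,
        "truth": truth,
        "result_pcna": res_p,
        "result_chromatin": res_h,
        "per_cell": per_cell,
        "n_founders_compared": len(g1s_diffs_h),
        "g1s_diffs_h": np.asarray(g1s_diffs_h),
        "max_g1s_diff_h": float(np.max(g1s_diffs_h)) if g1s_diffs_h else np.nan,
        "rel_dev_pct": np.asarray(rel_dev_pct),
        "p90_rel_dev_pct": (float(np.percentile(rel_dev_pct, 90))
                            if rel_dev_pct else np.nan),
        "fold_ratios": np.asarray(fold_ratios),
        "mean_fold_ratio": float(np.mean(fold_ratios)) if fold_ratios else np.nan,
        "onset_lags_min": np.asarray(lags_min),
        "median_onset_lag_min": float(np.median(lags_min)) if lags_min else np.nan,
        "track_purity": purity,
        "min_track_purity": float(min(purity.values())) if purity else np.nan,
        "n_true_divisions": n_true_div,
        "n_recovered_divisions": recovered,
    }


def acceptance_targets(seed: int, n_cells: int = 50) -> dict[str, dict]:
    """The four headline pipeline-accuracy numbers, computed from scratch."""
    bench = run_paired_benchmark(seed, n_cells=n_cells)
    return {
        "t1": {"value": round(bench["max_g1s_diff_h"], 4),
               "n": int(bench["n_founders_compared"])},
        "t2": {"value": round(bench["p90_rel_dev_pct"], 3),
               "n": int(len(bench["rel_dev_pct"]))},
        "t3": {"value": round(bench["mean_fold_ratio"], 4),
               "n": int(len(bench["fold_ratios"]))},
        "t4": {"value": round(bench["median_onset_lag_min"], 2),
               "n": int(len(bench["onset_lags_min"]))},
    }
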