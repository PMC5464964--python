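"""Shared fixtures: small ground-truthed movies analysed once per session."""

import numpy as np
import pytest

from pcnacycle import AnalysisConfig, SimulationParams, analyze_stack, simulate_movie
from pcnacycle.pipeline import match_tracks_to_truth


@pytest.fixture(scope="session")
def small_movie():
    """Five proliferating cells, default conditions, full cycles."""
    params = SimulationParams(n_cells=5, seed=11)
    stack, truth = simulate_movie(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def small_analysis(small_movie):
    _params, stack, truth = small_movie
    result = analyze_stack(stack)
    assignment, purity = match_tracks_to_truth(result, truth)
    return result, assignment, purity


@pytest.fixture(scope="session")
def starvation_movie():
    """Serum-starvation mode: no S entry, exponential PCNA decline."""
    params = SimulationParams(n_cells=6, seed=7, starvation=True,
                              n_frames=170)  # ~28 h at 10-min frames
    stack, truth = simulate_movie(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def starvation_analysis(starvation_movie):
    _params, stack, _truth = starvation_movie
    return analyze_stack(stack)


def truth_track_pairs(result, truth):
    """(true cell id -> track id) for founder cells born at frame 0."""
    assignment, _ = match_tracks_to_truth(result, truth)
    founders = set(truth.events.loc[truth.events.parent.isna(), "cell"].astype(int))
    out = {}
    for tid, cell in assignment.items():
        if cell in founders and result.tracks[tid].start == 0:
            if cell not in out or len(result.tracks[tid]) > len(result.tracks[out[cell]]):
                out[cell] = tid
    return out
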