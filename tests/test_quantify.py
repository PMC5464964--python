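"""Compartment extraction, calibration, population and single-cell statistics."""

import numpy as np
import pytest

from pcnacycle.quantify import (CalibrationConfig, RingParams, _rings,
                                classify_cyclinD1_class,
                                correct_for_tagged_fraction,
                                detect_decrease_onset,
                                extract_compartment_intensities,
                                population_summary, sister_statistics,
                                slope_at, standardize_intensity)
from pcnacycle.track import CellTrack, Lineage


def _disk_labels(shape, centers, radius):
    labels = np.zeros(shape, np.int32)
    rr, cc = np.mgrid[:shape[0], :shape[1]]
    for i, (r, c) in enumerate(centers, start=1):
        labels[(rr - r) ** 2 + (cc - c) ** 2 <= radius ** 2] = i
    return labels


class TestCompartmentExtraction:
    def test_programmed_levels_recovered(self):
        rng = np.random.default_rng(0)
        shape, noise_sd = (96, 96), 2.0
        labels = _disk_labels(shape, [(48, 48)], 12)
        rr, cc = np.mgrid[:shape[0], :shape[1]]
        cyto = ((rr - 48) ** 2 + (cc - 48) ** 2 <= 24 ** 2) & (labels == 0)
        a, b, bg = 80.0, 30.0, 10.0
        raster = np.full(shape, bg) + rng.normal(0, noise_sd, shape)
        raster[labels == 1] += a
        raster[cyto] += b
        nuc, cyt = extract_compartment_intensities(raster, labels, 1)
        assert abs(nuc - a) <= 2 * noise_sd
        assert abs(cyt - b) <= 2 * noise_sd

    def test_background_only_channel_near_zero(self):
        labels = _disk_labels((64, 64), [(32, 32)], 10)
        # noise-free: exactly zero after background subtraction
        nuc, cyt = extract_compartment_intensities(np.full((64, 64), 10.0),
                                                   labels, 1)
        assert nuc == pytest.approx(0.0, abs=1e-9)
        assert cyt == pytest.approx(0.0, abs=1e-9)
        # with noise the 5th-percentile background estimate sits ~1.6 sd
        # below the true level, bounding the residual means accordingly
        rng = np.random.default_rng(1)
        sd = 1.5
        raster = 10 + rng.normal(0, sd, (64, 64))
        nuc, cyt = extract_compartment_intensities(raster, labels, 1)
        assert abs(nuc) < 2.2 * sd and abs(cyt) < 2.2 * sd

    def test_adjacent_cells_rings_exclusive(self):
        labels = _disk_labels((80, 80), [(40, 30), (40, 52)], 10)
        rings, count = _rings(labels, RingParams())
        assert not (rings[1] & (labels > 0)).any()
        assert not (rings[2] & (labels > 0)).any()
        assert not (rings[1] & rings[2]).any()  # contested pixels dropped
        assert (count > 1).any()  # the geometry does produce contested pixels

    def test_missing_label_raises(self):
        labels = _disk_labels((32, 32), [(16, 16)], 6)
        with pytest.raises(ValueError, match="label 5"):
            extract_compartment_intensities(np.ones((32, 32)), labels, 5)


class TestCalibration:
    @pytest.mark.parametrize("intensity,f,expected", [
        (3.0, 0.30, 10.0),    # cyclin B1: 30% of the total pool
        (73.0, 0.73, 100.0),  # cyclin D1: 73% of the total pool
        (42.0, 1.0, 42.0),
    ])
    def test_tagged_fraction_correction(self, intensity, f, expected):
        assert correct_for_tagged_fraction(intensity, f) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_invalid_fraction_rejected(self, bad):
        with pytest.raises(ValueError):
            correct_for_tagged_fraction(1.0, bad)

    def test_standardization_linearity_and_exposure(self):
        calib = CalibrationConfig(reference_exposure=100.0, fluorophore_factor=1.0)
        assert standardize_intensity(5.0, 100.0, calib) == pytest.approx(5.0)
        assert standardize_intensity(5.0, 50.0, calib) == pytest.approx(10.0)
        s = lambda v: standardize_intensity(v, 80.0, calib)
        assert s(2.0) + s(3.0) == pytest.approx(s(5.0))
        with pytest.raises(ValueError):
            standardize_intensity(1.0, 0.0, calib)

    def test_correction_never_decreases(self):
        for f in (0.1, 0.5, 0.99, 1.0):
            assert correct_for_tagged_fraction(7.0, f) >= 7.0


class TestPopulationSummary:
    def test_identical_tracks_zero_band(self):
        curve = np.sin(np.linspace(0, 3, 40))
        mat = np.tile(curve, (5, 1))
        s = population_summary(mat, np.arange(40) / 6)
        assert np.allclose(s.mean, curve)
        assert np.allclose(s.lower, curve) and np.allclose(s.upper, curve)

    def test_band_contains_95_percent(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(400, 30))
        s = population_summary(mat, np.arange(30))
        outside = (mat < s.lower) | (mat > s.upper)
        # 5% by construction plus discreteness allowance
        assert outside.mean() <= 0.05 + 0.01
        assert (s.lower <= s.mean).all() and (s.mean <= s.upper).all()

    def test_mean_matches_bruteforce_column_mean(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(7, 12))
        mat[2, 4] = np.nan
        s = population_summary(mat, np.arange(12))
        for j in range(12):
            col = mat[:, j]
            expected = np.mean(col[np.isfinite(col)])
            assert s.mean[j] == pytest.approx(expected)


class TestSingleTrackStatistics:
    def test_decrease_onset_recovered(self):
        rng = np.random.default_rng(4)
        for bp in (25, 40):
            y = np.r_[np.linspace(50, 80, bp), np.linspace(80, 30, 60 - bp)]
            y = y + rng.normal(0, 0.3, 60)
            est = detect_decrease_onset(y, birth_index=0)
            assert est is not None and abs(est - bp) <= 2
            assert detect_decrease_onset(y * 7.7, 0) == est  # scale invariant

    def test_monotone_increase_has_no_onset(self):
        assert detect_decrease_onset(np.linspace(1, 9, 50), 0) is None

    def test_slope_exact_cases(self):
        dt = 1 / 6
        assert slope_at(np.full(20, 3.0), 10, dt_hours=dt) == pytest.approx(0.0)
        t = np.arange(30) * dt
        assert slope_at(4.2 * t, 15, dt_hours=dt) == pytest.approx(4.2)
        assert slope_at(np.array([1.0, 2.0]), 0, dt_hours=dt) is None

    def test_cyclin_d1_classes(self):
        down = np.linspace(100, 60, 40)
        assert classify_cyclinD1_class(down, 0, 39) == 1
        updown = np.r_[np.linspace(60, 100, 20), np.linspace(100, 70, 20)]
        assert classify_cyclinD1_class(updown, 0, 39) == 2
        # an exactly constant series shows no decrease: class II by tie-break
        assert classify_cyclinD1_class(np.full(40, 80.0), 0, 39) == 2
        assert classify_cyclinD1_class(down, 0, 2) is None  # span too short


class TestSisterStatistics:
    def _lineage(self, n_pairs):
        tracks = {}
        divisions = []
        tid = 1
        for i in range(n_pairs):
            mother = CellTrack(tid); tid += 1
            da = CellTrack(tid); tid += 1
            db = CellTrack(tid); tid += 1
            tracks.update({mother.track_id: mother, da.track_id: da,
                           db.track_id: db})
            divisions.append((mother.track_id, 10, da.track_id, db.track_id))
        return Lineage(tracks=tracks, divisions=divisions)

    def test_identical_sister_levels_give_rho_one(self):
        lineage = self._lineage(6)
        rng = np.random.default_rng(5)
        levels, births, g1, cls = {}, {}, {}, {}
        for i, (_m, _f, da, db) in enumerate(lineage.divisions):
            shared = float(rng.uniform(50, 150))
            for d in (da, db):
                levels[d] = np.full(30, shared)
                births[d] = 0
                g1[d] = float(rng.uniform(4, 12))
                cls[d] = 1 if i % 2 else 2
        out = sister_statistics(lineage, levels, births, g1, cls,
                                dt_hours=1 / 6)
        assert out["n_pairs"] == 6
        assert out["spearman_rho"] == pytest.approx(1.0)
        assert out["class_concordance"] == 1.0
        assert out["g1_mannwhitney_p"] is not None

    def test_too_few_pairs_rho_missing(self):
        lineage = self._lineage(2)
        levels = {d: np.full(30, 1.0) for _m, _f, da, db in lineage.divisions
                  for d in (da, db)}
        out = sister_statistics(lineage, levels, {d: 0 for d in levels},
                                {}, {}, dt_hours=1 / 6)
        assert out["spearman_rho"] is None
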