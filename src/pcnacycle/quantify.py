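"""Quantitative nuclear/cytoplasmic reporter extraction and statistics.

Fluorescence of a tagged allele is converted to a total-protein
estimate by dividing by the tagged-allele fraction determined by
quantitative western blotting (e.g. a cyclin B1 fusion carrying 30% of
the total pool is corrected by 1/0.30), and standardized across
exposure times against a purified-fluorophore reference so that
different reporter lines can be compared on one scale.

Cytoplasmic signal is measured in an annulus around each nucleus,
excluding every nucleus and every other cell's annulus (contested
pixels are dropped — conservative and deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phases import running_median
from .stats import mann_whitney_u, spearman_rho
from .track import Lineage

__all__ = [
    "CalibrationConfig", "PopulationSummary", "RingParams",
    "extract_compartment_intensities", "extract_all_compartments",
    "correct_for_tagged_fraction", "standardize_intensity",
    "population_summary", "detect_decrease_onset", "slope_at",
    "classify_cyclinD1_class", "sister_statistics",
]

#: Tagged-allele fractions from quantitative western blotting: the
#: cyclin A2 fusion is expressed at a level similar to the untagged
#: allele, cyclin B1-mVenus carries 30% of the total pool and cyclin
#: D1-mVenus 73%.
DEFAULT_TAGGED_FRACTIONS = {
    "cyclin_a2": 0.5,
    "cyclin_b1": 0.30,
    "cyclin_d1": 0.73,
}


@dataclass(frozen=True)
class CalibrationConfig:
    """Fluorescence-to-total-protein calibration."""

    tagged_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TAGGED_FRACTIONS))
    reference_exposure: float = 100.0  # ms
    fluorophore_factor: float = 1.0  # AFU per standard unit

    def __post_init__(self) -> None:
        for name, f in self.tagged_fraction.items():
            if not (0 < f <= 1):
                raise ValueError(f"tagged_fraction[{name!r}] must be in (0, 1]")
        if self.reference_exposure <= 0:
            raise ValueError("reference_exposure must be positive")


@dataclass(frozen=True)
class RingParams:
    """Cytoplasmic ring geometry (pixels beyond the nucleus edge)."""

    r_inner: int = 2
    r_outer: int = 6
    background_percentile: float = 5.0

    def __post_init__(self) -> None:
        if not (0 <= self.r_inner < self.r_outer):
            raise ValueError("need 0 <= r_inner < r_outer")


@dataclass
class PopulationSummary:
    """Mean curve with a 95%-of-values percentile band."""

    time_h: np.ndarray
    mean: np.ndarray
    lower: np.ndarray  # 2.5th percentile
    upper: np.ndarray  # 97.5th percentile
    n: np.ndarray


# ---------------------------------------------------------------------------
# compartment extraction
# ---------------------------------------------------------------------------

def _rings(labelmap: np.ndarray, params: RingParams,
           ) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Exclusive cytoplasmic rings per label (contested pixels dropped)."""
    ids = np.unique(labelmap)
    ids = ids[ids > 0]
    any_nucleus = labelmap > 0
    count = np.zeros(labelmap.shape, dtype=np.int16)
    raw: dict[int, np.ndarray] = {}
    for lab in ids:
        mask = labelmap == lab
        dist = ndimage.distance_transform_edt(~mask)
        ring = (dist > params.r_inner) & (dist <= params.r_outer) & ~any_nucleus
        raw[int(lab)] = ring
        count += ring
    rings = {lab: ring & (count == 1) for lab, ring in raw.items()}
    return rings, count


def extract_all_compartments(raster: np.ndarray, labelmap: np.ndarray,
                             params: RingParams = RingParams(),
                             ) -> dict[int, tuple[float, float | None]]:
    """Background-subtracted (nuclear, cytoplasmic) means for every label.

    The background is the ``background_percentile`` of pixels outside
    all nuclei and all rings; a label whose exclusive ring is empty gets
    a missing (None) cytoplasmic value.
    """
    raster = np.asarray(raster, dtype=float)
    labelmap = np.asarray(labelmap)
    rings, count = _rings(labelmap, params)
    outside = (labelmap == 0) & (count == 0)
    bg = float(np.percentile(raster[outside], params.background_percentile)) \
        if outside.any() else 0.0
    out: dict[int, tuple[float, float | None]] = {}
    for lab, ring in rings.items():
        nuc = float(raster[labelmap == lab].mean()) - bg
        cyto = float(raster[ring].mean()) - bg if ring.any() else None
        out[lab] = (nuc, cyto)
    return out


def extract_compartment_intensities(raster: np.ndarray, labelmap: np.ndarray,
                                    cell_label: int,
                                    params: RingParams = RingParams(),
                                    ) -> tuple[float, float | None]:
    """(nuclear_mean, cytoplasmic_mean) for one cell; see module docs."""
    if not (np.asarray(labelmap) == cell_label).any():
        raise ValueError(f"label {cell_label} not present in labelmap")
    return extract_all_compartments(raster, labelmap, params)[int(cell_label)]


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def correct_for_tagged_fraction(intensity: float, f: float) -> float:
    """Scale a tagged-allele intensity to a total-protein estimate (/f)."""
    if not (0 < f <= 1):
        raise ValueError("tagged fraction must be in (0, 1]")
    return intensity / f


def standardize_intensity(intensity: float, exposure: float,
                          calib: CalibrationConfig) -> float:
    """Exposure-normalized, fluorophore-standardized intensity.

    ``intensity * (reference_exposure / exposure) / fluorophore_factor``:
    linear in the intensity and inversely proportional to the exposure.
    """
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    return intensity * (calib.reference_exposure / exposure) / calib.fluorophore_factor


# ---------------------------------------------------------------------------
# population and single-track statistics
# ---------------------------------------------------------------------------

def population_summary(matrix: np.ndarray, time_h: np.ndarray,
                       ) -> PopulationSummary:
    """Per-time mean and [2.5th, 97.5th] percentile band over tracks."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need an aligned matrix with >= 2 tracks")
    n = np.sum(np.isfinite(matrix), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nanmean(matrix, axis=0), np.nan)
        lower = np.where(n > 0, np.nanpercentile(matrix, 2.5, axis=0), np.nan)
        upper = np.where(n > 0, np.nanpercentile(matrix, 97.5, axis=0), np.nan)
    return PopulationSummary(time_h=np.asarray(time_h), mean=mean,
                             lower=lower, upper=upper, n=n)


def detect_decrease_onset(series: np.ndarray, birth_index: int = 0,
                          m: int = 3, smooth_window: int = 3) -> int | None:
    """Start of the first run of >= m negative smoothed first differences."""
    sm = running_median(np.asarray(series, dtype=float), smooth_window)
    diff = np.diff(sm)
    run = 0
    for i in range(birth_index, len(diff)):
        if np.isfinite(diff[i]) and diff[i] < 0:
            run += 1
            if run >= m:
                return i - m + 1
        else:
            run = 0
    return None


def slope_at(series: np.ndarray, t_index: int, window: int = 5,
             dt_hours: float = 1.0) -> float | None:
    """Least-squares slope (AFU/hour) over a window centred on t_index."""
    series = np.asarray(series, dtype=float)
    half = window // 2
    lo = max(0, t_index - half)
    hi = min(len(series), t_index + half + 1)
    t = np.arange(lo, hi) * dt_hours
    y = series[lo:hi]
    good = np.isfinite(y)
    if good.sum() < 3:
        return None
    coef = np.polyfit(t[good], y[good], 1)
    return float(coef[0])


def classify_cyclinD1_class(series: np.ndarray, birth_index: int,
                            g1s_index: int | None, tau_frac: float = 0.02,
                            smooth_window: int = 3) -> int | None:
    """Class I/II call from G1-phase nuclear cyclin D1 kinetics.

    Class I: the smoothed series decreases continuously from birth to
    the G1/S transition — every step change <= +tau (tau = ``tau_frac``
    of the birth level) AND a net decrease larger than tau over the
    span. Anything else (including an exactly constant series, which
    shows no decrease) is class II. Returns 1, 2 or None (G1 span too
    short to classify).
    """
    sm = running_median(np.asarray(series, dtype=float), smooth_window)
    end = g1s_index if g1s_index is not None else len(sm)
    seg = sm[birth_index:end]
    seg = seg[np.isfinite(seg)]
    if len(seg) < 3:
        return None
    tau = tau_frac * abs(seg[0])
    steps_ok = bool(np.all(np.diff(seg) <= tau))
    net_decrease = seg[-1] < seg[0] - tau
    return 1 if (steps_ok and net_decrease) else 2


def sister_statistics(lineage: Lineage,
                      level_series: dict[int, np.ndarray],
                      birth_index: dict[int, int],
                      g1_length_h: dict[int, float],
                      d1_class: dict[int, int | None],
                      initial_window_h: float = 1.0,
                      dt_hours: float = 1.0) -> dict:
    """Sister-cell inheritance and G1-length statistics.

    For every division with both daughters tracked, the initial reporter
    level is the mean over the first ``initial_window_h`` hours after
    birth. Summaries: Spearman's rho of sister initial levels (missing
    when < 3 pairs), the fraction of class-concordant pairs, and a
    two-sided Mann-Whitney U comparing G1 lengths between class I and
    class II daughters.
    """
    k = max(1, int(round(initial_window_h / dt_hours)))
    pairs = []
    for mother, _frame, da, db in lineage.divisions:
        row = {"mother": mother, "daughter_a": da, "daughter_b": db}
        ok = True
        for tag, d in (("a", da), ("b", db)):
            s = level_series.get(d)
            b = birth_index.get(d, 0)
            if s is None or len(s) - b < k:
                ok = False
                break
            row[f"initial_{tag}"] = float(np.nanmean(s[b:b + k]))
            row[f"g1_len_{tag}"] = g1_length_h.get(d, np.nan)
            row[f"class_{tag}"] = d1_class.get(d)
        if ok:
            pairs.append(row)

    out: dict = {"pairs": pairs, "n_pairs": len(pairs)}
    if len(pairs) >= 3:
        a = [p["initial_a"] for p in pairs]
        b = [p["initial_b"] for p in pairs]
        out["spearman_rho"] = spearman_rho(a, b)
    else:
        out["spearman_rho"] = None
    classed = [p for p in pairs
               if p.get("class_a") is not None and p.get("class_b") is not None]
    out["class_concordance"] = (
        sum(p["class_a"] == p["class_b"] for p in classed) / len(classed)
        if classed else None)
    g1_by_class: dict[int, list[float]] = {1: [], 2: []}
    for p in pairs:
        for tag in ("a", "b"):
            c, g = p.get(f"class_{tag}"), p.get(f"g1_len_{tag}")
            if c in (1, 2) and np.isfinite(g):
                g1_by_class[c].append(g)
    if g1_by_class[1] and g1_by_class[2]:
        u, pval = mann_whitney_u(g1_by_class[1], g1_by_class[2])
        out["g1_mannwhitney_u"] = u
        out["g1_mannwhitney_p"] = pval
    else:
        out["g1_mannwhitney_u"] = out["g1_mannwhitney_p"] = None
    return out
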