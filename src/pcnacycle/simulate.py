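"""Synthetic PCNA time-lapse movies with full ground truth.

Generates 2-D multi-channel movies that emulate the dynamics of an
endogenously tagged PCNA reporter in proliferating epithelial cells:

* nuclear PCNA stays at a low baseline through G1, ramps linearly during
  S phase to a plateau ~2-fold above the baseline, and holds through G2;
* punctate replication foci appear at S entry and become larger and
  brighter toward the end of S, raising the within-nucleus intensity
  spread (the "distribution width" used downstream as an S/G2 marker);
* at nuclear envelope breakdown (NEBD) the nuclear signal redistributes
  over a larger cytoplasmic footprint, dropping the nuclear mean
  abruptly, after which the cell divides into two daughters;
* a chromatin (histone-like) channel is constant through interphase and
  condenses during mitosis (smaller, brighter region inside the nucleus,
  strongly increasing the within-nucleus pixel spread);
* optional co-reporter channels (cyclin A2-like, geminin-like, cyclin
  D1-like) switch on with a programmed delay relative to the PCNA ramp
  onset or follow G1-peaked kinetics;
* in starvation mode no cell enters S phase and nuclear PCNA decays
  exponentially toward quiescence over ~48 h.

Every movie comes with exhaustive ground truth: per-frame label maps,
the lineage forest, per-cell event times, and the programmed per-channel
nuclear/cytoplasmic levels, so that segmentation, tracking, phase
classification and quantification can all be validated without any
external data.

Times are handled in hours internally; the frame interval is given in
minutes and converted in one place (:func:`SimulationParams.dt_hours`).
Pixel coordinates are 0-based ``(row, col)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellProgram",
    "CoReporterSpec",
    "FrameStack",
    "GroundTruth",
    "NoiseModel",
    "SimulationError",
    "SimulationParams",
    "build_cell_program",
    "render_frame",
    "simulate_movie",
]


class SimulationError(ValueError):
    """Raised for invalid simulation parameters or failed placements."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian plus scaled-Poisson shot noise.

    A rendered pixel with clean value ``I`` is reported as
    ``Poisson(I * poisson_scale) / poisson_scale + N(0, gaussian_sd)``.
    Setting both parameters to 0 disables noise entirely.
    """

    gaussian_sd: float = 2.0
    poisson_scale: float = 1.0

    @property
    def enabled(self) -> bool:
        return self.gaussian_sd > 0 or self.poisson_scale > 0


@dataclass(frozen=True)
class CoReporterSpec:
    """Declarative description of one co-imaged reporter channel.

    profile
        ``"s_onset_ramp"`` — off until ``onset_offset_min`` minutes after
        the PCNA ramp onset (S entry), then a linear rise over
        ``rise_duration_h`` to ``plateau`` and a hold until NEBD
        (cyclin A2 / geminin-like behaviour; degraded at mitosis).
        ``"g1_peak"`` — cyclin D1-like: rises from an inherited initial
        level early in G1, then decreases around S entry and recovers;
        14% of cells instead decrease continuously from birth (class I),
        and class I cells have proportionally shorter G1 phases.
        ``"constant"`` — flat nuclear and cytoplasmic levels (useful for
        extraction tests).
    """

    name: str = "cyclin_a2"
    profile: str = "s_onset_ramp"
    onset_offset_min: float = 45.0
    rise_duration_h: float = 10.0
    plateau: float = 120.0
    cyto_level: float = 20.0


DEFAULT_COREPORTERS: tuple[CoReporterSpec, ...] = (CoReporterSpec(),)

#: Canonical onset delays (minutes after the PCNA ramp onset) for the two
#: reference S-phase reporters emulated by the generator.
COREPORTER_ONSET_OFFSETS_MIN = {"cyclin_a2": 45.0, "hgem": 16.0}


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic movie.

    Defaults describe an unperturbed proliferating population imaged at
    10-min intervals: G1 ~ TruncNormal(7.7 h, 3.0 h) with a 1 h floor,
    S fixed at 10 h (the duration of the PCNA expression ramp), G2 fixed
    at 4 h, mitosis 0.5 h, and a 2-fold PCNA plateau.
    """

    n_cells: int = 10
    n_frames: int | None = None  # None -> span all first-generation divisions
    frame_interval: float = 10.0  # minutes
    image_size: tuple[int, int] | None = None  # (rows, cols); None -> auto
    nucleus_radius: tuple[float, float] = (14.0, 1.2)  # mean, sd in px
    background_level: float = 10.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    motion_sd: float = 0.5  # px / frame random walk (~3 um/h at 10-min frames)
    g1_mean: float = 7.7
    g1_sd: float = 3.0
    g1_floor: float = 1.0
    s_duration: float = 10.0
    g2_duration: float = 4.0
    m_duration: float = 0.5
    pcna_base: float = 100.0
    pcna_base_cv: float = 0.08  # cell-to-cell baseline variability
    pcna_plateau_fold: float = 2.0
    chromatin_level: float = 120.0
    include_chromatin: bool = True
    coreporters: tuple[CoReporterSpec, ...] = DEFAULT_COREPORTERS
    starvation: bool = False
    decline_halftime: float = 16.0  # hours, quiescence mode
    decline_onset_range: tuple[float, float] = (1.0, 3.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise SimulationError("n_cells must be non-negative")
        if self.frame_interval <= 0:
            raise SimulationError("frame_interval must be positive")
        if self.g1_mean <= 0 or self.g1_sd < 0:
            raise SimulationError("G1 distribution parameters must be positive")
        if min(self.s_duration, self.g2_duration, self.m_duration) <= 0:
            raise SimulationError("phase durations must be positive")
        if self.pcna_plateau_fold < 1:
            raise SimulationError("pcna_plateau_fold must be >= 1")

    @property
    def dt_hours(self) -> float:
        return self.frame_interval / 60.0

    @property
    def channel_names(self) -> list[str]:
        names = ["pcna"]
        if self.include_chromatin:
            names.append("chromatin")
        names.extend(spec.name for spec in self.coreporters)
        return names


# ---------------------------------------------------------------------------
# per-cell programs
# ---------------------------------------------------------------------------

@dataclass
class CellProgram:
    """Deterministic dynamics of one simulated cell.

    All times are absolute hours from movie start. ``ramp_start_offset``
    (hours after birth) coincides with the G1/S transition; the ramp runs
    for ``ramp_duration`` hours up to ``pcna_plateau_fold`` times the
    baseline. ``foci_schedule`` is a list of ``(time_h, count, sigma_px,
    amplitude)`` entries spanning exactly the S interval with count,
    size and amplitude non-decreasing in time.
    """

    cell_id: int
    birth_time: float
    g1_duration: float
    s_duration: float
    g2_duration: float
    m_duration: float
    pcna_base: float
    pcna_plateau_fold: float = 2.0
    ramp_start_offset: float | None = None  # hours after birth; default = G1
    ramp_duration: float | None = None  # hours; default = S duration
    quiescent: bool = False
    decline_halftime: float = 16.0
    decline_onset: float = 2.0  # hours after birth (quiescence mode)
    chromatin_level: float = 120.0
    # geometry
    center: tuple[float, float] = (0.0, 0.0)  # (row, col) at birth
    axes: tuple[float, float] = (14.0, 12.0)  # semi-axes, px
    angle: float = 0.0  # radians
    path: np.ndarray | None = None  # (n_frames, 2) absolute positions
    foci_schedule: list[tuple[float, int, float, float]] = field(default_factory=list)
    foci_positions: np.ndarray | None = None  # (max_foci, 2) unit-disk coords
    coreporter_programs: dict[str, dict] = field(default_factory=dict)
    parent: int | None = None

    def __post_init__(self) -> None:
        if self.ramp_start_offset is None:
            self.ramp_start_offset = self.g1_duration
        if self.ramp_duration is None:
            self.ramp_duration = self.s_duration
        self._validate()

    def _validate(self) -> None:
        if min(self.g1_duration, self.s_duration, self.g2_duration, self.m_duration) <= 0:
            raise SimulationError("all phase durations must be positive")
        if self.pcna_plateau_fold < 1:
            raise SimulationError("pcna_plateau_fold must be >= 1")
        if self.pcna_base <= 0:
            raise SimulationError("pcna_base must be positive")
        if not self.quiescent:
            if not (self.birth_time < self.ramp_onset_time < self.nebd_time < self.division_time):
                raise SimulationError("event times must be strictly ordered")

    # -- event times -------------------------------------------------------
    @property
    def ramp_onset_time(self) -> float:
        """Absolute time of the PCNA expression onset (= S entry)."""
        return self.birth_time + self.ramp_start_offset

    @property
    def s_begin_time(self) -> float:
        return self.birth_time + self.g1_duration

    @property
    def s_end_time(self) -> float:
        return self.s_begin_time + self.s_duration

    @property
    def nebd_time(self) -> float:
        return self.birth_time + self.g1_duration + self.s_duration + self.g2_duration

    @property
    def division_time(self) -> float:
        return self.nebd_time + self.m_duration

    def position_at(self, frame: int) -> tuple[float, float]:
        if self.path is None:
            return self.center
        idx = min(max(frame, 0), len(self.path) - 1)
        return tuple(self.path[idx])

    # -- programmed intensity levels ---------------------------------------
    def pcna_level(self, t: float) -> float:
        """Diffuse nuclear PCNA level at absolute time ``t`` (AFU, no foci)."""
        if self.quiescent:
            onset = self.birth_time + self.decline_onset
            if t < onset:
                return self.pcna_base
            return self.pcna_base * 0.5 ** ((t - onset) / self.decline_halftime)
        rel = t - self.ramp_onset_time
        top = self.pcna_base * self.pcna_plateau_fold
        if t >= self.nebd_time:
            return 0.4 * top  # redistributed over the mitotic footprint
        if rel < 0:
            return self.pcna_base
        if self.ramp_duration <= 0:
            return top
        if rel >= self.ramp_duration:
            return top
        frac = rel / self.ramp_duration
        return self.pcna_base * (1.0 + (self.pcna_plateau_fold - 1.0) * frac)

    def in_s_phase(self, t: float) -> bool:
        return (not self.quiescent) and self.s_begin_time <= t < self.s_end_time

    def in_mitosis(self, t: float) -> bool:
        return (not self.quiescent) and self.nebd_time <= t < self.division_time

    def foci_state(self, t: float) -> tuple[int, float, float]:
        """Foci (count, sigma_px, amplitude) active at time ``t``."""
        if not self.foci_schedule or not self.in_s_phase(t):
            return 0, 0.0, 0.0
        state = self.foci_schedule[0]
        for entry in self.foci_schedule:
            if entry[0] <= t:
                state = entry
            else:
                break
        return state[1], state[2], state[3]

    def coreporter_level(self, name: str, t: float) -> tuple[float, float]:
        """(nuclear, cytoplasmic) programmed level of a co-reporter at ``t``."""
        prog = self.coreporter_programs.get(name)
        if prog is None or self.quiescent:
            return 0.0, 0.0
        if self.in_mitosis(t) or t >= self.division_time:
            return 0.0, 0.0  # degraded / dispersed at mitosis
        profile = prog["profile"]
        if profile == "constant":
            return prog["plateau"], prog["cyto_level"]
        if profile == "s_onset_ramp":
            onset = self.ramp_onset_time + prog["onset_offset_min"] / 60.0
            rel = t - onset
            if rel < 0:
                nuc = 0.0
            elif prog["rise_duration_h"] <= 0 or rel >= prog["rise_duration_h"]:
                nuc = prog["plateau"]
            else:
                nuc = prog["plateau"] * rel / prog["rise_duration_h"]
            return nuc, prog["cyto_level"]
        if profile == "g1_peak":
            return self._d1_level(prog, t), prog["cyto_level"]
        raise SimulationError(f"unknown co-reporter profile {profile!r}")

    def _d1_level(self, prog: dict, t: float) -> float:
        """Cyclin D1-like nuclear kinetics (class I or II)."""
        L0 = prog["initial_level"]
        rel = t - self.birth_time
        if prog["d1_class"] == 1:  # continuous decrease since mitosis
            return L0 * math.exp(-rel / prog["decay_tau_h"])
        # class II: early-G1 rise, decrease at S entry, recovery in S/G2
        g1 = self.g1_duration
        peak_t, peak = 0.6 * g1, 1.5 * L0
        trough_t, trough = g1 + 2.0, 0.7 * L0
        if rel <= peak_t:
            return L0 + (peak - L0) * rel / max(peak_t, 1e-9)
        if rel <= trough_t:
            return peak + (trough - peak) * (rel - peak_t) / max(trough_t - peak_t, 1e-9)
        return min(peak, trough + 0.1 * L0 * (rel - trough_t))


# ---------------------------------------------------------------------------
# program construction
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      floor: float) -> float:
    if sd <= 0:
        return max(mean, floor)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= floor:
            return float(x)
    return floor


def _make_foci(prog_start: float, prog_end: float, base: float,
               frame_dt: float, rng: np.random.Generator,
               n_start: int = 5, n_end: int = 20,
               sigma_start: float = 1.0, sigma_end: float = 1.5,
               amp_start_frac: float = 0.3, amp_end_frac: float = 0.8,
               ) -> tuple[list[tuple[float, int, float, float]], np.ndarray]:
    """Foci schedule spanning exactly [prog_start, prog_end).

    Count, size and amplitude ramp up linearly: small dim foci early in
    S phase, larger and brighter foci toward its end.
    """
    n_steps = max(2, int(round((prog_end - prog_start) / max(frame_dt, 1e-6))))
    schedule = []
    for i in range(n_steps):
        frac = i / (n_steps - 1)
        schedule.append((
            prog_start + frac * (prog_end - prog_start),
            int(round(n_start + frac * (n_end - n_start))),
            sigma_start + frac * (sigma_end - sigma_start),
            base * (amp_start_frac + frac * (amp_end_frac - amp_start_frac)),
        ))
    # fixed positions in the unit disk (scaled to the nucleus at render time)
    r = np.sqrt(rng.uniform(0.0, 0.8 ** 2, size=n_end))
    theta = rng.uniform(0, 2 * np.pi, size=n_end)
    positions = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return schedule, positions


def build_cell_program(params: SimulationParams, rng: np.random.Generator,
                       *, cell_id: int = 1, birth_time: float = 0.0,
                       center: tuple[float, float] = (0.0, 0.0),
                       pcna_base: float | None = None,
                       parent: int | None = None,
                       d1_initial: float | None = None) -> CellProgram:
    """Draw one cell's program from the study-condition distributions.

    Phase durations: G1 ~ TruncNormal(g1_mean, g1_sd) with a ``g1_floor``
    floor; S and G2 fixed (the S duration equals the PCNA ramp duration).
    The foci schedule spans exactly the S interval with non-decreasing
    count, radius and amplitude.
    """
    params.validate()
    g1 = _truncated_normal(rng, params.g1_mean, params.g1_sd, params.g1_floor)
    if pcna_base is None:
        pcna_base = params.pcna_base * max(
            0.2, 1.0 + params.pcna_base_cv * rng.normal())
    r_mean, r_sd = params.nucleus_radius
    radius = max(4.0, rng.normal(r_mean, r_sd))
    ratio = rng.uniform(1.0, 1.3)
    axes = (radius * math.sqrt(ratio), radius / math.sqrt(ratio))
    angle = rng.uniform(0, np.pi)

    coreporter_programs: dict[str, dict] = {}
    for spec in params.coreporters:
        prog = {
            "profile": spec.profile,
            "onset_offset_min": spec.onset_offset_min,
            "rise_duration_h": spec.rise_duration_h,
            "plateau": spec.plateau,
            "cyto_level": spec.cyto_level,
        }
        if spec.profile == "g1_peak":
            is_class1 = rng.uniform() < 0.14
            prog["d1_class"] = 1 if is_class1 else 2
            if is_class1:
                g1 = max(params.g1_floor, 0.6 * g1)  # class I -> shorter G1
            prog["initial_level"] = (d1_initial if d1_initial is not None
                                     else spec.plateau * max(0.2, 1 + 0.3 * rng.normal()))
            prog["decay_tau_h"] = 6.0
        coreporter_programs[spec.name] = prog

    program = CellProgram(
        cell_id=cell_id,
        birth_time=birth_time,
        g1_duration=g1,
        s_duration=params.s_duration,
        g2_duration=params.g2_duration,
        m_duration=params.m_duration,
        pcna_base=float(pcna_base),
        pcna_plateau_fold=params.pcna_plateau_fold,
        quiescent=params.starvation,
        decline_halftime=params.decline_halftime,
        decline_onset=rng.uniform(*params.decline_onset_range),
        chromatin_level=params.chromatin_level,
        center=center,
        axes=axes,
        angle=angle,
        coreporter_programs=coreporter_programs,
        parent=parent,
    )
    schedule, positions = _make_foci(
        program.s_begin_time, program.s_end_time, program.pcna_base,
        params.dt_hours, rng)
    program.foci_schedule = schedule
    program.foci_positions = positions
    return program


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float], angle: float,
                  scale: float = 1.0) -> tuple[np.ndarray, tuple[int, int]]:
    """Boolean mask (cropped) of an ellipse; returns (mask, bbox origin).

    A pixel belongs to the ellipse when its center lies inside.
    """
    a, b = axes[0] * scale, axes[1] * scale
    r0, c0 = center
    rad = int(math.ceil(max(a, b))) + 1
    rmin = max(0, int(math.floor(r0)) - rad)
    rmax = min(shape[0], int(math.ceil(r0)) + rad + 1)
    cmin = max(0, int(math.floor(c0)) - rad)
    cmax = min(shape[1], int(math.ceil(c0)) + rad + 1)
    if rmin >= rmax or cmin >= cmax:
        return np.zeros((0, 0), bool), (0, 0)
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    dr, dc = rr - r0, cc - c0
    ca, sa = math.cos(angle), math.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask, (rmin, cmin)


def _paint(canvas: np.ndarray, mask: np.ndarray, origin: tuple[int, int],
           value: float | np.ndarray, add: bool = True) -> None:
    if mask.size == 0:
        return
    r0, c0 = origin
    view = canvas[r0:r0 + mask.shape[0], c0:c0 + mask.shape[1]]
    if add:
        if np.isscalar(value):
            view[mask] += value
        else:
            view[mask] += value[mask]
    else:
        view[mask] = value


def _render_foci(pcna: np.ndarray, program: CellProgram, t: float,
                 center: tuple[float, float], nucleus_mask: np.ndarray,
                 origin: tuple[int, int]) -> None:
    count, sigma, amp = program.foci_state(t)
    if count <= 0 or amp <= 0:
        return
    positions = program.foci_positions[:count]
    a, b = program.axes
    ca, sa = math.cos(program.angle), math.sin(program.angle)
    r0, c0 = origin
    h, w = nucleus_mask.shape
    rr, cc = np.mgrid[r0:r0 + h, c0:c0 + w]
    spot_sum = np.zeros((h, w), dtype=np.float64)
    for (ur, uc) in positions:
        # unit-disk coords -> ellipse frame -> image frame
        dr = ur * a * ca - uc * b * sa
        dc = ur * a * sa + uc * b * ca
        fr, fc = center[0] + dr, center[1] + dc
        d2 = (rr - fr) ** 2 + (cc - fc) ** 2
        spot_sum += amp * np.exp(-0.5 * d2 / sigma ** 2)
    spot_sum[~nucleus_mask] = 0.0  # foci live strictly inside the nucleus
    pcna[r0:r0 + h, c0:c0 + w] += spot_sum


def render_frame(programs: Sequence[CellProgram], t: float,
                 params: SimulationParams,
                 rng: np.random.Generator | None = None,
                 frame_index: int | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Render one multi-channel frame and its true label map.

    Returns ``(raster, labels)`` where ``raster`` has shape
    ``(n_channels, rows, cols)`` (channel order per
    :attr:`SimulationParams.channel_names`) and ``labels`` is uint16 with
    0 = background. Nuclei are filled ellipses; during mitosis the PCNA
    signal spreads over a 1.6x footprint at 40% of its pre-NEBD nuclear
    level while the chromatin channel condenses to a half-area core at
    twice its interphase level (the remaining nucleoplasm dims to 20%).
    Labels are assigned first-come on the (sorted) program list; a pixel
    belongs to exactly one label.
    """
    shape = params.image_size
    if shape is None:
        raise SimulationError("render_frame requires an explicit image_size")
    channels = params.channel_names
    raster = np.zeros((len(channels), *shape), dtype=np.float64)
    raster += params.background_level
    labels = np.zeros(shape, dtype=np.uint16)
    if frame_index is None:
        frame_index = int(round(t / params.dt_hours))

    pcna = raster[0]
    chrom = raster[channels.index("chromatin")] if "chromatin" in channels else None

    for program in programs:
        if t < program.birth_time - 1e-9:
            continue
        if (not program.quiescent) and t >= program.division_time - 1e-9:
            continue
        center = program.position_at(frame_index)
        mitotic = program.in_mitosis(t)
        nuc_mask, origin = _ellipse_mask(shape, center, program.axes, program.angle)
        if nuc_mask.size == 0:
            continue

        # --- true label: the nucleus ellipse, first-come disjoint
        r0, c0 = origin
        lab_view = labels[r0:r0 + nuc_mask.shape[0], c0:c0 + nuc_mask.shape[1]]
        free = nuc_mask & (lab_view == 0)
        lab_view[free] = program.cell_id

        # --- PCNA channel
        level = program.pcna_level(t)
        if mitotic:
            big_mask, big_origin = _ellipse_mask(
                shape, center, program.axes, program.angle, scale=1.6)
            _paint(pcna, big_mask, big_origin, level)
        else:
            _paint(pcna, nuc_mask, origin, level)
            _render_foci(pcna, program, t, center, nuc_mask, origin)

        # --- chromatin channel
        if chrom is not None:
            if mitotic:
                core_mask, core_origin = _ellipse_mask(
                    shape, center, program.axes, program.angle,
                    scale=math.sqrt(0.5))
                _paint(chrom, nuc_mask, origin, 0.2 * program.chromatin_level)
                _paint(chrom, core_mask, core_origin, 1.8 * program.chromatin_level)
            else:
                _paint(chrom, nuc_mask, origin, program.chromatin_level)

        # --- co-reporters: nuclear level + cytoplasmic annulus
        for spec in params.coreporters:
            ch = raster[channels.index(spec.name)]
            nuc_level, cyto_level = program.coreporter_level(spec.name, t)
            if nuc_level > 0:
                _paint(ch, nuc_mask, origin, nuc_level)
            if cyto_level > 0:
                cyto_mask, cyto_origin = _ellipse_mask(
                    shape, center, program.axes, program.angle, scale=2.0)
                # annulus = big footprint minus the nucleus
                cr0, cc0 = cyto_origin
                sub = np.zeros_like(cyto_mask)
                rr0, cc1 = r0 - cr0, c0 - cc0
                sub[rr0:rr0 + nuc_mask.shape[0], cc1:cc1 + nuc_mask.shape[1]] = nuc_mask
                _paint(ch, cyto_mask & ~sub, cyto_origin, cyto_level)

    if rng is not None and params.noise.enabled:
        noise = params.noise
        for c in range(raster.shape[0]):
            clean = raster[c]
            if noise.poisson_scale > 0:
                lam = np.clip(clean, 0, None) * noise.poisson_scale
                raster[c] = rng.poisson(lam) / noise.poisson_scale
            if noise.gaussian_sd > 0:
                raster[c] = raster[c] + rng.normal(0, noise.gaussian_sd, size=shape)
    return raster.astype(np.float32), labels


# ---------------------------------------------------------------------------
# movie-level containers
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    """In-memory multi-channel time-lapse stack.

    ``data`` has shape (n_frames, n_channels, rows, cols).
    """

    data: np.ndarray
    channel_names: list[str]
    frame_interval: float  # minutes
    pixel_size: float = 1.0  # micrometres / px

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def dt_hours(self) -> float:
        return self.frame_interval / 60.0

    def channel(self, name: str) -> np.ndarray:
        """(n_frames, rows, cols) view of one channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel role {name!r} not present in stack "
                           f"(have {self.channel_names})") from None
        return self.data[:, idx]


@dataclass
class GroundTruth:
    """Complete truth for one synthetic movie."""

    labels: np.ndarray  # (n_frames, rows, cols) uint16
    frame_times: np.ndarray  # hours
    events: pd.DataFrame  # one row per cell
    lineage: dict[int, tuple[int, int]]  # parent cell_id -> (daughter, daughter)
    programs: list[CellProgram]
    compartment_levels: dict[str, np.ndarray]  # channel -> (n_cells+1, T, 2)

    @property
    def n_divisions(self) -> int:
        return len(self.lineage)

    def program(self, cell_id: int) -> CellProgram:
        for p in self.programs:
            if p.cell_id == cell_id:
                return p
        raise KeyError(cell_id)


# ---------------------------------------------------------------------------
# placement and full-movie simulation
# ---------------------------------------------------------------------------

def _auto_layout(n_cells: int, radius: float) -> tuple[tuple[int, int], list[tuple[float, float]]]:
    """Jitter-free grid centers plus the minimal image size holding them."""
    spacing = int(math.ceil(4.6 * radius))
    margin = int(math.ceil(3.2 * radius))
    if n_cells == 0:
        return (4 * margin, 4 * margin), []
    cols = int(math.ceil(math.sqrt(n_cells)))
    rows = int(math.ceil(n_cells / cols))
    size = (2 * margin + (rows - 1) * spacing + 1,
            2 * margin + (cols - 1) * spacing + 1)
    centers = []
    for i in range(n_cells):
        r, c = divmod(i, cols)
        centers.append((margin + r * spacing, margin + c * spacing))
    return size, centers


def _random_placement(n_cells: int, shape: tuple[int, int], radius: float,
                      rng: np.random.Generator,
                      retries: int = 2000) -> list[tuple[float, float]]:
    margin = 2.5 * radius
    min_sep = 4.0 * radius
    if shape[0] < 2 * margin or shape[1] < 2 * margin:
        raise SimulationError("image_size too small for even one nucleus")
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_cells:
        if attempts > retries * max(n_cells, 1):
            raise SimulationError(
                f"could not place {n_cells} non-overlapping nuclei in "
                f"{shape} within the retry budget")
        attempts += 1
        cand = (rng.uniform(margin, shape[0] - margin),
                rng.uniform(margin, shape[1] - margin))
        if all((cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_sep ** 2
               for r, c in centers):
            centers.append(cand)
    return centers


def _random_walk(start: tuple[float, float], n_steps: int, sd: float,
                 shape: tuple[int, int], rng: np.random.Generator,
                 margin: float) -> np.ndarray:
    path = np.empty((n_steps, 2))
    path[0] = start
    if n_steps > 1 and sd > 0:
        steps = rng.normal(0, sd, size=(n_steps - 1, 2))
        path[1:] = start + np.cumsum(steps, axis=0)
    else:
        path[1:] = start
    path[:, 0] = np.clip(path[:, 0], margin, shape[0] - margin)
    path[:, 1] = np.clip(path[:, 1], margin, shape[1] - margin)
    return path


def simulate_movie(params: SimulationParams) -> tuple[FrameStack, GroundTruth]:
    """Simulate a full movie plus its complete ground truth.

    In proliferation mode, every first-generation cell is born at t = 0
    and daughters are spawned recursively at each division while the
    movie lasts; the movie span defaults to one hour past the last
    first-generation division so every founder completes a full cycle.
    In starvation (quiescence) mode no cell enters S phase, nuclear PCNA
    decays exponentially (half-time ``decline_halftime``) and the movie
    defaults to 48 h.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    r_mean = params.nucleus_radius[0]

    if params.image_size is None:
        shape, centers = _auto_layout(params.n_cells, r_mean)
        params = replace(params, image_size=shape)
        jitter = 0.3 * r_mean
        centers = [(r + rng.uniform(-jitter, jitter), c + rng.uniform(-jitter, jitter))
                   for r, c in centers]
    else:
        shape = params.image_size
        centers = _random_placement(params.n_cells, shape, r_mean, rng)

    founders = [
        build_cell_program(params, rng, cell_id=i + 1, birth_time=0.0,
                           center=centers[i])
        for i in range(params.n_cells)
    ]

    dt = params.dt_hours
    if params.n_frames is not None:
        n_frames = int(params.n_frames)
        movie_end = n_frames * dt
    elif params.starvation:
        movie_end = 48.0
        n_frames = int(math.ceil(movie_end / dt)) + 1
    elif founders:
        movie_end = max(p.division_time for p in founders) + 1.0
        n_frames = int(math.ceil(movie_end / dt)) + 1
    else:
        n_frames = 1
        movie_end = dt

    # --- motion paths: founders first, then daughters are spawned in
    # birth order with their paths built immediately, so every division
    # can be placed against the known positions of all other cells
    def _build_path(cell: CellProgram, start_frame: int) -> None:
        margin = 1.2 * max(cell.axes)  # keep the nucleus inside the frame
        steps = max(1, n_frames - start_frame)
        walk = _random_walk(cell.center, steps, params.motion_sd, shape, rng,
                            margin)
        path = np.empty((n_frames, 2))
        path[:start_frame] = walk[0]
        path[start_frame:] = walk
        cell.path = path
        cell.center = tuple(walk[0])

    programs: list[CellProgram] = []
    lineage: dict[int, tuple[int, int]] = {}
    next_id = params.n_cells + 1
    for f in founders:
        _build_path(f, 0)
        programs.append(f)

    def _alive_at(frame: int, exclude: int) -> list[CellProgram]:
        t = frame * dt
        return [p for p in programs
                if p.cell_id != exclude and p.path is not None
                and p.birth_time - 1e-9 <= t
                and (p.quiescent or t < p.division_time - 1e-9)]

    queue = list(founders)
    while queue:
        cell = queue.pop(0)
        if cell.quiescent or cell.division_time >= movie_end:
            continue
        div_frame = min(n_frames - 1,
                        int(math.ceil(cell.division_time / dt - 1e-9)))
        mother_pos = np.asarray(cell.position_at(div_frame), dtype=float)
        # division axis: the candidate angle whose two daughter positions
        # have the largest clearance from the image margins and from
        # every other cell alive at the division frame
        base_angle = rng.uniform(0, 2 * np.pi)
        dist = 1.5 * max(cell.axes)
        d_rad = max(cell.axes) / math.sqrt(2)
        d_margin = 1.2 * d_rad
        neighbors = [(np.asarray(p.position_at(div_frame)), max(p.axes))
                     for p in _alive_at(div_frame, cell.cell_id)]
        best_offset, best_clear = None, -np.inf
        for k in range(16):
            ang = base_angle + k * np.pi / 8
            cand = dist * np.array([math.cos(ang), math.sin(ang)])
            clear = np.inf
            for sign in (+1, -1):
                pos = mother_pos + sign * cand
                clear = min(clear, pos[0] - d_margin, shape[0] - d_margin - pos[0],
                            pos[1] - d_margin, shape[1] - d_margin - pos[1])
                for npos, nrad in neighbors:
                    gap = float(np.hypot(*(pos - npos))) - (nrad + d_rad)
                    clear = min(clear, gap)
            if clear > best_clear:
                best_clear, best_offset = clear, cand
        offset = best_offset
        d1_inherit = None
        for name, prog in cell.coreporter_programs.items():
            if prog["profile"] == "g1_peak":
                d1_inherit = 0.5 * cell._d1_level(prog, cell.nebd_time - 1e-6)
        daughters = []
        for sign in (+1, -1):
            base = cell.pcna_base * cell.pcna_plateau_fold / 2.0
            d1_init = None
            if d1_inherit is not None:
                d1_init = d1_inherit * max(0.2, 1 + 0.03 * rng.normal())
            d = build_cell_program(
                params, rng, cell_id=next_id,
                birth_time=cell.division_time,
                center=tuple(mother_pos + sign * offset),
                pcna_base=base, parent=cell.cell_id,
                d1_initial=d1_init)
            # daughters are smaller: mother area is split between the two
            d.axes = (cell.axes[0] / math.sqrt(2), cell.axes[1] / math.sqrt(2))
            _build_path(d, div_frame)
            daughters.append(d)
            programs.append(d)
            next_id += 1
        queue.extend(daughters)
        queue.sort(key=lambda p: (p.division_time, p.cell_id))
        lineage[cell.cell_id] = (daughters[0].cell_id, daughters[1].cell_id)
    programs.sort(key=lambda p: p.cell_id)

    # --- render
    stack = np.empty((n_frames, len(params.channel_names), *shape), dtype=np.float32)
    labels = np.empty((n_frames, *shape), dtype=np.uint16)
    frame_times = np.arange(n_frames) * dt
    noise_rng = rng if params.noise.enabled else None
    for k in range(n_frames):
        raster, lab = render_frame(programs, frame_times[k], params,
                                   rng=noise_rng, frame_index=k)
        stack[k] = raster
        labels[k] = lab

    # --- ground truth tables
    rows = []
    for p in sorted(programs, key=lambda q: q.cell_id):
        if p.quiescent:
            rows.append(dict(
                cell=p.cell_id, parent=p.parent, birth_h=p.birth_time,
                g1s_h=np.nan, s_end_h=np.nan, nebd_h=np.nan, division_h=np.nan,
                quiescent=True, decline_onset_h=p.birth_time + p.decline_onset,
                pcna_base=p.pcna_base))
        else:
            rows.append(dict(
                cell=p.cell_id, parent=p.parent, birth_h=p.birth_time,
                g1s_h=p.s_begin_time, s_end_h=p.s_end_time,
                nebd_h=p.nebd_time, division_h=p.division_time,
                quiescent=False, decline_onset_h=np.nan,
                pcna_base=p.pcna_base))
    events = pd.DataFrame(rows)
    if not events.empty:
        for col in ("birth_h", "g1s_h", "s_end_h", "nebd_h", "division_h"):
            frame_col = col.replace("_h", "_frame")
            with np.errstate(invalid="ignore"):
                events[frame_col] = np.where(
                    np.isfinite(events[col]),
                    np.ceil(events[col] / dt - 1e-9), np.nan)

    # --- programmed compartment levels per channel
    n_ids = (max(p.cell_id for p in programs) + 1) if programs else 1
    compartments: dict[str, np.ndarray] = {}
    for name in params.channel_names:
        arr = np.full((n_ids, n_frames, 2), np.nan)
        for p in programs:
            for k, t in enumerate(frame_times):
                alive = (p.birth_time - 1e-9 <= t and
                         (p.quiescent or t < p.division_time - 1e-9))
                if not alive:
                    continue
                if name == "pcna":
                    count, sigma, amp = p.foci_state(t)
                    # diffuse level only; foci are additional structure
                    arr[p.cell_id, k] = (p.pcna_level(t), 0.0)
                elif name == "chromatin":
                    arr[p.cell_id, k] = (p.chromatin_level, 0.0)
                else:
                    arr[p.cell_id, k] = p.coreporter_level(name, t)
        compartments[name] = arr

    truth = GroundTruth(labels=labels, frame_times=frame_times, events=events,
                        lineage=lineage, programs=programs,
                        compartment_levels=compartments)
    frame_stack = FrameStack(data=stack, channel_names=params.channel_names,
                             frame_interval=params.frame_interval)
    return frame_stack, truth
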