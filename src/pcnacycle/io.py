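"""TIFF / CSV / lineage-text formats and the pipeline configuration file.

Canonical formats: multi-page TIFF for image stacks (axes TCYX, channel
roles and acquisition metadata in a JSON image description), 16-bit
TIFF for label maps, CSV for all tabular outputs, and a plain-text
lineage file (one division record per line). Frame indices are 0-based
everywhere; time columns are hours derived from the frame interval.
Every output directory receives a config echo carrying the producing
config and its hash, for provenance.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .phases import PhaseAnnotation, PhaseParams
from .quantify import RingParams
from .segment import LabelMap, SegParams
from .simulate import FrameStack
from .track import CellTrack, LinkParams, Lineage

__all__ = ["PipelineConfig", "read_stack", "write_stack", "write_labels",
           "read_labels", "write_outputs", "write_lineage", "read_lineage",
           "tracks_to_frame", "frame_to_tracks", "config_hash"]

LINEAGE_HEADER = "# pcnacycle lineage v1"
TRACKS_COLUMNS = ["track_id", "frame", "time_h", "label", "centroid_row",
                  "centroid_col", "area", "parent_track"]


@dataclass
class PipelineConfig:
    """Structured configuration binding all pipeline stages.

    The PCNA channel role is mandatory; co-reporter roles are free-form
    names mapped to channel indices or stack channel names.
    """

    channels: dict[str, str | int] = field(default_factory=lambda: {"pcna": "pcna"})
    frame_interval: float = 10.0  # minutes
    pixel_size: float = 1.0  # micrometres
    seed: int = 0
    output_dir: str = "."
    seg: SegParams = field(default_factory=SegParams)
    link: LinkParams = field(default_factory=LinkParams)
    phase: PhaseParams = field(default_factory=PhaseParams)
    ring: RingParams = field(default_factory=RingParams)

    def __post_init__(self) -> None:
        if "pcna" not in self.channels:
            raise ValueError("config must declare the 'pcna' channel role")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def to_dict(self) -> dict:
        # canonical JSON-compatible form (tuples become lists)
        return json.loads(json.dumps({
            "channels": dict(self.channels),
            "frame_interval": self.frame_interval,
            "pixel_size": self.pixel_size,
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "seg": asdict(self.seg),
            "link": asdict(self.link),
            "phase": asdict(self.phase),
            "ring": asdict(self.ring),
        }))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d.pop("config_hash", None)  # echoes carry their own hash
        for key, typ in (("seg", SegParams), ("link", LinkParams),
                         ("phase", PhaseParams), ("ring", RingParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a (T, C, Y, X) stack as multi-page TIFF with JSON metadata."""
    meta = {
        "axes": "TCYX",
        "channel_names": stack.channel_names,
        "frame_interval_min": stack.frame_interval,
        "pixel_size_um": stack.pixel_size,
    }
    tifffile.imwrite(path, stack.data, description=json.dumps(meta),
                     photometric="minisblack", metadata=None)


def read_stack(path: str | Path,
               config: PipelineConfig | None = None) -> FrameStack:
    """Read a stack written by :func:`write_stack` (or any TCYX TIFF).

    Declared channel roles in ``config`` are validated against the
    stack's channel names; a missing role raises an error naming it.
    Mixed bit depths across pages are rejected.
    """
    with tifffile.TiffFile(path) as tif:
        dtypes = {page.dtype for page in tif.pages}
        if len(dtypes) > 1:
            raise ValueError(f"mixed bit depths in stack: {sorted(map(str, dtypes))}")
        data = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    names = meta.get("channel_names")
    if data.ndim == 3:
        # flat page sequence: regroup into TCYX using the channel count
        n_ch = len(names) if names else 1
        if data.shape[0] % n_ch:
            raise ValueError(
                f"page count {data.shape[0]} not divisible by "
                f"{n_ch} declared channels")
        data = data.reshape(-1, n_ch, *data.shape[1:])
    elif data.ndim == 4 and names and data.shape[1] == 1 \
            and data.shape[0] % len(names) == 0:
        data = data.reshape(-1, len(names), *data.shape[2:])
    if data.ndim != 4:
        raise ValueError(f"expected a TCYX stack, got shape {data.shape}")
    names = names or [f"ch{i}" for i in range(data.shape[1])]
    stack = FrameStack(data=data, channel_names=list(names),
                       frame_interval=float(meta.get("frame_interval_min", 10.0)),
                       pixel_size=float(meta.get("pixel_size_um", 1.0)))
    if config is not None:
        for role, name in config.channels.items():
            if isinstance(name, int):
                if name >= data.shape[1]:
                    raise ValueError(
                        f"channel role {role!r} maps to index {name} but the "
                        f"stack has {data.shape[1]} channels")
            elif name not in stack.channel_names:
                raise ValueError(
                    f"channel role {role!r} ({name!r}) missing from stack "
                    f"channels {stack.channel_names}")
    return stack


def write_labels(labelmaps: list[LabelMap] | np.ndarray, path: str | Path) -> None:
    """Write per-frame label maps as one 16-bit multi-page TIFF."""
    if isinstance(labelmaps, np.ndarray):
        arr = labelmaps.astype(np.uint16)
    else:
        arr = np.stack([lm.labels for lm in labelmaps]).astype(np.uint16)
    tifffile.imwrite(path, arr, description=json.dumps({"axes": "TYX"}))


def read_labels(path: str | Path) -> list[LabelMap]:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return [LabelMap(k, arr[k].astype(np.int32)) for k in range(arr.shape[0])]


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def tracks_to_frame(tracks: dict[int, CellTrack], dt_hours: float) -> pd.DataFrame:
    rows = []
    for tid in sorted(tracks):
        tr = tracks[tid]
        for f, lab, (cr, cc), area in zip(tr.frames, tr.labels, tr.centroids,
                                          tr.areas):
            rows.append((tid, f, f * dt_hours, lab, cr, cc, area,
                         tr.parent_track))
    return pd.DataFrame(rows, columns=TRACKS_COLUMNS)


def frame_to_tracks(df: pd.DataFrame) -> dict[int, CellTrack]:
    tracks: dict[int, CellTrack] = {}
    for tid, group in df.groupby("track_id"):
        tr = CellTrack(int(tid))
        group = group.sort_values("frame")
        for _, row in group.iterrows():
            tr.append(int(row["frame"]), int(row["label"]),
                      (float(row["centroid_row"]), float(row["centroid_col"])),
                      int(row["area"]))
        parent = row["parent_track"]
        tr.parent_track = None if pd.isna(parent) else int(parent)
        tracks[int(tid)] = tr
    for tr in tracks.values():
        if tr.parent_track is not None and tr.parent_track in tracks:
            mother = tracks[tr.parent_track]
            sibs = (mother.daughter_tracks or ()) + (tr.track_id,)
            mother.daughter_tracks = tuple(sorted(set(sibs)))[:2]
    return tracks


def annotations_to_frame(annotations: dict[int, PhaseAnnotation]) -> pd.DataFrame:
    rows = []
    for tid in sorted(annotations):
        a = annotations[tid]
        rows.append(dict(
            track_id=tid, birth=a.birth_frame, g1s=a.g1s_frame,
            sg2=a.sg2_frame, nebd=a.nebd_frame, division=a.division_frame,
            quiescent=a.quiescent, decline_onset=a.decline_onset_frame,
            flags=";".join(f"{k}={v}" for k, v in sorted(a.flags.items()))))
    return pd.DataFrame(rows)


def phases_to_frame(annotations: dict[int, PhaseAnnotation],
                    tracks: dict[int, CellTrack]) -> pd.DataFrame:
    rows = []
    for tid in sorted(annotations):
        a = annotations[tid]
        if a.phases is None or tid not in tracks:
            continue
        start = tracks[tid].start
        for i, phase in enumerate(a.phases):
            rows.append((tid, start + i, phase))
    return pd.DataFrame(rows, columns=["track_id", "frame", "phase"])


# ---------------------------------------------------------------------------
# lineage text format
# ---------------------------------------------------------------------------

def write_lineage(lineage: Lineage, path: str | Path) -> None:
    lines = [LINEAGE_HEADER]
    for mother, frame, da, db in lineage.divisions:
        lines.append(f"division\t{mother}\t{frame}\t{da}\t{db}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_lineage(path: str | Path,
                 tracks: dict[int, CellTrack] | None = None) -> Lineage:
    divisions = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, mother, frame, da, db = line.split("\t")
        if kind != "division":
            raise ValueError(f"unknown lineage record {kind!r}")
        divisions.append((int(mother), int(frame), int(da), int(db)))
    tracks = tracks or {}
    lineage = Lineage(tracks=tracks, divisions=divisions)
    for mother, _frame, da, db in divisions:
        if mother in tracks:
            tracks[mother].daughter_tracks = (da, db)
        for d in (da, db):
            if d in tracks:
                tracks[d].parent_track = mother
    return lineage


# ---------------------------------------------------------------------------
# bundled outputs
# ---------------------------------------------------------------------------

def _check_writable(outdir: Path) -> None:
    if not outdir.exists():
        outdir.mkdir(parents=True, exist_ok=True)
    if not os.access(outdir, os.W_OK):
        raise PermissionError(f"output directory {outdir} is not writable")


def write_outputs(outdir: str | Path, config: PipelineConfig,
                  tracks: dict[int, CellTrack] | None = None,
                  labelmaps: list[LabelMap] | None = None,
                  annotations: dict[int, PhaseAnnotation] | None = None,
                  lineage: Lineage | None = None,
                  measurements: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write all available pipeline products with a config echo.

    Target writability is checked up front so a bad path fails before
    any partial file appears. Returns the paths written.
    """
    outdir = Path(outdir)
    _check_writable(outdir)
    dt = config.frame_interval / 60.0
    written: dict[str, Path] = {}

    echo = dict(config.to_dict())
    echo["config_hash"] = config_hash(config)
    p = outdir / "config_echo.yaml"
    p.write_text(yaml.safe_dump(echo, sort_keys=True))
    written["config"] = p

    if labelmaps is not None:
        p = outdir / "labels.tif"
        write_labels(labelmaps, p)
        written["labels"] = p
    if tracks is not None:
        p = outdir / "tracks.csv"
        tracks_to_frame(tracks, dt).to_csv(p, index=False)
        written["tracks"] = p
    if annotations is not None:
        p = outdir / "events.csv"
        annotations_to_frame(annotations).to_csv(p, index=False)
        written["events"] = p
        if tracks is not None:
            p = outdir / "phases.csv"
            phases_to_frame(annotations, tracks).to_csv(p, index=False)
            written["phases"] = p
    if lineage is not None:
        p = outdir / "lineage.txt"
        write_lineage(lineage, p)
        written["lineage"] = p
    if measurements is not None:
        p = outdir / "measurements.csv"
        measurements.to_csv(p, index=False)
        written["measurements"] = p
    return written
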