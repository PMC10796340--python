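"""Readers and writers for motion-capture text formats (TRC, MOT/STO).

TRC is the tab-delimited marker-trajectory format consumed by standard
musculoskeletal software; MOT and STO share one storage layout (a small
header ending in ``endheader`` followed by tab-separated numeric rows) and
differ only by convention: MOT carries joint-angle motions (``inDegrees``
flag), STO carries state/control time histories.

All writers are deterministic byte-for-byte: fixed float formatting
("%.5f" for TRC positions, shortest-exact repr for storage rows so that
numeric round trips are lossless), tab separators, LF line endings.
Readers tolerate CRLF and trailing blank columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .kinematics import JointTrajectory
from .skeleton import MarkerTrajectorySet
from .spastic_muscle import MuscleSimResult

__all__ = [
    "TrcDocument",
    "StoDocument",
    "TrcParseError",
    "StoParseError",
    "write_trc",
    "read_trc",
    "write_sto",
    "read_sto",
    "write_mot",
    "sto_from_trajectory",
    "sto_from_simulation",
    "trajectory_from_sto",
]

TRC_FLOAT_FMT = "%.5f"


def _sto_float(v: float) -> str:
    # shortest exact decimal representation: round-trips losslessly
    return repr(float(v))


class TrcParseError(ValueError):
    pass


class StoParseError(ValueError):
    pass


@dataclass(frozen=True)
class TrcDocument:
    """A parsed TRC file: acquisition metadata plus the marker set."""

    markers: MarkerTrajectorySet
    data_rate: float
    camera_rate: float
    orig_data_rate: float
    orig_start_frame: int
    orig_num_frames: int
    name: str = "markers.trc"

    @property
    def num_frames(self) -> int:
        return int(np.asarray(self.markers.times).size)

    @property
    def num_markers(self) -> int:
        return len(self.markers.marker_names)


@dataclass(frozen=True)
class StoDocument:
    """A parsed MOT/STO storage file."""

    name: str
    column_labels: tuple[str, ...]   # first is "time"
    data: np.ndarray                 # (nRows, nColumns)
    in_degrees: bool | None = None   # None: flag absent (plain STO)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[1] != len(self.column_labels):
            raise ValueError(
                f"data shape {d.shape} inconsistent with "
                f"{len(self.column_labels)} column labels"
            )
        if self.column_labels and self.column_labels[0] != "time":
            raise ValueError("first column label must be 'time'")
        t = d[:, 0]
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("time column must be strictly increasing")

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.column_labels.index(label)
        except ValueError as exc:
            raise KeyError(f"no column {label!r}") from exc
        return np.asarray(self.data)[:, j]


def write_trc(
    markers: MarkerTrajectorySet,
    path,
    data_rate: float,
    camera_rate: float | None = None,
    name: str | None = None,
) -> TrcDocument:
    """Write a marker set as a standard TRC file.

    Layout: line 1 ``PathFileType\t4\t(X/Y/Z)\t<name>``; lines 2-3 header
    keys and values (DataRate, CameraRate, NumFrames, NumMarkers, Units,
    OrigDataRate, OrigDataStartFrame, OrigNumFrames); line 4 marker names
    spanning three columns each; line 5 X/Y/Z sub-headers; then 1-based
    frame rows.
    """
    pos = np.asarray(markers.positions)
    n_frames, n_markers, _ = pos.shape
    if n_frames == 0 or n_markers == 0:
        raise ValueError("cannot write an empty marker set")
    path = Path(path)
    camera_rate = camera_rate if camera_rate is not None else data_rate
    name = name or path.name
    units = markers.units

    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{data_rate:g}\t{camera_rate:g}\t{n_frames}\t{n_markers}\t{units}\t"
        f"{data_rate:g}\t1\t{n_frames}",
        "Frame#\tTime\t" + "\t".join(f"{m}\t\t" for m in markers.marker_names).rstrip("\t"),
        "\t\t" + "\t".join(
            f"X{i}\tY{i}\tZ{i}" for i in range(1, n_markers + 1)
        ),
    ]
    times = np.asarray(markers.times, dtype=float)
    for f in range(n_frames):
        cells = [str(f + 1), TRC_FLOAT_FMT % times[f]]
        cells.extend(TRC_FLOAT_FMT % v for v in pos[f].ravel())
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return TrcDocument(
        markers=markers,
        data_rate=data_rate,
        camera_rate=camera_rate,
        orig_data_rate=data_rate,
        orig_start_frame=1,
        orig_num_frames=n_frames,
        name=name,
    )


def read_trc(source) -> TrcDocument:
    """Parse a TRC file (path or file-like). CRLF and trailing tabs tolerated."""
    if hasattr(source, "read"):
        text = source.read()
        fname = getattr(source, "name", "markers.trc")
    else:
        text = Path(source).read_text()
        fname = Path(source).name
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    lines = [ln for ln in lines]
    if len([ln for ln in lines if ln.strip()]) < 6:
        raise TrcParseError(f"{fname}: too short to be a TRC file")
    if not lines[0].startswith("PathFileType"):
        raise TrcParseError(f"{fname}: line 1 must start with 'PathFileType'")
    keys = lines[1].rstrip().split("\t")
    vals = lines[2].rstrip().split("\t")
    header = dict(zip(keys, vals))
    try:
        data_rate = float(header["DataRate"])
        camera_rate = float(header["CameraRate"])
        num_frames = int(header["NumFrames"])
        num_markers = int(header["NumMarkers"])
        units = header["Units"]
    except (KeyError, ValueError) as exc:
        raise TrcParseError(f"{fname}: bad header at line 3: {exc}") from exc
    marker_line = lines[3].rstrip("\t\n ").split("\t")
    marker_names = [c for c in marker_line[2:] if c != ""]
    if len(marker_names) != num_markers:
        raise TrcParseError(
            f"{fname}: line 4 names {len(marker_names)} markers but header "
            f"says NumMarkers {num_markers}"
        )
    data_rows = []
    times = []
    for i, ln in enumerate(lines[5:], start=6):
        if not ln.strip():
            continue
        cells = ln.rstrip("\t ").split("\t")
        if len(cells) != 2 + 3 * num_markers:
            raise TrcParseError(
                f"{fname}: line {i} has {len(cells)} columns, expected "
                f"{2 + 3 * num_markers}"
            )
        try:
            times.append(float(cells[1]))
            data_rows.append([float(c) for c in cells[2:]])
        except ValueError as exc:
            raise TrcParseError(f"{fname}: line {i}: {exc}") from exc
    if len(data_rows) != num_frames:
        raise TrcParseError(
            f"{fname}: {len(data_rows)} data rows but header says NumFrames "
            f"{num_frames}"
        )
    pos = np.asarray(data_rows).reshape(num_frames, num_markers, 3)
    markers = MarkerTrajectorySet(
        marker_names=tuple(marker_names),
        times=np.asarray(times),
        positions=pos,
        units=units,
    )
    return TrcDocument(
        markers=markers,
        data_rate=data_rate,
        camera_rate=camera_rate,
        orig_data_rate=float(header.get("OrigDataRate", data_rate)),
        orig_start_frame=int(header.get("OrigDataStartFrame", 1)),
        orig_num_frames=int(header.get("OrigNumFrames", num_frames)),
        name=fname,
    )


def write_sto(doc: StoDocument, path) -> None:
    """Write a MOT/STO storage file (numerically lossless round trip)."""
    data = np.asarray(doc.data, dtype=float)
    lines = [doc.name, f"nRows={data.shape[0]}", f"nColumns={data.shape[1]}"]
    if doc.in_degrees is not None:
        lines.append(f"inDegrees={'yes' if doc.in_degrees else 'no'}")
    lines.append("endheader")
    lines.append("\t".join(doc.column_labels))
    for row in data:
        lines.append("\t".join(_sto_float(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sto(source) -> StoDocument:
    """Parse a MOT/STO storage file."""
    if hasattr(source, "read"):
        text = source.read()
        fname = getattr(source, "name", "data.sto")
    else:
        text = Path(source).read_text()
        fname = Path(source).name
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    header: dict[str, str] = {}
    name = None
    body_start = None
    for i, ln in enumerate(lines):
        s = ln.strip()
        if s == "endheader":
            body_start = i + 1
            break
        if "=" in s:
            k, _, v = s.partition("=")
            header[k.strip()] = v.strip()
        elif s and name is None:
            name = s
    if body_start is None:
        raise StoParseError(f"{fname}: no 'endheader' line")
    labels = tuple(lines[body_start].rstrip().split("\t"))
    rows = []
    for i, ln in enumerate(lines[body_start + 1:], start=body_start + 2):
        if not ln.strip():
            continue
        cells = ln.rstrip("\t ").split("\t")
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise StoParseError(f"{fname}: line {i}: {exc}") from exc
        if len(cells) != len(labels):
            raise StoParseError(
                f"{fname}: line {i} has {len(cells)} columns, expected {len(labels)}"
            )
    data = np.asarray(rows, dtype=float) if rows else np.empty((0, len(labels)))
    if "nRows" in header and int(header["nRows"]) != data.shape[0]:
        raise StoParseError(
            f"{fname}: header nRows={header['nRows']} but {data.shape[0]} rows"
        )
    if "nColumns" in header and int(header["nColumns"]) != data.shape[1]:
        raise StoParseError(
            f"{fname}: header nColumns={header['nColumns']} but "
            f"{data.shape[1]} columns"
        )
    in_deg = None
    if "inDegrees" in header:
        in_deg = header["inDegrees"].lower() == "yes"
    return StoDocument(
        name=name or fname, column_labels=labels, data=data, in_degrees=in_deg
    )


def sto_from_trajectory(trajectory: JointTrajectory, name: str = "motion.mot") -> StoDocument:
    """Joint-angle motion as a MOT-convention storage document (degrees)."""
    data = np.column_stack([np.asarray(trajectory.times), np.asarray(trajectory.angles)])
    return StoDocument(
        name=name,
        column_labels=("time",) + tuple(trajectory.joint_names),
        data=data,
        in_degrees=True,
    )


def trajectory_from_sto(doc: StoDocument, rate_hz: float | None = None,
                        wrist_preset_deg: float = 0.0) -> JointTrajectory:
    """Rebuild a joint trajectory from a MOT document (must be in degrees)."""
    if doc.in_degrees is False:
        raise ValueError("motion document is in radians; trajectories use degrees")
    t = doc.column("time")
    if rate_hz is None:
        if t.size < 2:
            raise ValueError("cannot infer rate from a single row")
        rate_hz = 1.0 / (t[1] - t[0])
    return JointTrajectory(
        joint_names=tuple(doc.column_labels[1:]),
        times=t,
        angles=np.asarray(doc.data)[:, 1:],
        rate_hz=rate_hz,
        wrist_preset_deg=wrist_preset_deg,
    )


#: Per-muscle state columns written for simulation bundles, in order.
SIM_STATE_SUFFIXES = (
    "excitation", "activation", "fiber_length_norm", "fiber_velocity_norm", "force",
)


def sto_from_simulation(
    muscles: dict[str, MuscleSimResult] | Sequence[MuscleSimResult],
    name: str = "states.sto",
) -> StoDocument:
    """Bundle per-muscle state histories into one storage document.

    Columns: time, then ``<muscle>_excitation``, ``_activation``,
    ``_fiber_length_norm``, ``_fiber_velocity_norm``, ``_force`` per
    muscle, muscles in the given order.
    """
    if isinstance(muscles, dict):
        items = list(muscles.values())
    else:
        items = list(muscles)
    if not items:
        raise ValueError("no muscle results to serialize")
    t = np.asarray(items[0].times)
    labels = ["time"]
    cols = [t]
    for r in items:
        if np.asarray(r.times).shape != t.shape or not np.allclose(r.times, t):
            raise ValueError(f"muscle {r.muscle}: time base differs")
        for suffix in SIM_STATE_SUFFIXES:
            labels.append(f"{r.muscle}_{suffix}")
            cols.append(np.asarray(getattr(r, suffix)))
    return StoDocument(
        name=name, column_labels=tuple(labels), data=np.column_stack(cols),
        in_degrees=None,
    )


def write_mot(trajectory: JointTrajectory, path, name: str | None = None) -> StoDocument:
    """Write a joint trajectory as a MOT motion file (degrees)."""
    doc = sto_from_trajectory(trajectory, name or Path(path).name)
    write_sto(doc, path)
    return doc
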