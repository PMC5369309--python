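"""File formats for mother-machine channel data.

Three dialects live here: multi-page TIFF time-lapse stacks of a single
growth channel, the five-column per-mother-cell trace text files
(time, division flag, cell length, total fluorescence, mean fluorescence),
and the ``xyFF_CC`` dataset naming convention that encodes the field of
view and the mother-cell index within it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import tifffile

__all__ = [
    "TimeLapseStack",
    "MotherTrace",
    "DatasetName",
    "FormatError",
    "TraceParseError",
    "NamingError",
    "read_stack",
    "write_stack",
    "read_trace",
    "write_trace",
    "parse_dataset_name",
    "format_dataset_name",
]

TRACE_COLUMNS = ("time", "division_flag", "length", "total_fluor", "mean_fluor")


class FormatError(ValueError):
    """Raised for structurally invalid image stacks."""


class TraceParseError(ValueError):
    """Raised for malformed trace files; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class NamingError(ValueError):
    """Raised when a filename does not follow the xyFF_CC convention."""


@dataclass
class TimeLapseStack:
    """Ordered frames of one growth channel with a shared time base.

    frames : (n_frames, H, W) array of grayscale intensities.
    times : acquisition times in minutes, strictly increasing.
    pixel_size : µm per pixel; None means lengths stay in pixels.
    channel_axis : image axis that runs along the growth channel (0 or 1).
    closed_end : 'low' if the dead end (mother position) is at index 0 of
        the channel axis, 'high' if at the far index.
    """

    frames: np.ndarray
    times: np.ndarray
    pixel_size: float | None = None
    channel_axis: int = 0
    closed_end: str = "low"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError(
                f"expected frames with shape (n, H, W), got ndim={self.frames.ndim}"
            )
        if len(self.times) != len(self.frames):
            raise FormatError(
                f"{len(self.frames)} frames but {len(self.times)} time points"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("times must be strictly increasing")
        if self.channel_axis not in (0, 1):
            raise FormatError("channel_axis must be 0 or 1 (per-frame axis)")
        if self.closed_end not in ("low", "high"):
            raise FormatError("closed_end must be 'low' or 'high'")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class MotherTrace:
    """Per-minute series for one mother cell (the trace-file content)."""

    time: np.ndarray
    division_flag: np.ndarray
    length: np.ndarray
    total_fluor: np.ndarray
    mean_fluor: np.ndarray
    length_unit: str = "px"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.division_flag = np.asarray(self.division_flag, dtype=int)
        self.length = np.asarray(self.length, dtype=float)
        self.total_fluor = np.asarray(self.total_fluor, dtype=float)
        self.mean_fluor = np.asarray(self.mean_fluor, dtype=float)
        n = len(self.time)
        for name in ("division_flag", "length", "total_fluor", "mean_fluor"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column '{name}' length differs from time column")
        if not np.isin(self.division_flag, (0, 1)).all():
            raise ValueError("division_flag must be 0 or 1")
        if n and not (self.length > 0).all():
            raise ValueError("length must be positive at every time point")
        if n and not (self.mean_fluor >= 0).all():
            raise ValueError("mean_fluor must be non-negative")

    def __len__(self) -> int:
        return len(self.time)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MotherTrace):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, c), getattr(other, c)) for c in TRACE_COLUMNS
        )


@dataclass(frozen=True)
class DatasetName:
    """Field-of-view / mother-cell index pair behind the xyFF_CC names."""

    fov: int
    cell: int

    def __post_init__(self) -> None:
        if self.fov < 1 or self.cell < 1:
            raise NamingError("fov and cell indices are 1-based positive integers")


# ---------------------------------------------------------------------------
# TIFF stacks


def read_stack(
    path: str | Path,
    channel_axis: int = 0,
    closed_end: str = "low",
    minutes_per_frame: float = 1.0,
    pixel_size: float | None = None,
) -> TimeLapseStack:
    """Read a single- or multi-page TIFF into a :class:`TimeLapseStack`.

    Times are assigned as 0, dt, 2*dt, ... in file order; the TIFF itself
    carries no time metadata in this dialect.
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF stack {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.size == 0:
        raise FormatError(
            f"{path}: expected a stack of 2-D grayscale pages, got shape {frames.shape}"
        )
    times = np.arange(len(frames), dtype=float) * minutes_per_frame
    return TimeLapseStack(
        frames=frames,
        times=times,
        pixel_size=pixel_size,
        channel_axis=channel_axis,
        closed_end=closed_end,
    )


def write_stack(stack: TimeLapseStack, path: str | Path) -> None:
    """Write the stack as a multi-page TIFF (one page per frame)."""
    tifffile.imwrite(Path(path), stack.frames)


# ---------------------------------------------------------------------------
# Trace text files


def write_trace(trace: MotherTrace, path: str | Path) -> None:
    """Write a trace file: '#' header, then one tab-separated row per minute.

    Columns: time, division flag, cell length, total fluorescence, mean
    fluorescence. Numbers carry enough digits to round-trip at 6+
    significant figures.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# mother-machine trace; length unit: {trace.length_unit}\n")
        fh.write("# time_min\tdivision_flag\tlength\ttotal_fluor\tmean_fluor\n")
        for i in range(len(trace)):
            fh.write(
                f"{trace.time[i]:.6g}\t{trace.division_flag[i]:d}\t"
                f"{trace.length[i]:.9g}\t{trace.total_fluor[i]:.9g}\t"
                f"{trace.mean_fluor[i]:.9g}\n"
            )


def read_trace(path: str | Path) -> MotherTrace:
    """Read a five-column trace file (any whitespace delimiter tolerated)."""
    path = Path(path)
    rows: list[tuple[float, ...]] = []
    length_unit = "px"
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"length unit:\s*(\S+)", line)
                if m:
                    length_unit = m.group(1)
                continue
            fields = line.split()
            if len(fields) != 5:
                raise TraceParseError(
                    f"expected 5 columns, found {len(fields)}", lineno
                )
            try:
                rows.append(tuple(float(x) for x in fields))
            except ValueError as exc:
                raise TraceParseError(f"non-numeric value ({exc})", lineno) from exc
    data = np.array(rows, dtype=float).reshape(-1, 5)
    flags = data[:, 1]
    if not np.isin(flags, (0.0, 1.0)).all():
        raise TraceParseError("division flag column contains values other than 0/1")
    return MotherTrace(
        time=data[:, 0],
        division_flag=flags.astype(int),
        length=data[:, 2],
        total_fluor=data[:, 3],
        mean_fluor=data[:, 4],
        length_unit=length_unit,
    )


# ---------------------------------------------------------------------------
# Dataset naming

_NAME_RE = re.compile(r"^xy(\d{2,})_(\d{2,})\.(tif|txt)$")


def parse_dataset_name(filename: str) -> DatasetName:
    """Parse 'xyFF_CC.tif' / 'xyFF_CC.txt' into (fov, cell)."""
    m = _NAME_RE.match(Path(filename).name)
    if m is None:
        raise NamingError(
            f"{filename!r} does not match the xyFF_CC.tif/.txt naming convention"
        )
    return DatasetName(fov=int(m.group(1)), cell=int(m.group(2)))


def format_dataset_name(name: DatasetName, extension: str = "tif") -> str:
    """Inverse of :func:`parse_dataset_name` (two-digit zero padding)."""
    ext = extension.lstrip(".")
    if ext not in ("tif", "txt"):
        raise NamingError(f"unsupported extension {extension!r}")
    return f"xy{name.fov:02d}_{name.cell:02d}.{ext}"
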