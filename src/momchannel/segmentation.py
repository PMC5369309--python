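"""Per-frame segmentation of one-cell-wide mother-machine channel images.

The processing chain per frame: 3x3 median filter, percentile intensity
rescaling with the top and bottom 2% saturated, reduction to a 1-D axial
intensity profile, cell-boundary detection as prominent profile minima,
relative-threshold masking split at the boundaries, and per-cell
measurement (moment-based length, total and mean fluorescence from the
raw intensities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .io_formats import TimeLapseStack

__all__ = [
    "SegmentationParams",
    "CellMeasurement",
    "FrameSegmentation",
    "MotherSeries",
    "MeasurementError",
    "PipelineError",
    "preprocess_frame",
    "axial_profile",
    "detect_boundaries",
    "make_masks",
    "measure_cell",
    "segment_frame",
    "segment_stack",
]


class MeasurementError(ValueError):
    """Raised when a cell measurement is requested on an empty mask."""


class PipelineError(RuntimeError):
    """Raised when a stack is unusable (e.g. mother missing in most frames)."""


@dataclass
class SegmentationParams:
    """Tunable segmentation settings.

    threshold_rel is the mask threshold as a fraction of the frame's
    maximum (post-rescale) intensity. min_prominence is the minimum depth
    of a boundary minimum as a fraction of the axial-profile maximum.
    length_method selects the moment-based length convention: "rod"
    (sqrt(12)·axial s.d.; exact for a top-hat rod and unbiased for
    rod-shaped bacteria) or "ellipse" (major-axis length of the
    equal-moments ellipse, 4·sqrt(largest eigenvalue)).
    """

    median_kernel: int = 3
    saturate_frac: float = 0.02
    threshold_rel: float = 0.30
    min_boundary_distance_px: int = 5
    min_prominence: float = 0.10
    length_method: str = "rod"

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if not (0 < self.saturate_frac < 0.5):
            raise ValueError("saturate_frac must lie in (0, 0.5)")
        if not (0 < self.threshold_rel < 1):
            raise ValueError("threshold_rel must lie in (0, 1)")
        if self.min_boundary_distance_px < 1:
            raise ValueError("min_boundary_distance_px must be >= 1")
        if not (0 < self.min_prominence < 1):
            raise ValueError("min_prominence must lie in (0, 1)")
        if self.length_method not in ("rod", "ellipse"):
            raise ValueError("length_method must be 'rod' or 'ellipse'")


@dataclass
class CellMeasurement:
    """Mask-derived quantities for one cell in one frame.

    index_from_closed_end 0 is the mother. axial_span is the half-open
    pixel interval [start, end) the mask occupies along the channel axis,
    in the coordinates of the input frame.
    """

    index_from_closed_end: int
    length: float
    area_px: int
    total_fluor: float
    mean_fluor: float
    axial_span: tuple[int, int]


@dataclass
class FrameSegmentation:
    """Cells of one frame, ordered from the channel's closed end."""

    cells: list[CellMeasurement] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def mother(self) -> CellMeasurement | None:
        return self.cells[0] if self.cells else None


@dataclass
class MotherSeries:
    """Raw per-frame mother measurements; gaps are NaN with a QC flag set."""

    time: np.ndarray
    length: np.ndarray
    total_fluor: np.ndarray
    mean_fluor: np.ndarray
    gap_flags: np.ndarray   # bool per frame; True where no mother was measured
    measurements: list[CellMeasurement | None]

    @property
    def n_gaps(self) -> int:
        return int(self.gap_flags.sum())

    def to_trace(self):
        """Gap-free :class:`~momchannel.io_formats.MotherTrace`.

        Gaps carry the last valid measurement forward (leading gaps carry
        the first valid one backward); no interpolation. Division flags
        are zero — they are assigned by the lineage stage.
        """
        from .io_formats import MotherTrace

        if self.gap_flags.all():
            raise PipelineError("no valid mother measurement in any frame")
        idx = np.arange(len(self.time))
        valid = ~self.gap_flags
        # index of the nearest valid frame at or before each frame
        carry = np.maximum.accumulate(np.where(valid, idx, -1))
        first_valid = idx[valid][0]
        carry[carry < 0] = first_valid
        return MotherTrace(
            time=self.time.copy(),
            division_flag=np.zeros(len(self.time), dtype=int),
            length=self.length[carry],
            total_fluor=self.total_fluor[carry],
            mean_fluor=self.mean_fluor[carry],
        )


# ---------------------------------------------------------------------------
# Frame-level operations


def preprocess_frame(image: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Median-filter then rescale so the intensity tails saturate.

    Values at or below the lower percentile map to 0, at or above the
    upper percentile to 1, linearly in between (linear-interpolation
    percentiles). A degenerate frame — constant, or with no contrast
    beyond the pixel-noise floor (an empty channel) — rescales to all
    zeros with a warning rather than stretching noise into fake signal.
    """
    p = params if params is not None else SegmentationParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("expected a 2-D image of at least 3x3 pixels")
    filt = ndimage.median_filter(img, size=p.median_kernel, mode="reflect")
    lo, hi = np.percentile(filt, [100 * p.saturate_frac, 100 * (1 - p.saturate_frac)])
    # robust per-pixel noise scale from the median-filter residual
    noise = 1.4826 * np.median(np.abs(img - filt))
    if hi <= lo or hi - lo <= 8.0 * noise:
        warnings.warn("degenerate (blank or constant) frame: rescaled to all zeros")
        return np.zeros_like(filt)
    return np.clip((filt - lo) / (hi - lo), 0.0, 1.0)


def axial_profile(image: np.ndarray, channel_axis: int = 0) -> np.ndarray:
    """Mean intensity across the channel width at each axial position."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    return img.mean(axis=1 - channel_axis)


def detect_boundaries(
    profile: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Cell-cell boundary positions: prominent minima of the axial profile.

    Minima must be at least ``min_prominence`` of the profile maximum
    deep, pairwise at least ``min_boundary_distance_px`` apart, and lie
    above ``threshold_rel`` of the profile maximum (minima down in the
    background do not separate cells). Anchoring prominence to the
    profile maximum rather than to max-min keeps the criterion stable
    when the channel is completely filled with cells and the profile's
    dynamic range collapses.
    """
    p = params if params is not None else SegmentationParams()
    prof = np.asarray(profile, dtype=float)
    if prof.size < 3 or prof.max() <= prof.min():
        return np.array([], dtype=int)
    minima, _ = signal.find_peaks(
        -prof,
        prominence=p.min_prominence * prof.max(),
        distance=p.min_boundary_distance_px,
    )
    keep = prof[minima] >= p.threshold_rel * prof.max()
    minima = minima[keep]
    # Boundaries are reported as split indices: the axial row where the
    # next cell starts. A parabola through the minimum and its neighbours
    # locates the septum centre at sub-pixel precision (profile index m
    # is the centre of pixel [m, m+1), hence the +0.5), removing the
    # half-pixel bias of the discrete argmin.
    splits = []
    for m in minima:
        pos = float(m)
        if 0 < m < len(prof) - 1:
            yl, yc, yr = prof[m - 1], prof[m], prof[m + 1]
            denom = yl - 2 * yc + yr
            if denom > 0:
                pos = m + 0.5 * (yl - yr) / denom
        splits.append(int(round(pos + 0.5)))
    return np.sort(np.unique(splits)).astype(int)


def make_masks(
    rescaled_image: np.ndarray,
    boundaries: np.ndarray,
    params: SegmentationParams | None = None,
) -> list[np.ndarray]:
    """Split the relative-threshold foreground into per-cell binary masks.

    Foreground pixels are those at or above ``threshold_rel`` times the
    frame maximum. Boundaries partition the channel axis (axis 0 here)
    into half-open intervals; within each, the largest connected
    foreground component is one cell. Intervals without foreground yield
    no cell.
    """
    from skimage import measure as skmeasure

    p = params if params is not None else SegmentationParams()
    img = np.asarray(rescaled_image, dtype=float)
    peak = img.max()
    if peak <= 0:
        return []
    fg = img >= p.threshold_rel * peak
    edges = np.concatenate(([0], np.asarray(boundaries, dtype=int), [img.shape[0]]))
    masks: list[np.ndarray] = []
    for start, end in zip(edges[:-1], edges[1:]):
        if end <= start:
            continue
        section = np.zeros_like(fg)
        section[start:end] = fg[start:end]
        if not section.any():
            continue
        labels = skmeasure.label(section, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        largest = counts.argmax()
        masks.append(labels == largest)
    return masks


def _moment_length(mask: np.ndarray, method: str) -> float:
    """Moment-based length of a binary mask along its dominant axis.

    Each pixel is treated as a unit square (adds 1/12 to each marginal
    variance, so a single pixel has length 1). "rod" returns
    sqrt(12 * axial variance) — exact for a filled axis-aligned rod;
    "ellipse" returns the major-axis length of the equal-second-moments
    ellipse, 4 * sqrt(largest covariance eigenvalue).
    """
    ax, tr = np.nonzero(mask)
    pts = np.stack([ax, tr]).astype(float)
    cov = np.cov(pts, bias=True).reshape(2, 2) + np.eye(2) / 12.0
    if method == "rod":
        return float(np.sqrt(12.0 * cov[0, 0]))
    eigval = np.linalg.eigvalsh(cov)[-1]
    return float(4.0 * np.sqrt(eigval))


def measure_cell(
    mask: np.ndarray,
    raw_image: np.ndarray,
    params: SegmentationParams | None = None,
    index_from_closed_end: int = 0,
) -> CellMeasurement:
    """Measure one cell: moment length plus raw-intensity fluorescence.

    Fluorescence uses the raw (pre-rescale) intensities so totals and
    means are comparable across frames; the rescaled image only shapes
    the mask.
    """
    p = params if params is not None else SegmentationParams()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MeasurementError("cannot measure an empty mask")
    raw = np.asarray(raw_image, dtype=float)
    area = int(mask.sum())
    total = float(raw[mask].sum())
    ax = np.nonzero(mask)[0]
    return CellMeasurement(
        index_from_closed_end=index_from_closed_end,
        length=_moment_length(mask, p.length_method),
        area_px=area,
        total_fluor=total,
        mean_fluor=total / area,
        axial_span=(int(ax.min()), int(ax.max()) + 1),
    )


def segment_frame(
    image: np.ndarray,
    params: SegmentationParams | None = None,
    channel_axis: int = 0,
    closed_end: str = "low",
) -> FrameSegmentation:
    """Segment one frame; cells are ordered from the closed end (mother first).

    Axial spans are reported in the coordinates of the input frame, so a
    mirrored frame (closed end at the far index) yields identical
    measurements with mirrored spans.
    """
    p = params if params is not None else SegmentationParams()
    img = np.asarray(image, dtype=float)
    if channel_axis == 1:
        img = img.T
    flipped = closed_end == "high"
    if flipped:
        img = img[::-1]

    rescaled = preprocess_frame(img, p)
    profile = axial_profile(rescaled, channel_axis=0)
    boundaries = detect_boundaries(profile, p)
    masks = make_masks(rescaled, boundaries, p)

    n_axial = img.shape[0]
    cells = []
    for idx, mask in enumerate(masks):
        m = measure_cell(mask, img, p, index_from_closed_end=idx)
        if flipped:
            s, e = m.axial_span
            m.axial_span = (n_axial - e, n_axial - s)
        cells.append(m)
    return FrameSegmentation(cells=cells)


def segment_stack(
    stack: TimeLapseStack, params: SegmentationParams | None = None
) -> MotherSeries:
    """Segment every frame and extract the mother-cell series.

    Frames where no mother is found become gaps flagged for review (no
    silent interpolation — the original workflow corrected such frames
    manually). A stack with more than 50% gap frames raises
    :class:`PipelineError`.
    """
    p = params if params is not None else SegmentationParams()
    n = stack.n_frames
    length = np.full(n, np.nan)
    total = np.full(n, np.nan)
    mean = np.full(n, np.nan)
    gaps = np.zeros(n, dtype=bool)
    measurements: list[CellMeasurement | None] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate frames become gaps, not noise
        for i in range(n):
            seg = segment_frame(
                stack.frames[i], p, channel_axis=stack.channel_axis,
                closed_end=stack.closed_end,
            )
            mother = seg.mother
            if mother is None:
                gaps[i] = True
                measurements.append(None)
                continue
            length[i] = mother.length
            total[i] = mother.total_fluor
            mean[i] = mother.mean_fluor
            measurements.append(mother)
    if gaps.sum() > 0.5 * n:
        raise PipelineError(
            f"unusable stack: mother missing in {int(gaps.sum())}/{n} frames"
        )
    return MotherSeries(
        time=stack.times.copy(),
        length=length,
        total_fluor=total,
        mean_fluor=mean,
        gap_flags=gaps,
        measurements=measurements,
    )
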