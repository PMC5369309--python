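"""Division detection and cell-cycle assembly from mother length series.

A division shows up in the per-minute length series as an abrupt large
drop (a symmetric division halves the length); detection therefore flags
frames where the length falls by at least ``min_drop_frac`` relative to
the previous frame, subject to a refractory period of ``refractory_min``
minutes between consecutive divisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MotherTrace

__all__ = [
    "DivisionParams",
    "CellCycle",
    "DivisionMetrics",
    "detect_divisions",
    "assemble_cycles",
    "division_metrics",
]


@dataclass
class DivisionParams:
    """min_drop_frac: minimal fractional length decrease between consecutive
    frames to call a division; refractory_min: minimum minutes between
    divisions."""

    min_drop_frac: float = 0.25
    refractory_min: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.min_drop_frac < 1):
            raise ValueError("min_drop_frac must lie in (0, 1)")
        if self.refractory_min < 0:
            raise ValueError("refractory_min must be >= 0")


@dataclass
class CellCycle:
    """One birth-to-division interval of the mother.

    L_b is the length at the first post-division frame; L_d the length at
    the last frame before the next division drop.
    """

    birth_time: float
    division_time: float
    L_b: float
    L_d: float
    duration: float
    mean_cycle_fluor: float = float("nan")
    filament_flag: bool = False
    undersize_flag: bool = False
    gap_frames: int = 0


@dataclass
class DivisionMetrics:
    precision: float
    recall: float
    f1: float
    n_true: int
    n_detected: int
    n_matched: int
    degenerate: bool = False  # True when precision/recall was undefined (0/0)


def detect_divisions(
    length_series: np.ndarray,
    times: np.ndarray,
    params: DivisionParams | None = None,
) -> np.ndarray:
    """Flag division frames in a length series.

    A frame t is flagged iff length(t)/length(t-1) <= 1 - min_drop_frac
    and no earlier flag lies within the preceding refractory window
    (divisions are assumed at least ``refractory_min`` minutes apart);
    among conflicting candidates the earliest wins.
    """
    p = params if params is not None else DivisionParams()
    length = np.asarray(length_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if length.shape != times.shape:
        raise ValueError("length series and times must have equal shape")
    n = len(length)
    flags = np.zeros(n, dtype=int)
    if n < 2:
        return flags
    if not (length > 0).all():
        raise ValueError("length series must be positive (carry gaps upstream)")
    last_flag_time = -np.inf
    for i in range(1, n):
        if (
            length[i] / length[i - 1] <= 1.0 - p.min_drop_frac
            and times[i] - last_flag_time >= p.refractory_min
        ):
            flags[i] = 1
            last_flag_time = times[i]
    return flags


def assemble_cycles(
    trace: MotherTrace, gap_flags: np.ndarray | None = None
) -> list[CellCycle]:
    """Cut the flagged trace into complete cell cycles.

    Each cycle spans one inter-division interval; the partial stretches
    before the first and after the last division are discarded. Cycles
    containing more than 2 consecutive QC-gap frames are dropped; cycles
    with fewer gaps are kept with ``gap_frames`` recorded.
    """
    flags_idx = np.nonzero(trace.division_flag == 1)[0]
    cycles: list[CellCycle] = []
    if len(flags_idx) < 2:
        return cycles
    for start, nxt in zip(flags_idx[:-1], flags_idx[1:]):
        gap_count = 0
        max_run = 0
        if gap_flags is not None:
            window = np.asarray(gap_flags[start:nxt], dtype=bool)
            gap_count = int(window.sum())
            run = 0
            for g in window:
                run = run + 1 if g else 0
                max_run = max(max_run, run)
        if max_run > 2:
            continue
        cycles.append(
            CellCycle(
                birth_time=float(trace.time[start]),
                division_time=float(trace.time[nxt]),
                L_b=float(trace.length[start]),
                L_d=float(trace.length[nxt - 1]),
                duration=float(trace.time[nxt] - trace.time[start]),
                mean_cycle_fluor=float(np.mean(trace.mean_fluor[start:nxt])),
                gap_frames=gap_count,
            )
        )
    return cycles


def division_metrics(
    detected_times: np.ndarray,
    true_division_times: np.ndarray,
    tolerance_frames: int = 1,
    dt_minutes: float = 1.0,
) -> DivisionMetrics:
    """Precision/recall/F1 of detected divisions against ground truth.

    A detection matches a true event if within ±tolerance_frames frames;
    matching is one-to-one and greedy in time order. Undefined ratios
    (no detections or no truth) are reported as 0 with the degenerate
    flag set.
    """
    det = np.sort(np.asarray(detected_times, dtype=float))
    tru = np.sort(np.asarray(true_division_times, dtype=float))
    tol = tolerance_frames * dt_minutes + 1e-9
    i = j = matched = 0
    while i < len(det) and j < len(tru):
        if abs(det[i] - tru[j]) <= tol:
            matched += 1
            i += 1
            j += 1
        elif det[i] < tru[j]:
            i += 1
        else:
            j += 1
    degenerate = len(det) == 0 or len(tru) == 0
    precision = matched / len(det) if len(det) else 0.0
    recall = matched / len(tru) if len(tru) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return DivisionMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        n_true=len(tru),
        n_detected=len(det),
        n_matched=matched,
        degenerate=degenerate,
    )
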