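"""Downstream analyses: the noisy-linear-map fit and validation harnesses.

The central statistic is the ordinary least-squares fit of division
length on birth length, L_d = a·L_b + b + η — the "noisy linear map" of
cell-size homeostasis (a = 1 would be a pure adder in disguise only for
the increment parameterisation; here a < 1 means size control, with
fixed-point birth size r·b/(1 − a·r) for division ratio r). The module
also implements the two-threshold segmentation-consistency check and an
end-to-end recovery report against simulator ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .io_formats import MotherTrace, TimeLapseStack
from .lineage import CellCycle, DivisionMetrics, division_metrics
from .segmentation import SegmentationParams, segment_stack
from .simulator import GroundTruthLineage

__all__ = [
    "LinearMapFit",
    "ConsistencyResult",
    "RecoveryReport",
    "DegenerateDesignError",
    "InsufficientDataError",
    "AlignmentError",
    "fit_noisy_linear_map",
    "threshold_consistency",
    "recovery_report",
    "birth_size_autocorrelation",
]


class DegenerateDesignError(ValueError):
    """Raised when all birth lengths coincide (slope not identifiable)."""


class InsufficientDataError(ValueError):
    """Raised when too few paired frames/cycles exist for an analysis."""


class AlignmentError(ValueError):
    """Raised when trace and ground truth do not share a time base."""


@dataclass
class LinearMapFit:
    """OLS fit of L_d on L_b with residual noise scale.

    resid_sd (n−2 denominator) estimates the s.d. of the map noise η.
    saturated marks an exact two-point interpolation, where resid_sd is
    undefined (reported as NaN).
    """

    a_hat: float
    b_hat: float
    resid_sd: float
    r_squared: float
    n_cycles: int
    a_se: float
    b_se: float
    saturated: bool = False

    def to_dict(self) -> dict:
        return {
            "a_hat": self.a_hat,
            "b_hat": self.b_hat,
            "resid_sd": self.resid_sd,
            "r_squared": self.r_squared,
            "n_cycles": self.n_cycles,
            "a_se": self.a_se,
            "b_se": self.b_se,
            "saturated": self.saturated,
        }


@dataclass
class ConsistencyResult:
    """Two-threshold segmentation comparison across paired frames."""

    r_squared_length: float
    r_squared_mean_fluor: float
    slope_length: float
    intercept_length: float
    slope_fluor: float
    intercept_fluor: float
    n_frames: int
    length_larger_at_low: bool   # median length(thr_low) >= median length(thr_high)
    fluor_lower_at_low: bool     # median mean_fluor(thr_low) <= at thr_high

    def to_dict(self) -> dict:
        return {
            "r_squared_length": self.r_squared_length,
            "r_squared_mean_fluor": self.r_squared_mean_fluor,
            "slope_length": self.slope_length,
            "intercept_length": self.intercept_length,
            "slope_fluor": self.slope_fluor,
            "intercept_fluor": self.intercept_fluor,
            "n_frames": self.n_frames,
            "length_larger_at_low": self.length_larger_at_low,
            "fluor_lower_at_low": self.fluor_lower_at_low,
        }


@dataclass
class RecoveryReport:
    """End-to-end pipeline accuracy against simulator ground truth."""

    length_rmse_px: float
    division: DivisionMetrics
    lb_mae_px: float
    ld_mae_px: float
    n_matched_cycles: int
    a_err: float
    b_err: float


def _extract_lb_ld(cycles) -> tuple[np.ndarray, np.ndarray]:
    if len(cycles) and hasattr(cycles[0], "L_b"):
        lb = np.array([c.L_b for c in cycles], dtype=float)
        ld = np.array([c.L_d for c in cycles], dtype=float)
    else:
        arr = np.asarray(cycles, dtype=float)
        lb, ld = arr[:, 0], arr[:, 1]
    return lb, ld


def fit_noisy_linear_map(cycles: Sequence[CellCycle]) -> LinearMapFit:
    """OLS fit of the noisy linear map to (L_b, L_d) pairs.

    Accepts a sequence of cycles (or an (n, 2) array of pairs). R² is the
    squared Pearson correlation of observed and fitted values. Two
    distinct points interpolate exactly (saturated fit, NaN residual
    s.d.); fewer than 2 points, or identical birth lengths, are errors.
    """
    lb, ld = _extract_lb_ld(cycles)
    ok = np.isfinite(lb) & np.isfinite(ld)
    lb, ld = lb[ok], ld[ok]
    n = len(lb)
    if n < 2:
        raise InsufficientDataError("need at least 2 cycles to fit the map")
    if np.ptp(lb) == 0:
        raise DegenerateDesignError("all birth lengths identical; slope undefined")
    res = sps.linregress(lb, ld)
    fitted = res.slope * lb + res.intercept
    ssr = float(np.sum((ld - fitted) ** 2))
    if n > 2:
        resid_sd = float(np.sqrt(ssr / (n - 2)))
        saturated = False
    else:
        resid_sd = float("nan")
        saturated = True
    return LinearMapFit(
        a_hat=float(res.slope),
        b_hat=float(res.intercept),
        resid_sd=resid_sd,
        r_squared=float(res.rvalue**2),
        n_cycles=n,
        a_se=float(res.stderr) if n > 2 else float("nan"),
        b_se=float(res.intercept_stderr) if n > 2 else float("nan"),
        saturated=saturated,
    )


def threshold_consistency(
    stack: TimeLapseStack,
    params: SegmentationParams | None = None,
    thr_low: float = 0.2,
    thr_high: float = 0.3,
) -> ConsistencyResult:
    """Segment a stack at two mask thresholds and compare the results.

    Mirrors the robustness check of re-analysing the images with a lower
    threshold: the series should be linearly related with R² near 1,
    with lengths no smaller and mean fluorescence no larger at the low
    threshold.
    """
    from dataclasses import replace

    if not thr_low < thr_high:
        raise ValueError("thr_low must be smaller than thr_high")
    p = params if params is not None else SegmentationParams()
    low = segment_stack(stack, replace(p, threshold_rel=thr_low))
    high = segment_stack(stack, replace(p, threshold_rel=thr_high))
    paired = ~(low.gap_flags | high.gap_flags)
    n = int(paired.sum())
    if n < 10:
        raise InsufficientDataError(f"only {n} paired frames; need at least 10")

    def _reg(y_low: np.ndarray, y_high: np.ndarray):
        res = sps.linregress(y_high[paired], y_low[paired])
        return res.rvalue**2, res.slope, res.intercept

    r2_len, sl_len, ic_len = _reg(low.length, high.length)
    r2_fl, sl_fl, ic_fl = _reg(low.mean_fluor, high.mean_fluor)
    return ConsistencyResult(
        r_squared_length=float(r2_len),
        r_squared_mean_fluor=float(r2_fl),
        slope_length=float(sl_len),
        intercept_length=float(ic_len),
        slope_fluor=float(sl_fl),
        intercept_fluor=float(ic_fl),
        n_frames=n,
        length_larger_at_low=bool(
            np.median(low.length[paired]) >= np.median(high.length[paired])
        ),
        fluor_lower_at_low=bool(
            np.median(low.mean_fluor[paired]) <= np.median(high.mean_fluor[paired])
        ),
    )


def recovery_report(
    trace: MotherTrace,
    cycles: Sequence[CellCycle],
    truth: GroundTruthLineage,
    tolerance_frames: int = 1,
) -> RecoveryReport:
    """Compare a measured trace and its cycles against simulator truth.

    Reports per-frame length RMSE, division precision/recall/F1 at the
    given frame tolerance, mean absolute errors of matched per-cycle
    birth/division lengths, and the difference between map fits on the
    measured and the true cycles.
    """
    if len(trace.time) != len(truth.times) or not np.allclose(
        trace.time, truth.times
    ):
        raise AlignmentError("trace and ground truth do not share a time base")
    dt = float(np.median(np.diff(truth.times))) if len(truth.times) > 1 else 1.0
    rmse = float(np.sqrt(np.mean((trace.length - truth.length) ** 2)))
    det_times = trace.time[trace.division_flag == 1]
    div = division_metrics(
        det_times, truth.division_times, tolerance_frames=tolerance_frames,
        dt_minutes=dt,
    )
    # match cycles to true cycles on birth time (within 2 frames)
    lb_err, ld_err = [], []
    true_by_birth = {c.birth_time: c for c in truth.cycles}
    true_births = np.array(sorted(true_by_birth))
    for c in cycles:
        if len(true_births) == 0:
            break
        k = int(np.argmin(np.abs(true_births - c.birth_time)))
        if abs(true_births[k] - c.birth_time) <= 2 * dt + 1e-9:
            tc = true_by_birth[true_births[k]]
            lb_err.append(abs(c.L_b - tc.L_b))
            # measured L_d is the last pre-division snapshot; the true
            # pre-split length sits up to one frame's growth above it
            ld_err.append(abs(c.L_d - tc.L_d))
    a_err = b_err = float("nan")
    if len(cycles) >= 3 and len(truth.cycles) >= 3:
        fit_meas = fit_noisy_linear_map(cycles)
        fit_true = fit_noisy_linear_map(truth.cycles)
        a_err = fit_meas.a_hat - fit_true.a_hat
        b_err = fit_meas.b_hat - fit_true.b_hat
    return RecoveryReport(
        length_rmse_px=rmse,
        division=div,
        lb_mae_px=float(np.mean(lb_err)) if lb_err else float("nan"),
        ld_mae_px=float(np.mean(ld_err)) if ld_err else float("nan"),
        n_matched_cycles=len(lb_err),
        a_err=float(a_err),
        b_err=float(b_err),
    )


def birth_size_autocorrelation(
    cycles: Sequence[CellCycle], max_lag: int = 20
) -> np.ndarray:
    """Autocorrelation of the birth-size sequence over generation lags.

    A descriptive utility for eyeballing transient size oscillations;
    returns the normalised autocorrelation at lags 0..max_lag.
    """
    lb, _ = _extract_lb_ld(cycles)
    lb = lb - lb.mean()
    n = len(lb)
    if n < 2:
        raise InsufficientDataError("need at least 2 cycles")
    denom = float(np.dot(lb, lb))
    lags = min(max_lag, n - 1)
    return np.array(
        [np.dot(lb[: n - k], lb[k:]) / denom for k in range(lags + 1)]
    )
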