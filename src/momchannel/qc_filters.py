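"""Cell-cycle quality filters: filamentation, undersize, lineage selection.

A cycle is filamentous when its initial length exceeds L̄ + 2σ_L or its
final length exceeds 2(L̄ + 2σ_L), and undersized when its initial
length falls below L̄ − 2σ_L, where L̄ and σ_L summarise the cell-size
distribution of the experiment. The statistics are computed once on the
unfiltered cycle set and frozen (single pass, no iterative
re-filtering), so filtering the kept set again with the same statistics
excludes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .lineage import CellCycle

__all__ = [
    "LengthStats",
    "FilterResult",
    "StatsError",
    "FilterError",
    "length_stats",
    "flag_filamentous",
    "flag_undersize",
    "filter_cycles",
    "select_full_lineages",
]

BASES = ("frame_lengths", "birth_lengths", "endpoint_lengths")


class StatsError(ValueError):
    """Raised when too few observations exist to form length statistics."""


class FilterError(ValueError):
    """Raised when filtering is requested on an empty cycle set."""


@dataclass
class LengthStats:
    """Mean and s.d. of the chosen cell-size observable."""

    L_bar: float
    sigma_L: float
    n: int
    basis: str

    @property
    def upper(self) -> float:
        return self.L_bar + 2.0 * self.sigma_L

    @property
    def lower(self) -> float:
        return self.L_bar - 2.0 * self.sigma_L


@dataclass
class FilterResult:
    kept: list[CellCycle]
    excluded: list[CellCycle]
    fraction_excluded: float
    stats: LengthStats
    report: list[tuple[int, str]] = field(default_factory=list)  # (index, rule)


def _basis_values(
    cycles: Sequence[CellCycle], basis: str, dt_minutes: float
) -> np.ndarray:
    if basis == "birth_lengths":
        return np.array([c.L_b for c in cycles], dtype=float)
    if basis == "endpoint_lengths":
        return np.array([v for c in cycles for v in (c.L_b, c.L_d)], dtype=float)
    if basis == "frame_lengths":
        # Instantaneous sizes at every frame of every cycle, reconstructed
        # by geometric interpolation between L_b and L_d — exact under
        # exponential growth, which is also how measured cycles behave.
        vals: list[np.ndarray] = []
        for c in cycles:
            k = max(int(round(c.duration / dt_minutes)), 1)
            frac = np.arange(k) / k
            vals.append(c.L_b * (c.L_d / c.L_b) ** frac)
        return np.concatenate(vals) if vals else np.array([], dtype=float)
    raise ValueError(f"unknown basis {basis!r}; choose one of {BASES}")


def length_stats(
    cycles: Sequence[CellCycle],
    basis: str = "frame_lengths",
    dt_minutes: float = 1.0,
) -> LengthStats:
    """Mean and unbiased s.d. of the cell-size distribution.

    The default basis pools the instantaneous per-frame sizes of all
    cycles, so the distribution spans birth-to-division sizes; bases over
    birth lengths only or over both cycle endpoints are selectable.
    """
    if len(cycles) < 2:
        raise StatsError("need at least 2 cycles for length statistics")
    values = _basis_values(cycles, basis, dt_minutes)
    if len(values) < 2:
        raise StatsError("need at least 2 size observations")
    return LengthStats(
        L_bar=float(values.mean()),
        sigma_L=float(values.std(ddof=1)),
        n=len(values),
        basis=basis,
    )


def flag_filamentous(cycle: CellCycle, stats: LengthStats) -> bool:
    """True iff L_b > L̄+2σ_L or L_d > 2(L̄+2σ_L) (strict inequalities)."""
    return cycle.L_b > stats.upper or cycle.L_d > 2.0 * stats.upper


def flag_undersize(cycle: CellCycle, stats: LengthStats) -> bool:
    """True iff L_b < L̄−2σ_L (strict inequality)."""
    return cycle.L_b < stats.lower


def filter_cycles(
    cycles: Sequence[CellCycle],
    basis: str = "frame_lengths",
    stats: LengthStats | None = None,
    dt_minutes: float = 1.0,
) -> FilterResult:
    """Apply both exclusion rules to one experiment's cycles.

    Statistics are computed once over the full (unfiltered) input unless
    frozen statistics are supplied. Flags are written onto the cycles;
    the report lists each exclusion with the rule that fired.
    """
    if len(cycles) == 0:
        raise FilterError("cannot filter an empty cycle set")
    if stats is None:
        stats = length_stats(cycles, basis=basis, dt_minutes=dt_minutes)
    kept: list[CellCycle] = []
    excluded: list[CellCycle] = []
    report: list[tuple[int, str]] = []
    for i, c in enumerate(cycles):
        c.filament_flag = flag_filamentous(c, stats)
        c.undersize_flag = flag_undersize(c, stats)
        if c.filament_flag:
            report.append((i, "filamentous"))
            excluded.append(c)
        elif c.undersize_flag:
            report.append((i, "undersize"))
            excluded.append(c)
        else:
            kept.append(c)
    return FilterResult(
        kept=kept,
        excluded=excluded,
        fraction_excluded=len(excluded) / len(cycles),
        stats=stats,
        report=report,
    )


def select_full_lineages(
    lineage_lengths: Mapping[object, int],
    required_generations: int = 70,
) -> list:
    """Ids of lineages with at least ``required_generations`` full cycles."""
    return [
        lid for lid, n in lineage_lengths.items() if n >= required_generations
    ]
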