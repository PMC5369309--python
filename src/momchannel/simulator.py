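"""Synthetic mother-machine channel time-lapse generator with ground truth.

The simulated biology is deliberately minimal but captures what the
downstream pipeline must measure:

* every cell elongates exponentially, ``L(t) = L_b * exp(lambda * t)``;
* division follows a noisy linear map: a cell born at length ``L_b``
  divides when it first reaches ``L_d = a * L_b + b + eta`` (on the frame
  grid), ``eta ~ Normal(0, eta_sd)``, and the mother keeps a fraction
  ``r ~ Normal(ratio_mean, ratio_sd)`` of the divided length;
* a per-cycle filamentation probability models division failure: the cell
  elongates to ``filament_factor`` times its drawn division length before
  recovering, and on recovery it divides at two septa so the retained
  mother is of ordinary birth size again;
* fluorescence concentration fluctuates as a discrete
  Ornstein--Uhlenbeck process with a correlation time longer than the
  cell cycle, emulating slowly varying constitutive expression. The
  slow fluctuation is shared by all cells in the channel (they are
  recent kin in a common microenvironment); cells individually carry a
  partition offset inherited at birth, so neighbours are bright or dim
  together but not identical.

Rendering draws each cell as a filled rod (axial top-hat times
transverse top-hat, area-weighted at sub-pixel edges; mother-machine
cells are slightly compressed by the channel walls, so their projection
is close to uniform across the width). A 2 px band at each cell-cell
interface is dimmed by ``septum_dip``; a Gaussian PSF blur, background,
optional Poisson shot noise and Gaussian read noise are applied before
quantisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io_formats import TimeLapseStack

__all__ = [
    "GrowthParams",
    "OpticsParams",
    "CellState",
    "TrueCycle",
    "GroundTruthLineage",
    "SimulationParameterError",
    "simulate_lineage",
    "render_frame",
    "simulate_stack",
    "write_ground_truth",
]

LN2 = math.log(2.0)


class SimulationParameterError(ValueError):
    """Raised when growth or optics parameters violate their invariants."""


@dataclass
class GrowthParams:
    """Single-cell growth, division and fluorescence parameters.

    Defaults emulate fast (37 °C-like) E. coli growth on a ~0.1 µm/px
    scale: a 25 min doubling time, mean birth length 25 px and division
    length 50 px. ``a``/``b``/``eta_sd`` parameterise the noisy linear
    map L_d = a*L_b + b + eta; with ``a = 0.5`` and ``b = 37.5`` the
    map's fixed point puts the mean birth length at
    r*b/(1 - a*r) = 25 px. ``eta_sd = 2.5`` px is 5% of the mean
    division length. Fluorescence concentration is an OU process with a
    100 min correlation time, i.e. slower than the cell cycle.
    """

    lam: float = LN2 / 25.0        # elongation rate, 1/min
    a: float = 0.5                 # division-map slope
    b: float = 37.5                # division-map intercept, px
    eta_sd: float = 2.5            # s.d. of additive division noise, px
    ratio_mean: float = 0.5        # fraction of L_d kept by the mother
    ratio_sd: float = 0.02
    L0: float = 25.0               # mother length at t = 0, px
    filament_prob: float = 0.006   # per-cycle probability of filamentation
    filament_factor: float = 2.5   # elongation factor beyond L_d while filamentous
    fluor_mean: float = 100.0      # mean fluorescence concentration, a.u.
    fluor_sd: float = 10.0
    fluor_tau: float = 100.0       # OU correlation time, min
    channel_length: float = 150.0  # px; cells pushed past this are flushed

    def validate(self) -> None:
        if not self.lam > 0:
            raise SimulationParameterError("elongation rate lam must be > 0")
        if not (0 < self.ratio_mean < 1):
            raise SimulationParameterError("ratio_mean must lie in (0, 1)")
        if not abs(self.a * self.ratio_mean) < 1:
            raise SimulationParameterError(
                "unstable division map: require |a * ratio_mean| < 1"
            )
        if self.eta_sd < 0 or self.ratio_sd < 0:
            raise SimulationParameterError("noise s.d. must be >= 0")
        if not (0 <= self.filament_prob <= 1):
            raise SimulationParameterError("filament_prob must lie in [0, 1]")
        if self.filament_factor <= 1:
            raise SimulationParameterError("filament_factor must be > 1")
        if not self.fluor_tau > 0:
            raise SimulationParameterError("fluor_tau must be > 0")
        if self.L0 <= 0 or self.b < 0:
            raise SimulationParameterError("L0 must be > 0 and b >= 0")


@dataclass
class OpticsParams:
    """Rendering model: geometry, PSF, intensity scale and noise."""

    channel_length_px: int = 150
    channel_width_px: int = 15
    cell_width_px: float = 7.5
    psf_sigma_px: float = 1.0
    background: float = 200.0
    gain: float = 30.0             # intensity counts per concentration unit
    septum_dip: float = 0.4        # fractional dimming at cell-cell interfaces
    read_noise_sd: float = 50.0
    shot_noise: bool = True
    bit_depth: int = 16

    def validate(self) -> None:
        if min(self.channel_length_px, self.channel_width_px) <= 0:
            raise SimulationParameterError("channel geometry must be positive")
        if not (0 < self.cell_width_px < self.channel_width_px):
            raise SimulationParameterError(
                "cell_width_px must be positive and below channel_width_px"
            )
        if not (0 <= self.septum_dip < 1):
            raise SimulationParameterError("septum_dip must lie in [0, 1)")
        if self.psf_sigma_px < 0 or self.read_noise_sd < 0:
            raise SimulationParameterError("psf/noise parameters must be >= 0")
        if self.background < 0 or self.gain <= 0:
            raise SimulationParameterError("background >= 0 and gain > 0 required")
        if self.bit_depth not in (8, 16):
            raise SimulationParameterError("bit_depth must be 8 or 16")

    @property
    def max_intensity(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass
class CellState:
    """One cell in the channel at one instant (positions from the closed end)."""

    start: float    # axial position of the pole nearer the closed end, px
    length: float   # px
    fluor: float    # fluorescence concentration, a.u.


@dataclass
class TrueCycle:
    """One complete birth-to-division interval of the mother, from truth."""

    birth_time: float
    division_time: float
    L_b: float        # length at birth (just after the previous division)
    L_d: float        # length immediately before this cycle's division
    duration: float
    filament: bool = False


@dataclass
class GroundTruthLineage:
    """Per-minute truth for the mother plus per-cycle and whole-channel state."""

    times: np.ndarray
    length: np.ndarray            # mother length; post-division value at flags
    division_flags: np.ndarray    # 0/1 per frame
    mean_fluor: np.ndarray        # mother fluorescence concentration
    cycles: list[TrueCycle]
    cells_per_frame: list[list[CellState]]

    @property
    def division_times(self) -> np.ndarray:
        return self.times[self.division_flags == 1]

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


class _Cell:
    """Mutable simulation state for one cell (module-internal)."""

    __slots__ = ("length", "fluor", "target", "filament")

    def __init__(self, length: float, fluor: float, target: float, filament: bool):
        self.length = length
        self.fluor = fluor
        self.target = target
        self.filament = filament


def _draw_target(L_b: float, p: GrowthParams, rng: np.random.Generator) -> tuple[float, bool]:
    """Division length from the noisy linear map; filamentous with prob p."""
    target = p.a * L_b + p.b + rng.normal(0.0, p.eta_sd)
    target = max(target, 1.05 * L_b)  # guard: division length must exceed birth length
    filament = rng.random() < p.filament_prob
    if filament:
        target *= p.filament_factor
    return target, filament


def _draw_ratio(p: GrowthParams, rng: np.random.Generator) -> float:
    r = rng.normal(p.ratio_mean, p.ratio_sd)
    return float(np.clip(r, 0.2, 0.8))


def simulate_lineage(
    growth: GrowthParams | None = None,
    n_generations: int = 70,
    dt_minutes: float = 1.0,
    seed: int = 0,
) -> GroundTruthLineage:
    """Simulate one mother lineage until ``n_generations`` complete cycles.

    The simulation steps on the frame grid (one frame per ``dt_minutes``).
    Division is assigned to the first frame at which the true length has
    reached the drawn division length, matching per-minute snapshot
    observation; the recorded length at a division frame is the
    post-division (birth) length, so the series shows the division drop
    at the flagged frame. The interval before the first division is a
    partial cycle and is not counted.

    Deterministic for a fixed seed: all stochastic draws pass through one
    seeded generator.
    """
    p = growth if growth is not None else GrowthParams()
    p.validate()
    if n_generations < 1:
        raise SimulationParameterError("n_generations must be >= 1")
    rng = np.random.default_rng(seed)

    gf = math.exp(p.lam * dt_minutes)            # per-frame growth factor
    phi = math.exp(-dt_minutes / p.fluor_tau)    # OU autoregression coefficient
    ou_innov = p.fluor_sd * math.sqrt(1.0 - phi * phi)

    mother_fluor = max(rng.normal(p.fluor_mean, p.fluor_sd), 0.0)
    target0, fil0 = _draw_target(p.L0, p, rng)
    cells: list[_Cell] = [_Cell(p.L0, mother_fluor, target0, fil0)]

    times: list[float] = [0.0]
    lengths: list[float] = [p.L0]
    flags: list[int] = [0]
    fluors: list[float] = [mother_fluor]
    frame_cells: list[list[CellState]] = [_snapshot(cells)]
    cycles: list[TrueCycle] = []

    # the first division opens cycle 1; we need n_generations+1 divisions
    birth_time: float | None = None
    birth_length = p.L0
    cycle_filament = fil0
    last_div_time = -math.inf
    t = 0.0
    max_frames = int(5e6)

    for _ in range(max_frames):
        if len(cycles) >= n_generations:
            break
        t += dt_minutes
        # grow and fluctuate; the OU innovation is drawn once per frame and
        # shared by all cells in the channel
        z = rng.normal(0.0, ou_innov)
        for c in cells:
            c.length *= gf
            c.fluor = max(p.fluor_mean + phi * (c.fluor - p.fluor_mean) + z, 0.0)
        # divisions, closed end first; mother division needs >= 2 frames spacing
        divided_mother = False
        i = 0
        while i < len(cells):
            c = cells[i]
            if c.length >= c.target and not (
                i == 0 and t - last_div_time < 2 * dt_minutes
            ):
                r = _draw_ratio(p, rng)
                if c.filament:
                    r /= 2.0  # recovery divides at two septa
                L_d = c.length
                kept = r * L_d
                shed = L_d - kept
                t_new, fil_new = _draw_target(kept, p, rng)
                d_fluor = max(c.fluor + rng.normal(0.0, p.fluor_sd / 3.0), 0.0)
                d_target, d_fil = _draw_target(shed, p, rng)
                if i == 0:
                    divided_mother = True
                    if birth_time is not None:
                        cycles.append(
                            TrueCycle(
                                birth_time=birth_time,
                                division_time=t,
                                L_b=birth_length,
                                L_d=L_d,
                                duration=t - birth_time,
                                filament=cycle_filament,
                            )
                        )
                    birth_time = t
                    birth_length = kept
                    cycle_filament = fil_new
                    last_div_time = t
                kept_cell = _Cell(kept, c.fluor, t_new, fil_new)
                shed_cell = _Cell(shed, d_fluor, d_target, d_fil)
                cells[i : i + 1] = [kept_cell, shed_cell]
                i += 2
            else:
                i += 1
        # flush cells pushed fully past the channel end
        pos = 0.0
        keep: list[_Cell] = []
        for c in cells:
            if pos < p.channel_length:
                keep.append(c)
            pos += c.length
        cells = keep

        times.append(t)
        lengths.append(cells[0].length)
        flags.append(1 if divided_mother else 0)
        fluors.append(cells[0].fluor)
        frame_cells.append(_snapshot(cells))
    else:
        raise RuntimeError("simulation did not reach the requested generation count")

    return GroundTruthLineage(
        times=np.asarray(times),
        length=np.asarray(lengths),
        division_flags=np.asarray(flags, dtype=int),
        mean_fluor=np.asarray(fluors),
        cycles=cycles,
        cells_per_frame=frame_cells,
    )


def _snapshot(cells: list[_Cell]) -> list[CellState]:
    out = []
    pos = 0.0
    for c in cells:
        out.append(CellState(start=pos, length=c.length, fluor=c.fluor))
        pos += c.length
    return out


# ---------------------------------------------------------------------------
# Rendering


def _coverage(n: int, lo: float, hi: float) -> np.ndarray:
    """Fraction of each unit pixel [i, i+1) covered by the interval [lo, hi)."""
    edges = np.arange(n + 1, dtype=float)
    return np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, 1.0)


def render_frame(
    cells_at_t: list[CellState],
    optics: OpticsParams | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one channel frame (channel axis 0, closed end at row 0).

    With ``psf_sigma_px = 0`` and noise off, a single cell renders as an
    axial top-hat of its true pixel length; abutting cells are separated
    by a 2 px intensity dip of fractional depth ``septum_dip``.
    """
    o = optics if optics is not None else OpticsParams()
    o.validate()
    L, W = o.channel_length_px, o.channel_width_px
    signal = np.zeros((L, W), dtype=float)

    t_lo = (W - o.cell_width_px) / 2.0
    trans = _coverage(W, t_lo, t_lo + o.cell_width_px)
    for c in cells_at_t:
        ax = _coverage(L, c.start, c.start + c.length)
        signal += (o.gain * c.fluor) * np.outer(ax, trans)

    if o.septum_dip > 0 and len(cells_at_t) > 1:
        dip = np.zeros(L, dtype=float)
        for prev, nxt in zip(cells_at_t, cells_at_t[1:]):
            iface = prev.start + prev.length
            if abs(nxt.start - iface) < 0.5 and 0 < iface < L:
                dip = np.maximum(dip, _coverage(L, iface - 1.0, iface + 1.0))
        signal *= (1.0 - o.septum_dip * dip)[:, None]

    if o.psf_sigma_px > 0:
        signal = ndimage.gaussian_filter(signal, o.psf_sigma_px, mode="reflect")

    img = o.background + signal
    if o.shot_noise:
        if rng is None:
            rng = np.random.default_rng()
        img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
    if o.read_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        img = img + rng.normal(0.0, o.read_noise_sd, size=img.shape)

    img = np.clip(np.rint(img), 0, o.max_intensity)
    return img.astype(np.uint8 if o.bit_depth == 8 else np.uint16)


def simulate_stack(
    growth: GrowthParams | None = None,
    optics: OpticsParams | None = None,
    n_generations: int = 10,
    seed: int = 0,
    dt_minutes: float = 1.0,
) -> tuple[TimeLapseStack, GroundTruthLineage]:
    """Simulate a lineage and render every frame; stack and truth share times.

    Bit-identical for a fixed seed. The lineage uses the seed directly, so
    the same seed yields the same truth regardless of optics; rendering
    noise uses an independent stream derived from the same seed.
    """
    g = growth if growth is not None else GrowthParams()
    o = optics if optics is not None else OpticsParams()
    o.validate()
    if abs(g.channel_length - o.channel_length_px) > 1e-9:
        g = replace(g, channel_length=float(o.channel_length_px))
    truth = simulate_lineage(g, n_generations=n_generations, dt_minutes=dt_minutes, seed=seed)
    render_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    frames = np.stack(
        [render_frame(cells, o, render_rng) for cells in truth.cells_per_frame]
    )
    stack = TimeLapseStack(
        frames=frames,
        times=truth.times.copy(),
        channel_axis=0,
        closed_end="low",
    )
    return stack, truth


def write_ground_truth(
    truth: GroundTruthLineage,
    frame_path: str | Path,
    cycle_path: str | Path,
) -> None:
    """Write truth as two tab-separated tables (per-frame and per-cycle)."""
    import pandas as pd

    pd.DataFrame(
        {
            "time": truth.times,
            "true_length": truth.length,
            "division_flag": truth.division_flags,
            "true_mean_fluor": truth.mean_fluor,
        }
    ).to_csv(frame_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "birth_time": c.birth_time,
                "division_time": c.division_time,
                "L_b": c.L_b,
                "L_d": c.L_d,
                "duration": c.duration,
                "filament": int(c.filament),
            }
            for c in truth.cycles
        ],
        columns=["birth_time", "division_time", "L_b", "L_d", "duration", "filament"],
    ).to_csv(cycle_path, sep="\t", index=False)
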