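"""Serpentine raster-scan exposure schedules and damage-spread models.

An unpatterned sheet target is rastered line by line: the *fast* axis steps
within a line and the *slow* axis steps between lines, with the fast
direction alternating per line (boustrophedon).  Everything downstream of
the schedule — time lags between spatial neighbours, the reach of a
damage-spread front, multiple hits on large crystals, conductive heating of
neighbouring positions — is a pure function of that schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .core import rng_from


class EmptyScanError(ValueError):
    """A scan with zero exposures was requested."""


class SingularSourceError(ValueError):
    """Conduction kernel evaluated at r = 0, t = 0."""


@dataclass(frozen=True)
class ScanGrid:
    """Raster-scan geometry and timing.

    ``step_fast``/``step_slow`` are the in-line and between-line spacings in
    µm, ``rate`` the exposure rate in Hz.  ``fast_axis`` records which
    laboratory axis the in-line translation uses; the schedule itself is
    axis-agnostic.
    """

    step_fast: float
    step_slow: float
    n_per_line: int
    n_lines: int
    rate: float
    fast_axis: Literal["x", "y"] = "x"

    def __post_init__(self) -> None:
        if self.step_fast <= 0 or self.step_slow <= 0:
            raise ValueError("grid steps must be positive")
        if self.n_per_line < 1 or self.n_lines < 1:
            raise EmptyScanError("grid counts must be >= 1")
        if self.rate <= 0:
            raise ValueError("exposure rate must be positive")
        if self.fast_axis not in ("x", "y"):
            raise ValueError("fast_axis must be 'x' or 'y'")

    @property
    def n_exposures(self) -> int:
        return self.n_per_line * self.n_lines


@dataclass(frozen=True)
class ExposureEvent:
    """One X-ray shot: ordinal index, chip-plane position (µm), time (s)."""

    index: int
    x: float
    y: float
    time: float


@dataclass(frozen=True)
class SpreadModel:
    """Radial damage-spread law: constant speed or diffusive sqrt(4 D t)."""

    mode: Literal["constant_speed", "diffusive"]
    speed: float = 0.0        # µm/s, constant_speed mode
    diffusivity: float = 0.0  # µm²/s, diffusive mode

    def __post_init__(self) -> None:
        if self.mode not in ("constant_speed", "diffusive"):
            raise ValueError(f"unknown spread mode {self.mode!r}")
        if self.speed < 0 or self.diffusivity < 0:
            raise ValueError("spread parameters must be >= 0")


@dataclass(frozen=True)
class CrystalSizeModel:
    """Disc-shaped crystals in the chip plane with a size distribution."""

    mean_diameter: float
    sd: float = 0.0
    distribution: Literal["lognormal", "normal-truncated"] = "lognormal"

    def __post_init__(self) -> None:
        if self.mean_diameter <= 0:
            raise ValueError("mean diameter must be positive")
        if self.sd < 0:
            raise ValueError("size sd must be >= 0")

    def sample_diameters(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean_diameter)
        if self.distribution == "lognormal":
            # parameterize so that mean and sd match the requested moments
            var = self.sd**2
            mu2 = self.mean_diameter**2
            sigma2 = math.log(1.0 + var / mu2)
            mu = math.log(self.mean_diameter) - sigma2 / 2.0
            return rng.lognormal(mu, math.sqrt(sigma2), size=n)
        draws = rng.normal(self.mean_diameter, self.sd, size=n)
        while np.any(draws <= 0):  # redraw non-physical sizes
            bad = draws <= 0
            draws[bad] = rng.normal(self.mean_diameter, self.sd, size=bad.sum())
        return draws


def build_serpentine_scan(grid: ScanGrid) -> list[ExposureEvent]:
    """Exposure schedule of a serpentine raster scan.

    The first line runs in the +fast direction, the next in −fast, and so
    on; the slow coordinate advances by one step per line.  Times are
    ``index / rate``.
    """
    events: list[ExposureEvent] = []
    idx = 0
    for line in range(grid.n_lines):
        cols = range(grid.n_per_line)
        if line % 2 == 1:
            cols = reversed(cols)
        for col in cols:
            fast = col * grid.step_fast
            slow = line * grid.step_slow
            x, y = (fast, slow) if grid.fast_axis == "x" else (slow, fast)
            events.append(ExposureEvent(idx, x, y, idx / grid.rate))
            idx += 1
    return events


def events_to_frame(events: Iterable[ExposureEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.index, e.x, e.y, e.time) for e in events],
        columns=["index", "x", "y", "t"],
    )


def neighbor_separations(
    events: list[ExposureEvent], cutoff: float = np.inf
) -> pd.DataFrame:
    """Distance and time lag from each exposure to all earlier exposures.

    Pairs farther apart than ``cutoff`` (µm) are dropped.  Columns:
    ``later``, ``earlier``, ``distance``, ``dt``.
    """
    if len(events) < 2:
        return pd.DataFrame(columns=["later", "earlier", "distance", "dt"])
    pos = np.array([(e.x, e.y) for e in events])
    t = np.array([e.time for e in events])
    li, ei = np.tril_indices(len(events), k=-1)  # li > ei: later vs earlier
    dist = np.linalg.norm(pos[li] - pos[ei], axis=1)
    keep = dist <= cutoff
    return pd.DataFrame({
        "later": [events[i].index for i in li[keep]],
        "earlier": [events[i].index for i in ei[keep]],
        "distance": dist[keep],
        "dt": t[li[keep]] - t[ei[keep]],
    })


def separation_summary(pairs: pd.DataFrame, n_classes: int = 10) -> pd.DataFrame:
    """Min/max time lag per distance class (equal-width distance bins)."""
    if pairs.empty:
        return pd.DataFrame(columns=["d_lo", "d_hi", "min_dt", "max_dt", "n"])
    edges = np.linspace(0.0, pairs["distance"].max() * (1 + 1e-12), n_classes + 1)
    labels = np.digitize(pairs["distance"], edges) - 1
    rows = []
    for cls in range(n_classes):
        sel = pairs[labels == cls]
        if sel.empty:
            continue
        rows.append((edges[cls], edges[cls + 1],
                     sel["dt"].min(), sel["dt"].max(), len(sel)))
    return pd.DataFrame(rows, columns=["d_lo", "d_hi", "min_dt", "max_dt", "n"])


def spread_radius(model: SpreadModel, t: float | np.ndarray) -> float | np.ndarray:
    """Damage-front radius (µm) a time ``t`` (s) after an exposure.

    Constant-speed mode: ``v t``.  Diffusive mode: ``sqrt(4 D t)``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    if model.mode == "constant_speed":
        r = model.speed * t_arr
    else:
        r = np.sqrt(4.0 * model.diffusivity * t_arr)
    return float(r) if np.isscalar(t) else r


def affected_fraction(events: list[ExposureEvent], model: SpreadModel) -> float:
    """Fraction of exposures inside the spread front of an earlier exposure.

    Spread is evaluated at the exposure instants only: exposure *j* is
    affected if for some earlier exposure *i*,
    ``|p_j − p_i| <= spread_radius(t_j − t_i)``.
    """
    if not events:
        return 0.0
    times = np.array([e.time for e in events])
    if np.any(np.diff(times) < 0):
        raise ValueError("events must be time-ordered")
    pos = np.array([(e.x, e.y) for e in events])
    n = len(events)
    affected = 0
    for j in range(1, n):
        d = np.linalg.norm(pos[:j] - pos[j], axis=1)
        r = spread_radius(model, times[j] - times[:j])
        if np.any(d <= r):
            affected += 1
    return affected / n


def multi_hit_fraction(
    grid: ScanGrid,
    crystals: CrystalSizeModel,
    n_sim: int = 1000,
    seed=None,
    beam_diameter: float = 0.0,
) -> float:
    """Monte-Carlo fraction of hit crystals intersected by ≥2 beam positions.

    Disc-shaped crystals are dropped with centres uniform over the scanned
    area (padded by one mean diameter so edge effects average out); a grid
    point hits a crystal if it lies within ``radius + beam_diameter/2`` of
    the centre.  Only crystals hit at least once enter the denominator.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = rng_from(seed)
    events = build_serpentine_scan(grid)
    pts = np.array([(e.x, e.y) for e in events])
    # centres are drawn within the scanned rectangle: the estimate describes
    # crystals in the probed region, without outside-edge dilution
    centers = rng.uniform(pts.min(axis=0), pts.max(axis=0), size=(n_sim, 2))
    radii = crystals.sample_diameters(n_sim, rng) / 2.0 + beam_diameter / 2.0
    # pairwise distances crystal centre -> every grid point
    d = np.linalg.norm(centers[:, None, :] - pts[None, :, :], axis=2)
    hits = (d <= radii[:, None]).sum(axis=1)
    n_hit = int((hits >= 1).sum())
    if n_hit == 0:
        return 0.0
    return int((hits >= 2).sum()) / n_hit


def thermal_increment(
    deposited_energy: float,
    distance: float,
    t: float,
    medium: dict,
    kernel: Literal["point3d", "sheet2d"] = "point3d",
    sheet_thickness: float | None = None,
) -> float:
    """Conductive temperature rise (K) at ``distance`` µm, ``t`` s after a shot.

    Instantaneous point-source conduction kernel in an infinite medium:

        ΔT = E / (ρ c (4 π κ t)^{3/2}) · exp(−r² / (4 κ t))        (point3d)

    or, for energy deposited uniformly across a thin sheet of thickness
    ``h`` (quasi-2-D spreading in the sheet plane):

        ΔT = E / (ρ c h · 4 π κ t) · exp(−r² / (4 κ t))            (sheet2d)

    ``medium`` must provide ``density`` (kg/m³), ``heat_capacity``
    (J/(kg·K)) and ``diffusivity`` (m²/s).  This is a documented stand-in
    for a full heat/gas-diffusion treatment; it conserves the deposited
    energy under spatial integration.
    """
    rho = medium["density"]
    cp = medium["heat_capacity"]
    kappa = medium["diffusivity"]
    if min(rho, cp, kappa) <= 0:
        raise ValueError("medium parameters must be positive")
    if deposited_energy < 0 or distance < 0 or t < 0:
        raise ValueError("energy, distance and time must be >= 0")
    r = distance * 1e-6  # µm -> m
    if t == 0.0:
        if r == 0.0:
            raise SingularSourceError("kernel is singular at r = 0, t = 0")
        return 0.0
    gauss = math.exp(-(r**2) / (4.0 * kappa * t))
    if kernel == "point3d":
        norm = rho * cp * (4.0 * math.pi * kappa * t) ** 1.5
    elif kernel == "sheet2d":
        if sheet_thickness is None or sheet_thickness <= 0:
            raise ValueError("sheet2d kernel needs a positive sheet_thickness (µm)")
        h = sheet_thickness * 1e-6
        norm = rho * cp * h * 4.0 * math.pi * kappa * t
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return deposited_energy * gauss / norm
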