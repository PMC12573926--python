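"""Monte-Carlo merging of snapshot reflection lists and shell diagnostics.

Many partial snapshot observations of each unique reflection are averaged
with equal weights so that partiality averages out; uncertainty per unique
reflection is the standard error of that mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .core import UnitCell
from .synth import ImageRecord

Symmetry = Literal["P1", "monoclinic_2"]


class CellInconsistencyError(ValueError):
    """Image cells disagree beyond tolerance; split populations first
    (see :func:`ssxdamage.wilson.cluster_cells`)."""


@dataclass
class MergedEntry:
    mean_I: float
    sem_I: float       # NaN where redundancy == 1
    redundancy: int
    d: float


@dataclass
class MergedDataset:
    entries: dict[tuple[int, int, int], MergedEntry]
    cell: UnitCell
    n_images: int
    symmetry: Symmetry = "P1"

    def to_frame(self) -> pd.DataFrame:
        rows = [(h, k, l, e.mean_I, e.sem_I, e.redundancy, e.d)
                for (h, k, l), e in sorted(self.entries.items())]
        return pd.DataFrame(rows, columns=["h", "k", "l", "I", "sem",
                                           "redundancy", "d"])


@dataclass
class Shell:
    d_min: float
    d_max: float
    mean_I: float
    mean_I_over_sigma: float
    n_refl: int
    completeness: float


@dataclass
class ShellTable:
    shells: list[Shell]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.d_min, s.d_max, s.mean_I, s.mean_I_over_sigma, s.n_refl,
              s.completeness) for s in self.shells],
            columns=["d_min", "d_max", "mean_I", "mean_I_over_sigma",
                     "n_refl", "completeness"],
        )


@dataclass
class SnrCutoff:
    d: float
    geometry_limited: bool = False


def fold_hkl(hkl: np.ndarray, symmetry: Symmetry = "P1") -> np.ndarray:
    """Map Miller indices to a canonical symmetry-equivalent representative.

    ``P1`` folds Friedel pairs only (point group -1); ``monoclinic_2`` folds
    the 2/m orbit {(h,k,l), (-h,k,-l)} plus Friedel mates (unique axis b).
    The representative is the lexicographically largest orbit member.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    mates = [hkl, -hkl]
    if symmetry == "monoclinic_2":
        twofold = hkl * np.array([-1, 1, -1])
        mates += [twofold, -twofold]
    elif symmetry != "P1":
        raise ValueError(f"unknown symmetry {symmetry!r}")
    stacked = np.stack(mates, axis=0)  # (n_ops, n, 3)
    # lexicographic max over operators, per reflection
    order = np.lexsort((stacked[..., 2], stacked[..., 1], stacked[..., 0]), axis=0)
    best = order[-1]
    return stacked[best, np.arange(hkl.shape[0])]


def median_cell(images: Iterable[ImageRecord]) -> UnitCell:
    cells = np.array([[im.cell.a, im.cell.b, im.cell.c,
                       im.cell.alpha, im.cell.beta, im.cell.gamma]
                      for im in images])
    med = np.median(cells, axis=0)
    return UnitCell(*med)


def check_cell_consistency(images: list[ImageRecord], tol: float = 0.01) -> UnitCell:
    cell = median_cell(images)
    ref = np.array([cell.a, cell.b, cell.c])
    for im in images:
        dev = np.abs(np.array([im.cell.a, im.cell.b, im.cell.c]) - ref) / ref
        if np.any(dev > tol):
            raise CellInconsistencyError(
                f"image {im.image_id} cell deviates {dev.max():.2%} from the "
                f"median (tolerance {tol:.0%}); run cluster_cells and merge "
                "populations separately"
            )
    return cell


def mc_merge(
    images: list[ImageRecord],
    symmetry: Symmetry = "P1",
    cell_tolerance: float = 0.01,
    weighted: bool = False,
) -> MergedDataset:
    """Monte-Carlo merge: per-unique-HKL mean of all observations.

    Symmetry equivalents are folded per ``symmetry``; the merged cell is the
    per-axis median of the image cells.  The default is the unweighted mean
    (Monte-Carlo merging convention); ``weighted=True`` uses 1/sigma²
    weights instead.
    """
    if not images:
        raise ValueError("need at least one image")
    cell = check_cell_consistency(images, cell_tolerance)

    hkl = np.concatenate([fold_hkl(im.hkl, symmetry) for im in images])
    intens = np.concatenate([im.intensity for im in images])
    sig = np.concatenate([im.sigma for im in images])

    # group by folded hkl
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    hkl, intens, sig = hkl[order], intens[order], sig[order]
    boundaries = np.any(np.diff(hkl, axis=0) != 0, axis=1)
    starts = np.concatenate([[0], np.nonzero(boundaries)[0] + 1, [len(hkl)]])

    uniq = hkl[starts[:-1]]
    d = np.asarray(median_cell(images).d_spacing(uniq.astype(float)))
    entries: dict[tuple[int, int, int], MergedEntry] = {}
    for i in range(len(starts) - 1):
        lo, hi = starts[i], starts[i + 1]
        vals = intens[lo:hi]
        n = hi - lo
        if weighted:
            w = 1.0 / sig[lo:hi] ** 2
            mean = float(np.sum(w * vals) / np.sum(w))
        else:
            mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
        key = (int(uniq[i, 0]), int(uniq[i, 1]), int(uniq[i, 2]))
        entries[key] = MergedEntry(mean, sem, int(n), float(d[i]))
    return MergedDataset(entries, cell, len(images), symmetry)


def _shell_edges(d: np.ndarray, n_shells: int) -> np.ndarray:
    """Contiguous equal-volume shell edges in 1/d³, returned as d values
    (descending: low resolution first)."""
    q = np.asarray(d, dtype=float) ** -3
    edges_q = np.linspace(q.min(), q.max(), n_shells + 1)
    edges_q[0] -= 1e-12
    edges_q[-1] += 1e-12
    return edges_q ** (-1.0 / 3.0)


def shell_statistics(
    merged: MergedDataset, n_shells: int = 10
) -> ShellTable:
    """Equal-volume (in 1/d³) resolution shells with per-shell means.

    Completeness compares observed unique reflections in the shell against
    the full symmetry-unique HKL count of the merged cell.
    """
    if not merged.entries:
        raise ValueError("merged dataset is empty")
    if n_shells > len(merged.entries):
        raise ValueError("more shells than unique reflections")
    keys = np.array(list(merged.entries.keys()))
    d = np.array([e.d for e in merged.entries.values()])
    mean_i = np.array([e.mean_I for e in merged.entries.values()])
    sem = np.array([e.sem_I for e in merged.entries.values()])
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(np.isfinite(sem) & (sem > 0), mean_i / sem, np.nan)

    edges = _shell_edges(d, n_shells)
    full = merged.cell.hkl_sphere(d.min() * (1 - 1e-9))
    folded = fold_hkl(full, merged.symmetry)
    uniq_full = np.unique(folded, axis=0)
    d_full = np.asarray(merged.cell.d_spacing(uniq_full.astype(float)))

    shells = []
    for i in range(n_shells):
        d_hi, d_lo = edges[i], edges[i + 1]   # d_hi: low-res edge (large d)
        sel = (d <= d_hi) & (d > d_lo) if i else (d <= d_hi) & (d >= d_lo)
        n_possible = int(((d_full <= d_hi) & (d_full > d_lo)).sum()) or 1
        vals = mean_i[sel]
        shell_snr = snr[sel]
        shells.append(Shell(
            d_min=float(d_lo),
            d_max=float(d_hi),
            mean_I=float(vals.mean()) if len(vals) else float("nan"),
            mean_I_over_sigma=(float(np.nanmean(shell_snr))
                               if np.any(np.isfinite(shell_snr)) else float("nan")),
            n_refl=int(sel.sum()),
            completeness=min(1.0, float(sel.sum()) / n_possible),
        ))
    return ShellTable(shells)


def snr_resolution(shells: ShellTable, threshold: float = 1.0) -> SnrCutoff:
    """Resolution at which shell-mean I/sigma crosses ``threshold``.

    Linear interpolation in 1/d³ between shell centres.  If the signal never
    drops below the threshold the best shell edge is returned flagged
    ``geometry_limited``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not shells.shells:
        raise ValueError("empty shell table")
    usable = [s for s in shells.shells if np.isfinite(s.mean_I_over_sigma)]
    if not usable:
        raise ValueError("no shells with finite I/sigma")
    centers = np.array([(s.d_min**-3 + s.d_max**-3) / 2 for s in usable])
    snr = np.array([s.mean_I_over_sigma for s in usable])
    best_edge = min(s.d_min for s in usable)
    below = np.nonzero(snr < threshold)[0]
    if len(below) == 0:
        return SnrCutoff(best_edge, geometry_limited=True)
    j = below[0]
    if j == 0:
        return SnrCutoff(float(usable[0].d_max))
    # interpolate crossing between shell centres j-1 and j in 1/d³
    q = centers[j - 1] + (threshold - snr[j - 1]) * (
        centers[j] - centers[j - 1]
    ) / (snr[j] - snr[j - 1])
    return SnrCutoff(float(q ** (-1.0 / 3.0)))


def clipping_report(
    images: list[ImageRecord], cap: float, n_shells: int = 10
) -> dict:
    """Fraction of observations at/above the saturation cap, overall and per
    resolution shell."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    d = np.concatenate([
        np.asarray(im.cell.d_spacing(im.hkl.astype(float))) for im in images
    ])
    intens = np.concatenate([im.intensity for im in images])
    clipped = intens >= cap
    edges = _shell_edges(d, n_shells)
    per_shell = []
    for i in range(n_shells):
        d_hi, d_lo = edges[i], edges[i + 1]
        sel = (d <= d_hi) & (d > d_lo) if i else (d <= d_hi) & (d >= d_lo)
        frac = float(clipped[sel].mean()) if np.any(sel) else float("nan")
        per_shell.append({"d_min": float(d_lo), "d_max": float(d_hi),
                          "clipped_fraction": frac, "n_obs": int(sel.sum())})
    return {"clipped_fraction": float(clipped.mean()), "per_shell": per_shell}
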