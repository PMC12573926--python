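"""Global-damage diagnostics: Wilson plots and unit-cell populations.

Slope convention, used everywhere: shell-mean intensity follows
``<I> ∝ exp(−B / (2 d²))``, so the fitted line ``ln<I> = intercept + slope ·
(1/d²)`` has ``slope = −B/2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .core import ToyStructure, UnitCell
from .merging import MergedDataset
from .refine import calc_structure_factors
from .synth import unique_hkls

#: Observed Wilson plots are non-linear at low resolution (background and
#: solvent effects); points below this 1/d² are excluded from fits.
DEFAULT_FIT_MIN_INV_D2 = 0.1


@dataclass
class WilsonFit:
    points: pd.DataFrame        # columns inv_d2, ln_mean_I, n_refl
    fit_range: tuple[float, float]
    B: float
    intercept: float
    source: Literal["observed", "calculated"]

    def predict_ln_I(self, inv_d2) -> np.ndarray:
        return self.intercept - self.B / 2.0 * np.asarray(inv_d2, dtype=float)


@dataclass
class CellClusterResult:
    labels: np.ndarray
    cluster_centers: list[UnitCell]
    fraction_per_cluster: np.ndarray
    assignment_margin: np.ndarray
    degenerate: bool = False


def _fit_wilson(inv_d2, ln_i, n_refl, fit_range, source) -> WilsonFit:
    points = pd.DataFrame({"inv_d2": inv_d2, "ln_mean_I": ln_i, "n_refl": n_refl})
    lo, hi = fit_range
    sel = (points["inv_d2"] >= lo) & (points["inv_d2"] <= hi) & np.isfinite(ln_i)
    if sel.sum() < 2:
        raise ValueError("fewer than 2 usable Wilson points in the fit range")
    x = points.loc[sel, "inv_d2"].to_numpy()
    y = points.loc[sel, "ln_mean_I"].to_numpy()
    w = points.loc[sel, "n_refl"].to_numpy().astype(float)
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    return WilsonFit(points, (float(lo), float(hi)), B=float(-2.0 * slope),
                     intercept=float(intercept), source=source)


def _binned_wilson_points(inv_d2, intensity, n_bins):
    edges = np.linspace(inv_d2.min(), inv_d2.max() * (1 + 1e-12), n_bins + 1)
    idx = np.digitize(inv_d2, edges) - 1
    centers, ln_i, counts = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if not np.any(sel):
            continue
        mean_i = intensity[sel].mean()
        centers.append(inv_d2[sel].mean())
        ln_i.append(np.log(mean_i) if mean_i > 0 else np.nan)
        counts.append(int(sel.sum()))
    return np.array(centers), np.array(ln_i), np.array(counts)


def wilson_observed(
    merged: MergedDataset,
    n_bins: int = 20,
    fit_range: tuple[float, float] | None = None,
) -> WilsonFit:
    """Wilson fit of merged observed intensities.

    Bins are equal-width in 1/d²; bins with non-positive mean intensity are
    excluded (with a NaN point retained for inspection).  The default fit
    range starts at 1/d² = 0.1 Å⁻² to skip the non-linear low-resolution
    region of observed Wilson plots.
    """
    if not merged.entries:
        raise ValueError("merged dataset is empty")
    d = np.array([e.d for e in merged.entries.values()])
    mean_i = np.array([e.mean_I for e in merged.entries.values()])
    inv_d2 = 1.0 / d**2
    centers, ln_i, counts = _binned_wilson_points(inv_d2, mean_i, n_bins)
    if fit_range is None:
        fit_range = (max(DEFAULT_FIT_MIN_INV_D2, centers.min()), centers.max())
    return _fit_wilson(centers, ln_i, counts, fit_range, "observed")


def wilson_calculated(
    structure: ToyStructure,
    d_min: float,
    n_bins: int = 20,
    fit_range: tuple[float, float] | None = None,
) -> WilsonFit:
    """Wilson fit of |F_calc|² on the full HKL sphere to ``d_min``.

    Calculated intensities reflect only the model's Bragg falloff, so no
    low-resolution exclusion is applied by default.
    """
    hkl = unique_hkls(structure.cell, d_min)
    if len(hkl) == 0:
        raise ValueError("empty HKL sphere at this resolution")
    i_calc = np.abs(calc_structure_factors(structure, hkl)) ** 2
    inv_d2 = 1.0 / np.asarray(structure.cell.d_spacing(hkl.astype(float))) ** 2
    centers, ln_i, counts = _binned_wilson_points(inv_d2, i_calc, n_bins)
    if fit_range is None:
        fit_range = (centers.min(), centers.max())
    return _fit_wilson(centers, ln_i, counts, fit_range, "calculated")


def excess_wilson_b(
    merged: MergedDataset,
    structure: ToyStructure,
    d_min: float,
    n_bins: int = 20,
    fit_range: tuple[float, float] | None = None,
) -> float:
    """Observed-minus-calculated Wilson B over a matched fit range.

    A single observed fit is biased by the structure's own interference
    (Debye) term; subtracting the calculated-intensity fit of the same
    model over the same bins and range cancels it, leaving the extra
    attenuation planted on top of the model — the quantity of interest when
    comparing global damage between datasets.
    """
    if fit_range is None:
        inv_d2_max = 1.0 / d_min**2
        fit_range = (DEFAULT_FIT_MIN_INV_D2, inv_d2_max)
    obs = wilson_observed(merged, n_bins=n_bins, fit_range=fit_range)
    calc = wilson_calculated(structure, d_min, n_bins=n_bins, fit_range=fit_range)
    return obs.B - calc.B


def inv_d2_to_resolution(inv_d2: float) -> float:
    """Resolution d (Å) of a reciprocal-space coordinate 1/d² (Å⁻²)."""
    if inv_d2 <= 0:
        raise ValueError("1/d² must be positive")
    return float(1.0 / np.sqrt(inv_d2))


def falloff_ratio(
    fit1: WilsonFit,
    fit2: WilsonFit,
    at_inv_d2: float,
    anchor_inv_d2: float = 0.0,
    force: bool = False,
) -> float:
    """Intensity ratio of two Wilson fits at ``at_inv_d2``.

    The fitted lines are first matched at ``anchor_inv_d2`` (default 0, the
    extrapolated infinite-resolution intercept) so only the slope difference
    contributes:  ratio = exp(ΔB/2 · (x − x_anchor)) with ΔB = B2 − B1.
    Evaluation outside either fit range raises unless ``force``.
    """
    for fit in (fit1, fit2):
        lo, hi = fit.fit_range
        if not force and not lo <= at_inv_d2 <= hi:
            raise ValueError(
                f"1/d² = {at_inv_d2} outside fit range {fit.fit_range}; "
                "pass force=True to extrapolate"
            )
    delta_b = fit2.B - fit1.B
    return float(np.exp(delta_b / 2.0 * (at_inv_d2 - anchor_inv_d2)))


def cluster_cells(
    cells: Sequence[UnitCell],
    k: int = 2,
    seed: int | None = 0,
    n_restarts: int = 10,
    degenerate_margin: float = 0.2,
) -> CellClusterResult:
    """K-means clustering of unit cells on standardized (a, b, c, β).

    Clusters are reported sorted by cell volume (ascending), so labels are
    permutation-stable.  ``assignment_margin`` is the per-cell relative gap
    between the nearest and second-nearest centre,
    ``(d2 − d1)/(d2 + d1)``; a median margin below ``degenerate_margin``
    flags a degenerate split of a single population.
    """
    cells = list(cells)
    if k > len(cells):
        raise ValueError(f"k = {k} exceeds number of cells ({len(cells)})")
    feats = np.array([[c.a, c.b, c.c, c.beta] for c in cells])
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts,
                random_state=None if seed is None else int(seed))
    with warnings.catch_warnings():
        # duplicate cells collapse centres; the degenerate flag reports it
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        raw_labels = km.fit_predict(z)
    centers_raw = km.cluster_centers_ * sd + mu

    center_cells = [UnitCell(a, b, c, 90.0, beta, 90.0)
                    for a, b, c, beta in centers_raw]
    order = np.argsort([c.volume for c in center_cells])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw_labels]
    center_cells = [center_cells[i] for i in order]

    dists = np.linalg.norm(z[:, None, :] - km.cluster_centers_[None, order, :],
                           axis=2)
    sorted_d = np.sort(dists, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        margin = (sorted_d[:, 1] - sorted_d[:, 0]) / (sorted_d[:, 1] + sorted_d[:, 0])
    margin = np.nan_to_num(margin, nan=0.0)
    fractions = np.bincount(labels, minlength=k) / len(cells)
    return CellClusterResult(
        labels=labels,
        cluster_centers=center_cells,
        fraction_per_cluster=fractions,
        assignment_margin=margin,
        degenerate=bool(np.median(margin) < degenerate_margin),
    )
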