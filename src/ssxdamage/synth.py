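"""Synthetic snapshot-diffraction generator with known ground truth.

Produces every input the analysis pipeline consumes: toy heme-site
structures with requested geometry, per-snapshot partial reflection lists
with planted Wilson-B attenuation, per-image scale and noise, one- or
two-population unit cells, detector saturation clipping, and noisy
coordinate ensembles.  All generation is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    Atom,
    GeometryError,
    ToyStructure,
    UnitCell,
    rng_from,
    ROLE_BYSTANDER,
    ROLE_FE,
    ROLE_HIS,
    ROLE_O1,
    ROLE_O2,
    ROLE_PLANE,
    ROLE_WAT,
    ROLE_WAT_ALT,
    ROLE_WATX,
)
from .refine import calc_structure_factors

#: The two unit-cell populations observed for the dehydration-driven
#: small-to-large lattice transition (monoclinic, alpha = gamma = 90).
SMALL_CELL = UnitCell(73.4, 68.8, 75.9, 90.0, 105.7, 90.0)
LARGE_CELL = UnitCell(75.0, 68.4, 77.6, 90.0, 107.6, 90.0)

#: Default toy cell: small enough that full-sphere structure-factor sums
#: stay cheap, monoclinic so the beta axis is exercised.
DEFAULT_TOY_CELL = UnitCell(14.0, 15.0, 16.0, 90.0, 95.0, 90.0)


def derive_large_cell(cell: UnitCell) -> UnitCell:
    """Apply the small->large population shift (fractional axis changes and
    the beta offset of the observed transition) to an arbitrary cell."""
    return UnitCell(
        cell.a * LARGE_CELL.a / SMALL_CELL.a,
        cell.b * LARGE_CELL.b / SMALL_CELL.b,
        cell.c * LARGE_CELL.c / SMALL_CELL.c,
        cell.alpha,
        cell.beta + (LARGE_CELL.beta - SMALL_CELL.beta),
        cell.gamma,
    )


@dataclass
class ImageRecord:
    """One snapshot: unit cell plus indexed partial reflection observations.

    ``true_scale`` retains the planted per-image multiplicative scale for
    oracle use only; it is not written to disk by default.
    """

    image_id: str
    cell: UnitCell
    hkl: np.ndarray          # (n, 3) int
    intensity: np.ndarray    # (n,)
    sigma: np.ndarray        # (n,)
    true_scale: float = 1.0

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.hkl)
        if self.intensity.shape != (n,) or self.sigma.shape != (n,):
            raise ValueError("hkl/intensity/sigma length mismatch")
        if np.any(self.sigma <= 0):
            raise ValueError("sigmas must be positive")
        if len({tuple(h) for h in self.hkl}) != n:
            raise ValueError("duplicate (h,k,l) within an image")

    @property
    def n_obs(self) -> int:
        return len(self.hkl)


@dataclass
class GenerationRecipe:
    """Knobs of the snapshot generator; every field has a planted truth."""

    n_images: int = 100
    reflections_per_image: float = 0.3
    planted_B: float = 0.0           # extra Wilson-B attenuation, Å²
    noise_sd: float = 0.0            # relative (fraction of model intensity)
    scale_sd: float = 0.0            # lognormal sigma of per-image scale
    fraction_large_cell: float = 0.0
    large_cell_extra_B: float = 20.0
    clip_cap: float | None = None
    resolution_limit: float = 1.8
    seed: int | None = 0
    large_cell: UnitCell | None = None
    sigma_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if not 0.0 < self.reflections_per_image <= 1.0:
            raise ValueError("reflections_per_image must be in (0, 1]")
        if not 0.0 <= self.fraction_large_cell <= 1.0:
            raise ValueError("fraction_large_cell must be in [0, 1]")
        if self.planted_B < 0 or self.noise_sd < 0 or self.scale_sd < 0:
            raise ValueError("planted_B, noise_sd, scale_sd must be >= 0")
        if self.resolution_limit <= 0:
            raise ValueError("resolution_limit must be positive")


def make_toy_structure(
    fe_wat: float,
    fe_his: float,
    feoop: float,
    o_o: float | None = None,
    cell: UnitCell = DEFAULT_TOY_CELL,
    seed=0,
    fe_o_o_angle: float = 160.0,
    fe_wat_watx_angle: float = 117.0,
    wat_watx: float = 2.7,
    n_bystanders: int = 6,
    two_state_water: bool = False,
    wat_alt_shift: float = 1.0,
) -> ToyStructure:
    """Construct a heme-like active site with exactly the requested geometry.

    The porphyrin plane is the z = 0 plane (four N atoms on a 2 Å ring), the
    iron sits at (0, 0, feoop) — so FeOOP is signed positive toward the
    distal water — the coordinating water ``fe_wat`` above the iron on +z
    and the proximal His nitrogen ``fe_his`` below.  If ``o_o`` is given, a
    diatomic distal ligand (O1 at ``fe_wat`` from Fe on a tilted axis, O2 at
    ``o_o`` from O1 subtending ``fe_o_o_angle`` at O1) is added.  With
    ``two_state_water`` an alternative remote water position is added
    ``wat_alt_shift`` Å further from the iron along +z.  Bystander carbon
    atoms provide scattering diversity; their placement is seeded.
    """
    if fe_wat <= 0 or fe_his <= 0:
        raise GeometryError("fe_wat and fe_his must be positive")
    if abs(feoop) >= fe_his:
        raise GeometryError(f"feoop ({feoop}) inconsistent with fe_his ({fe_his})")
    if feoop + fe_wat <= 0:
        raise GeometryError("water must lie on the distal (+z) side of the plane")
    if o_o is not None and o_o <= 0:
        raise GeometryError("o_o must be positive")

    rng = rng_from(seed)
    atoms: list[Atom] = []
    ring = 2.0
    for i, (dx, dy) in enumerate([(ring, 0), (0, ring), (-ring, 0), (0, -ring)]):
        atoms.append(Atom(f"N{'ABCD'[i]}", "N", ROLE_PLANE, (dx, dy, 0.0)))
    fe = np.array([0.0, 0.0, feoop])
    atoms.append(Atom("FE", "FE", ROLE_FE, fe))
    atoms.append(Atom("NE2", "N", ROLE_HIS, fe + [0.0, 0.0, -fe_his]))
    wat = fe + [0.0, 0.0, fe_wat]
    atoms.append(Atom("O", "O", ROLE_WAT, wat))
    if two_state_water:
        atoms.append(Atom("OALT", "O", ROLE_WAT_ALT,
                          wat + [0.0, 0.0, wat_alt_shift]))
    # WatX: at wat_watx from the water, subtending fe_wat_watx_angle at it
    theta = math.radians(fe_wat_watx_angle)
    d = np.array([math.sin(theta), 0.0, -math.cos(theta)])  # angle to -z is theta
    atoms.append(Atom("OX", "O", ROLE_WATX, wat + wat_watx * d))
    if o_o is not None:
        tilt = math.radians(35.0)  # keep the diatomic clear of the water axis
        v = np.array([math.sin(tilt), 0.0, math.cos(tilt)])
        o1 = fe + fe_wat * v
        phi = math.radians(fe_o_o_angle)
        # unit vector subtending phi at O1 with the O1->Fe direction (-v),
        # rotated within the plane spanned by v and x-hat
        perp = np.array([math.cos(tilt), 0.0, -math.sin(tilt)])
        e = math.cos(phi) * (-v) + math.sin(phi) * perp
        atoms.append(Atom("O1", "O", ROLE_O1, o1))
        atoms.append(Atom("O2", "O", ROLE_O2, o1 + o_o * e))
    positions = np.array([a.xyz for a in atoms])
    n_placed = 0
    while n_placed < n_bystanders:
        p = rng.uniform(-6.0, 6.0, size=3)
        r = np.linalg.norm(p)
        if r < 3.0 or r > 6.5:
            continue
        if np.min(np.linalg.norm(positions - p, axis=1)) < 1.8:
            continue
        atoms.append(Atom(f"C{n_placed + 1}", "C", ROLE_BYSTANDER, p))
        positions = np.vstack([positions, p])
        n_placed += 1
    # park the motif away from the origin so no atom sits on a special position
    offset = cell.orthogonalization @ np.array([0.27, 0.31, 0.33])
    for atom in atoms:
        atom.xyz = atom.xyz + offset
    return ToyStructure(atoms, cell)


def unique_hkls(cell: UnitCell, d_min: float) -> np.ndarray:
    """Friedel-unique Miller indices with d >= d_min (canonical hemisphere)."""
    hkl = cell.hkl_sphere(d_min)
    canon = {max(tuple(h), tuple(-h)) for h in map(np.asarray, hkl)}
    return np.array(sorted(canon), dtype=int)


def simulate_image_set(
    structure: ToyStructure, recipe: GenerationRecipe
) -> list[ImageRecord]:
    """Generate a set of partial snapshot reflection lists.

    Per image: a uniform random subset of the Friedel-unique HKL list to the
    recipe's resolution limit; intensity = scale_i · |F_calc|² · planted-B
    attenuation (plus the large-cell extra attenuation for large-cell
    images) + relative Gaussian noise, clipped at ``clip_cap`` if set.
    """
    hkl = unique_hkls(structure.cell, recipe.resolution_limit)
    if len(hkl) == 0:
        raise ValueError("empty HKL list: resolution limit too low for this cell")
    i_true = np.abs(calc_structure_factors(structure, hkl)) ** 2
    s2 = 1.0 / structure.cell.d_spacing(hkl.astype(float)) ** 2
    base = i_true * np.exp(-recipe.planted_B * s2 / 2.0)
    large_cell = recipe.large_cell or derive_large_cell(structure.cell)

    rng = rng_from(recipe.seed)
    images: list[ImageRecord] = []
    for i in range(recipe.n_images):
        keep = rng.random(len(hkl)) < recipe.reflections_per_image
        if not np.any(keep):
            keep[rng.integers(len(hkl))] = True
        is_large = rng.random() < recipe.fraction_large_cell
        scale = 1.0 if recipe.scale_sd == 0 else float(
            rng.lognormal(-recipe.scale_sd**2 / 2.0, recipe.scale_sd)
        )
        model = scale * base[keep]
        if is_large:
            model = model * np.exp(-recipe.large_cell_extra_B * s2[keep] / 2.0)
        sigma = np.maximum(recipe.noise_sd * model, recipe.sigma_floor)
        obs = model + (rng.normal(0.0, sigma) if recipe.noise_sd > 0 else 0.0)
        if recipe.clip_cap is not None:
            obs = np.minimum(obs, recipe.clip_cap)
        images.append(ImageRecord(
            image_id=f"img{i:05d}",
            cell=large_cell if is_large else structure.cell,
            hkl=hkl[keep],
            intensity=np.asarray(obs, dtype=float),
            sigma=sigma,
            true_scale=scale,
        ))
    return images


def simulate_geometry_ensemble(
    structure: ToyStructure, coord_sd: float, n: int, seed=0
) -> list[ToyStructure]:
    """``n`` copies with i.i.d. per-coordinate Gaussian displacement."""
    if coord_sd < 0:
        raise ValueError("coord_sd must be >= 0")
    rng = rng_from(seed)
    out = []
    for _ in range(n):
        copy = structure.copy()
        if coord_sd > 0:
            copy.coordinates = copy.coordinates + rng.normal(
                0.0, coord_sd, copy.coordinates.shape
            )
        out.append(copy)
    return out
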