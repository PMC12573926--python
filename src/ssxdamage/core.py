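"""Shared domain types: unit cells, atoms, toy structures, seed handling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Flat per-element form factors (electron counts); no resolution dependence.
#: The generator and refinement engine deliberately use a single number per
#: element so that resolution falloff comes only from B factors.
FORM_FACTORS = {
    "H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0, "S": 16.0, "FE": 26.0, "P": 15.0,
}

ROLE_FE = "FE"
ROLE_PLANE = "PLANE_N"
ROLE_HIS = "HIS_N"
ROLE_WAT = "WAT_O"
ROLE_WAT_ALT = "WAT_O_ALT"
ROLE_WATX = "WATX_O"
ROLE_O1 = "DISTAL_O1"
ROLE_O2 = "DISTAL_O2"
ROLE_BYSTANDER = "BYSTANDER"


class GeometryError(ValueError):
    """Inconsistent or missing geometric input."""


@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell; lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angles must lie in (0, 180): {self}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])

    @property
    def orthogonalization(self) -> np.ndarray:
        """3x3 matrix mapping fractional to Cartesian (Å) coordinates."""
        ca, cb, cg = np.cos(np.radians(self.angles))
        sg = np.sin(np.radians(self.gamma))
        v = np.sqrt(1.0 - ca**2 - cb**2 - cg**2 + 2.0 * ca * cb * cg)
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    @property
    def fractionalization(self) -> np.ndarray:
        """Inverse of :attr:`orthogonalization`."""
        return np.linalg.inv(self.orthogonalization)

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.orthogonalization))

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Å) for an (..., 3) integer array of Miller indices."""
        hkl = np.asarray(hkl, dtype=float)
        # reciprocal metric tensor = (M^-1) (M^-1)^T with M orthogonalization
        f = self.fractionalization
        gstar = f @ f.T
        inv_d2 = np.einsum("...i,ij,...j->...", hkl, gstar, hkl)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(inv_d2)

    def hkl_sphere(self, d_min: float) -> np.ndarray:
        """All Miller indices (excluding 000) with d >= d_min, unfolded."""
        if d_min <= 0:
            raise ValueError("d_min must be positive")
        hmax = int(np.ceil(self.a / d_min)) + 1
        kmax = int(np.ceil(self.b / d_min)) + 1
        lmax = int(np.ceil(self.c / d_min)) + 1
        h, k, l = np.meshgrid(
            np.arange(-hmax, hmax + 1),
            np.arange(-kmax, kmax + 1),
            np.arange(-lmax, lmax + 1),
            indexing="ij",
        )
        hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
        hkl = hkl[np.any(hkl != 0, axis=1)]
        return hkl[self.d_spacing(hkl) >= d_min]

    def isclose(self, other: "UnitCell", rtol: float = 1e-6) -> bool:
        return bool(
            np.allclose(self.lengths, other.lengths, rtol=rtol)
            and np.allclose(self.angles, other.angles, rtol=rtol)
        )


@dataclass
class Atom:
    """One atom of a toy structure."""

    name: str
    element: str
    role: str
    xyz: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValueError("xyz must be a 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy outside [0, 1]: {self.occupancy}")
        if self.b_factor < 0:
            raise ValueError(f"negative B factor: {self.b_factor}")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.role, self.xyz.copy(),
                    self.b_factor, self.occupancy)

    @property
    def form_factor(self) -> float:
        return FORM_FACTORS[self.element.upper()]


@dataclass
class ToyStructure:
    """Small atomic model with heme-site roles, in Cartesian Å."""

    atoms: list[Atom]
    cell: UnitCell
    chain: str = "A"

    def __post_init__(self) -> None:
        n_fe = sum(a.role == ROLE_FE for a in self.atoms)
        if n_fe != 1:
            raise ValueError(f"expected exactly one FE atom, found {n_fe}")
        if sum(a.role == ROLE_PLANE for a in self.atoms) < 3:
            raise ValueError("need at least 3 plane atoms")

    def copy(self) -> "ToyStructure":
        return ToyStructure([a.copy() for a in self.atoms], self.cell, self.chain)

    def atoms_with_role(self, role: str) -> list[Atom]:
        return [a for a in self.atoms if a.role == role]

    def atom(self, role: str) -> Atom:
        found = self.atoms_with_role(role)
        if not found:
            raise GeometryError(f"no atom with role {role}")
        return found[0]

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    @coordinates.setter
    def coordinates(self, value: np.ndarray) -> None:
        value = np.asarray(value, dtype=float)
        if value.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms, value):
            atom.xyz = xyz.copy()

    @property
    def form_factors(self) -> np.ndarray:
        return np.array([a.form_factor for a in self.atoms])

    @property
    def b_factors(self) -> np.ndarray:
        return np.array([a.b_factor for a in self.atoms])

    @property
    def occupancies(self) -> np.ndarray:
        return np.array([a.occupancy for a in self.atoms])


def split_seed(seed: int | None, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from a master seed.

    Uses :class:`numpy.random.SeedSequence` spawning so that consumers of
    early streams are unaffected when more streams are requested later.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def rng_from(seed) -> np.random.Generator:
    """Accept an int seed, a Generator, or None and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
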