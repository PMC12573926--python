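"""Toy structure-factor calculator and least-squares refinement engine.

Stands in for a full macromolecular refinement program inside the bootstrap
loop.  The forward model is the standard kinematic sum with flat per-element
form factors,

    F(hkl) = Σ_j occ_j f_j exp(−B_j s² / 4) exp(2πi hkl · x_frac,j),  s = 1/d,

and the target is intensity-based weighted least squares,
Σ w (I_obs − k |F_calc|²)², minimized by Levenberg–Marquardt with an
analytic Jacobian.  There are no geometric restraints: starting models are
assumed within ~0.3 Å of a minimum.

Note that |F|² is exactly invariant under a common translation of all
atoms (and, in P1, under inversion), so refined *absolute* positions are
defined only modulo a global origin shift; every derived distance and
angle is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ToyStructure, rng_from
from .core import ROLE_WAT, ROLE_WAT_ALT, ROLE_WATX


class UnderdeterminedError(ValueError):
    """Fewer observations than free parameters."""


class DivergenceError(RuntimeError):
    """Refinement failed to converge within max_iter."""


@dataclass
class RefinementOptions:
    refine_positions: bool = True
    refine_b: bool = False
    refine_occupancies: bool = False
    scramble_sd: float = 0.0
    max_iter: int = 50
    convergence_tol: float = 1e-8
    seed: int | None = None
    #: restrict positional refinement to atoms with these roles (None = all)
    position_roles: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.scramble_sd < 0:
            raise ValueError("scramble_sd must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class RefinementResult:
    structure: ToyStructure
    scale: float
    n_iter: int
    converged: bool
    residual: float
    history: list[tuple[int, float, float]] = field(default_factory=list)


def calc_structure_factors(
    structure: ToyStructure, hkls: np.ndarray
) -> np.ndarray:
    """Complex structure factors for an (n, 3) array of Miller indices."""
    hkls = np.atleast_2d(np.asarray(hkls, dtype=float))
    frac = structure.coordinates @ structure.cell.fractionalization.T
    if np.any(np.abs(frac) > 10):
        raise ValueError("atom fractional coordinate outside sanity bounds (|frac| > 10)")
    s2 = 1.0 / structure.cell.d_spacing(hkls) ** 2  # (n,)
    # per-atom amplitude with B attenuation: (n_hkl, n_atom)
    amp = (structure.occupancies * structure.form_factors)[None, :] * np.exp(
        -np.outer(s2, structure.b_factors) / 4.0
    )
    phase = np.exp(2j * np.pi * (hkls @ frac.T))
    return (amp * phase).sum(axis=1)


def scramble(structure: ToyStructure, sd: float, seed=None) -> ToyStructure:
    """Displace every Cartesian coordinate by i.i.d. N(0, sd²) noise."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    out = structure.copy()
    if sd > 0:
        rng = rng_from(seed)
        out.coordinates = out.coordinates + rng.normal(0.0, sd, out.coordinates.shape)
    return out


def _pack_parameters(structure: ToyStructure, opts: RefinementOptions):
    """Index bookkeeping for the free-parameter vector (scale excluded)."""
    pos_atoms: list[int] = []
    if opts.refine_positions:
        for i, atom in enumerate(structure.atoms):
            if opts.position_roles is None or atom.role in opts.position_roles:
                pos_atoms.append(i)
    b_atoms = list(range(len(structure.atoms))) if opts.refine_b else []
    occ_atoms = list(range(len(structure.atoms))) if opts.refine_occupancies else []
    return pos_atoms, b_atoms, occ_atoms


def _model_and_jacobian(structure, hkls, s2, opts, pos_atoms, b_atoms, occ_atoms):
    """|F|² and its Jacobian w.r.t. the packed structural parameters."""
    frac_mat = structure.cell.fractionalization
    frac = structure.coordinates @ frac_mat.T
    occ_f = structure.occupancies * structure.form_factors
    amp = occ_f[None, :] * np.exp(-np.outer(s2, structure.b_factors) / 4.0)
    phase = np.exp(2j * np.pi * (hkls @ frac.T))
    terms = amp * phase                      # (n_hkl, n_atom)
    F = terms.sum(axis=1)
    I = np.abs(F) ** 2

    cols = []
    # d|F|²/dp = 2 Re(conj(F) dF/dp)
    conjF = np.conj(F)
    if pos_atoms:
        # d(hkl·x_frac)/dx_cart = frac_mat^T @ hkl  -> per hkl a 3-vector
        hm = hkls @ frac_mat                 # (n_hkl, 3)
        for j in pos_atoms:
            dF = 2j * np.pi * hm * terms[:, j][:, None]   # (n_hkl, 3)
            cols.append(2.0 * np.real(conjF[:, None] * dF))
    for j in b_atoms:
        dF = -(s2 / 4.0) * terms[:, j]
        cols.append(2.0 * np.real(conjF * dF)[:, None])
    for j in occ_atoms:
        occ = structure.atoms[j].occupancy
        dF = terms[:, j] / occ if occ > 0 else (
            structure.atoms[j].form_factor
            * np.exp(-s2 * structure.atoms[j].b_factor / 4.0)
            * np.exp(2j * np.pi * (hkls @ frac[j]))
        )
        cols.append(2.0 * np.real(conjF * dF)[:, None])
    J = np.concatenate(cols, axis=1) if cols else np.zeros((len(F), 0))
    return I, J


def _apply_parameters(structure, delta, opts, pos_atoms, b_atoms, occ_atoms):
    k = 0
    coords = structure.coordinates
    for j in pos_atoms:
        coords[j] += delta[k:k + 3]
        k += 3
    structure.coordinates = coords
    for j in b_atoms:
        structure.atoms[j].b_factor = max(0.0, structure.atoms[j].b_factor + delta[k])
        k += 1
    for j in occ_atoms:
        structure.atoms[j].occupancy = float(
            np.clip(structure.atoms[j].occupancy + delta[k], 0.0, 1.0)
        )
        k += 1


def refine(
    start: ToyStructure,
    merged,
    opts: RefinementOptions | None = None,
    weights: np.ndarray | None = None,
) -> RefinementResult:
    """Levenberg–Marquardt refinement against merged intensities.

    ``merged`` is a :class:`~ssxdamage.merging.MergedDataset` (anything with
    an ``entries`` mapping (h,k,l) -> record with ``mean_I`` works).  The
    overall scale is always refined; positions/Bs/occupancies per ``opts``.
    Marquardt damping is adjusted ×10 on rejection and ÷10 on acceptance;
    steps that do not increase the residual are accepted.
    """
    opts = opts or RefinementOptions()
    structure = start.copy()
    if opts.scramble_sd > 0:
        structure = scramble(structure, opts.scramble_sd, opts.seed)

    hkls = np.array(sorted(merged.entries.keys()), dtype=float)
    i_obs = np.array([merged.entries[tuple(int(v) for v in h)].mean_I for h in hkls])
    w = np.ones_like(i_obs) if weights is None else np.asarray(weights, dtype=float)
    s2 = 1.0 / structure.cell.d_spacing(hkls) ** 2

    pos_atoms, b_atoms, occ_atoms = _pack_parameters(structure, opts)
    n_par = 1 + 3 * len(pos_atoms) + len(b_atoms) + len(occ_atoms)
    if len(i_obs) <= n_par:
        raise UnderdeterminedError(
            f"{len(i_obs)} observations for {n_par} free parameters"
        )

    def residual_for(struct, scale):
        I, _ = _model_and_jacobian(struct, hkls, s2, opts, [], [], [])
        return float(np.sum(w * (i_obs - scale * I) ** 2))

    # initial scale: weighted linear LSQ given the starting model
    I0, _ = _model_and_jacobian(structure, hkls, s2, opts, [], [], [])
    scale = float(np.sum(w * i_obs * I0) / np.sum(w * I0**2))
    resid = residual_for(structure, scale)

    lam = 1e-3
    history = [(0, resid, 0.0)]
    converged = False
    n_iter = 0
    for n_iter in range(1, opts.max_iter + 1):
        I, Jstruct = _model_and_jacobian(
            structure, hkls, s2, opts, pos_atoms, b_atoms, occ_atoms
        )
        r = i_obs - scale * I
        # residual Jacobian: dr/dscale = -I ; dr/dstruct = -scale * dI/dp
        J = np.concatenate([-I[:, None], -scale * Jstruct], axis=1)
        sw = np.sqrt(w)
        A = (sw[:, None] * J).T @ (sw[:, None] * J)
        g = (sw[:, None] * J).T @ (sw * r)
        accepted = False
        for _ in range(12):
            try:
                delta = np.linalg.solve(A + lam * np.diag(np.diag(A) + 1e-30), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = structure.copy()
            trial_scale = scale + delta[0]
            _apply_parameters(trial, delta[1:], opts, pos_atoms, b_atoms, occ_atoms)
            trial_resid = residual_for(trial, trial_scale)
            if trial_resid <= resid:
                structure, scale = trial, trial_scale
                shift = float(np.linalg.norm(delta))
                improvement = resid - trial_resid
                resid = trial_resid
                lam = max(lam / 10.0, 1e-12)
                history.append((n_iter, resid, shift))
                accepted = True
                if shift < opts.convergence_tol or improvement <= opts.convergence_tol * (
                    1.0 + resid
                ):
                    converged = True
                break
            lam *= 10.0
        if not accepted:
            converged = True  # no acceptable step: at a (possibly flat) minimum
            break
        if converged:
            break
    return RefinementResult(structure, scale, n_iter, converged, resid, history)


def refine_two_state_water(
    start: ToyStructure,
    merged,
    opts: RefinementOptions | None = None,
) -> dict:
    """Two-conformer water occupancy refinement with steric anti-correlation.

    The distal water is modelled in two alternative positions (roles
    ``WAT_O`` = heme-coordinating pos1 and ``WAT_O_ALT`` = remote pos2) with
    occupancies constrained to ``occ_pos1 + occ_pos2 = 1`` and the adjacent
    water ``WATX_O`` anti-correlated with pos2 (``occ_watx = 1 − occ_pos2``),
    i.e. a single free occupancy parameter alongside the overall scale.
    """
    from scipy.optimize import minimize_scalar

    opts = opts or RefinementOptions()
    structure = start.copy()
    for role in (ROLE_WAT, ROLE_WAT_ALT, ROLE_WATX):
        structure.atom(role)  # raises if missing

    hkls = np.array(sorted(merged.entries.keys()), dtype=float)
    i_obs = np.array([merged.entries[tuple(int(v) for v in h)].mean_I for h in hkls])
    s2 = 1.0 / structure.cell.d_spacing(hkls) ** 2

    def set_occ(struct, q):
        struct.atom(ROLE_WAT).occupancy = q
        struct.atom(ROLE_WAT_ALT).occupancy = 1.0 - q
        struct.atom(ROLE_WATX).occupancy = q  # 1 - occ_pos2

    def loss(q):
        trial = structure.copy()
        set_occ(trial, float(np.clip(q, 0.0, 1.0)))
        I = np.abs(calc_structure_factors(trial, hkls)) ** 2
        scale = float(np.sum(i_obs * I) / np.sum(I**2))
        return float(np.sum((i_obs - scale * I) ** 2))

    res = minimize_scalar(loss, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-6})
    q = float(res.x)
    return {"occ_pos1": q, "occ_pos2": 1.0 - q, "occ_watx": q,
            "residual": float(res.fun)}
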