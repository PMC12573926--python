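"""Coordinate-file parsing and heme-site geometric measurements.

Reads PDB files (via Biopython), assigns heme-site roles by residue/atom
name and proximity rules, and measures the distal/proximal coordination
geometry: Fe–Wat, Fe–His, the signed iron-out-of-plane displacement from a
total-least-squares porphyrin plane, O–O separation of a diatomic distal
ligand, the Fe–O–O and Fe–Wat–WatX angles, and hydrogen-bond distances
around the coordinating water.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Atom,
    GeometryError,
    ToyStructure,
    UnitCell,
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

PYRROLE_N = ("NA", "NB", "NC", "ND")
#: heme 24-atom core (porphyrin ring) atom names, for the wide-plane option
HEME_CORE = PYRROLE_N + tuple(
    f"C{i}{j}" for i in "1234" for j in "ABCD"
) + tuple(f"CH{j}" for j in "ABCD")

MAX_FE_WAT = 3.2       # Å, water counted as coordinating the iron
MAX_DIATOMIC_OO = 2.2  # Å, two O atoms counted as one diatomic ligand
HBOND_MAX = 3.5        # Å


@dataclass
class PlaneFit:
    normal: np.ndarray
    centroid: np.ndarray
    rmsd: float


@dataclass
class GeometryReport:
    chain: str
    fe_wat: float | None = None
    fe_his: float | None = None
    feoop: float | None = None
    o_o: float | None = None
    fe_o_o_angle: float | None = None
    fe_wat_watx_angle: float | None = None
    wat_watx: float | None = None
    hbonds: dict = field(default_factory=dict)
    missing: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "chain": self.chain, "fe_wat": self.fe_wat, "fe_his": self.fe_his,
            "feoop": self.feoop, "o_o": self.o_o,
            "fe_o_o_angle": self.fe_o_o_angle,
            "fe_wat_watx_angle": self.fe_wat_watx_angle,
            "wat_watx": self.wat_watx, "hbonds": dict(self.hbonds),
            "missing": list(self.missing),
        }


def lsq_plane(points: np.ndarray) -> PlaneFit:
    """Total-least-squares plane through >= 3 points.

    The normal is the singular vector of the centred coordinates with the
    smallest singular value; collinear inputs are rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise GeometryError("need at least 3 points in 3-D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10 * max(s[0], 1e-300):
        raise GeometryError("points are collinear; plane is undefined")
    normal = vt[2]
    rmsd = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return PlaneFit(normal=normal, centroid=centroid, rmsd=rmsd)


def signed_plane_distance(fit: PlaneFit, point: np.ndarray) -> float:
    return float((np.asarray(point, dtype=float) - fit.centroid) @ fit.normal)


def _distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def angle(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> float:
    """Angle a–vertex–c in degrees."""
    u = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    v = np.asarray(c, dtype=float) - np.asarray(vertex, dtype=float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def heme_report(
    structure: ToyStructure,
    chain: str | None = None,
    plane: str = "pyrrole",
) -> GeometryReport:
    """All heme-site measurements available from the assigned roles.

    ``plane`` selects the porphyrin-plane convention: ``"pyrrole"`` (the four
    pyrrole N atoms, default) or ``"core"`` (all plane-role atoms, which for
    parsed files with the 24-atom option includes the full ring).  FeOOP is
    signed positive toward the distal (water) side.  Missing role atoms are
    reported in ``missing`` rather than raising.
    """
    rep = GeometryReport(chain=chain or structure.chain)

    def pos(role):
        found = structure.atoms_with_role(role)
        return found[0].xyz if found else None

    fe = pos(ROLE_FE)
    plane_pts = np.array([a.xyz for a in structure.atoms_with_role(ROLE_PLANE)])
    wat, watx, his = pos(ROLE_WAT), pos(ROLE_WATX), pos(ROLE_HIS)
    o1, o2 = pos(ROLE_O1), pos(ROLE_O2)

    if wat is not None:
        rep.fe_wat = _distance(fe, wat)
    elif o1 is not None:
        rep.fe_wat = _distance(fe, o1)  # diatomic ligand: proximal O stands in
    else:
        rep.missing.append(ROLE_WAT)
    if his is not None:
        rep.fe_his = _distance(fe, his)
    else:
        rep.missing.append(ROLE_HIS)
    if len(plane_pts) >= 3:
        fit = lsq_plane(plane_pts)
        d = signed_plane_distance(fit, fe)
        distal = wat if wat is not None else o1
        reference = distal if distal is not None else his
        flip = 1.0
        if reference is not None:
            side = signed_plane_distance(fit, reference)
            if distal is None:
                side = -side  # His marks the proximal side
            flip = 1.0 if side >= 0 else -1.0
        rep.feoop = flip * d
    else:
        rep.missing.append(ROLE_PLANE)
    if o1 is not None and o2 is not None:
        rep.o_o = _distance(o1, o2)
        rep.fe_o_o_angle = angle(fe, o1, o2)
    if wat is not None and watx is not None:
        rep.wat_watx = _distance(wat, watx)
        rep.hbonds["wat-watx"] = rep.wat_watx
        rep.fe_wat_watx_angle = angle(fe, wat, watx)
    # named hydrogen-bond partners picked up at parse time
    if wat is not None:
        for atom in structure.atoms_with_role(ROLE_BYSTANDER):
            if atom.name.startswith(("ARG", "ASP")):
                dist = _distance(wat, atom.xyz)
                if dist <= HBOND_MAX:
                    rep.hbonds[f"wat-{atom.name.lower()}"] = dist
    return rep


# ---------------------------------------------------------------------------
# PDB input/output
# ---------------------------------------------------------------------------

_ROLE_TO_PDB = {
    ROLE_FE: ("HETATM", "FE", "HEM", 101),
    ROLE_HIS: ("ATOM", "NE2", "HIS", 26),
    ROLE_WAT: ("HETATM", "O", "HOH", 201),
    ROLE_WAT_ALT: ("HETATM", "O", "HOH", 202),
    ROLE_WATX: ("HETATM", "O", "HOH", 203),
    ROLE_O1: ("HETATM", "O1", "PEO", 102),
    ROLE_O2: ("HETATM", "O2", "PEO", 102),
}


def write_pdb(structure: ToyStructure, path) -> None:
    """Write a toy structure as a minimal PDB file (CRYST1 + ATOM/HETATM)."""
    cell = structure.cell
    lines = [
        f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
        f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} P 1           1"
    ]
    serial = 1
    plane_seen = 0
    byst_seen = 0
    for atom in structure.atoms:
        if atom.role == ROLE_PLANE:
            record, name, resname, resseq = "HETATM", PYRROLE_N[plane_seen % 4], "HEM", 101
            plane_seen += 1
        elif atom.role == ROLE_BYSTANDER:
            byst_seen += 1
            record, name, resname, resseq = "HETATM", f"C{byst_seen}", "UNK", 300 + byst_seen
        else:
            record, name, resname, resseq = _ROLE_TO_PDB[atom.role]
        x, y, z = atom.xyz
        el = atom.element.upper().rjust(2)
        pdb_name = name if len(name) == 4 else f" {name}"
        lines.append(
            f"{record:<6}{serial:>5} {pdb_name:<4} {resname:<3} "
            f"{structure.chain}{resseq:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
            f"          {el}"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_structure(path):
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PDBParser(QUIET=True).get_structure("model", str(path))


def _read_cryst1(path) -> UnitCell | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                try:
                    return UnitCell(
                        float(line[6:15]), float(line[15:24]), float(line[24:33]),
                        float(line[33:40]), float(line[40:47]), float(line[47:54]),
                    )
                except ValueError:
                    return None
    return None


def read_coordinates(
    path,
    use_first_altloc: bool = True,
    plane: str = "pyrrole",
) -> tuple[dict[str, ToyStructure], pd.DataFrame]:
    """Parse a PDB file and assign heme-site roles per chain.

    Returns one :class:`ToyStructure` per chain that carries a heme (keyed by
    chain id) plus a role-assignment table covering every assigned atom.
    Role rules: heme FE and pyrrole N atoms by residue/atom name (HEM, or
    the PEO/UNK toy residues written by :func:`write_pdb`), the proximal His
    NE2 as the closest one to the iron, the coordinating water as the
    closest water O within 3.2 Å of the iron, WatX as the water closest to
    the coordinating water, and a diatomic distal ligand either from
    O1/O2-named het atoms near the iron or from two waters within 2.2 Å of
    each other.  Arg/Asp side-chain partners within hydrogen-bond range of
    the coordinating water are retained for the H-bond report.
    """
    model = _parse_structure(path)[0]
    cell = _read_cryst1(path) or UnitCell(1.0, 1.0, 1.0)

    structures: dict[str, ToyStructure] = {}
    rows = []
    candidates = []
    for bio_chain in model:
        chain_id = bio_chain.id.strip() or "A"
        heme = None
        for res in bio_chain:
            if res.get_resname().strip() in ("HEM", "HEC", "HEA", "HEB"):
                heme = res
                break
        if heme is None:
            candidates.extend(
                res.get_resname().strip() for res in bio_chain
                if not res.id[0].startswith("W") and res.id[0] != " "
            )
            continue

        def atom_xyz(bio_atom):
            if bio_atom.is_disordered():
                bio_atom = sorted(bio_atom.child_dict.values(),
                                  key=lambda a: a.get_altloc())[0]
            return np.array(bio_atom.get_coord(), dtype=float)

        atoms: list[Atom] = []

        def add(name, element, role, bio_atom, resname, resseq):
            atoms.append(Atom(name, element, role, atom_xyz(bio_atom),
                              b_factor=float(bio_atom.get_bfactor()),
                              occupancy=float(min(1.0, bio_atom.get_occupancy() or 1.0))))
            rows.append((chain_id, resname, resseq, name, role))

        if "FE" not in heme:
            raise GeometryError(
                f"chain {chain_id}: heme residue without FE atom"
            )
        add("FE", "FE", ROLE_FE, heme["FE"], "HEM", heme.id[1])
        fe_pos = atom_xyz(heme["FE"])
        plane_names = PYRROLE_N if plane == "pyrrole" else HEME_CORE
        for nm in plane_names:
            if nm in heme:
                element = "N" if nm.startswith("N") else "C"
                add(nm, element, ROLE_PLANE, heme[nm], "HEM", heme.id[1])
        if sum(a.role == ROLE_PLANE for a in atoms) < 3:
            raise GeometryError(
                f"chain {chain_id}: fewer than 3 porphyrin plane atoms"
            )

        # proximal histidine: nearest HIS NE2 (fall back to ND1)
        best = None
        for res in bio_chain:
            if res.get_resname().strip() != "HIS":
                continue
            for nm in ("NE2", "ND1"):
                if nm in res:
                    dist = np.linalg.norm(atom_xyz(res[nm]) - fe_pos)
                    if best is None or dist < best[0]:
                        best = (dist, res, nm)
        if best is not None and best[0] < 3.5:
            add(best[2], "N", ROLE_HIS, best[1][best[2]], "HIS", best[1].id[1])

        # waters of this chain
        waters = []
        for res in bio_chain:
            if res.get_resname().strip() in ("HOH", "WAT") and "O" in res:
                waters.append((res, atom_xyz(res["O"])))
        wat_entry = None
        if waters:
            dists = [np.linalg.norm(p - fe_pos) for _, p in waters]
            j = int(np.argmin(dists))
            if dists[j] <= MAX_FE_WAT:
                wat_entry = waters[j]
                add("O", "O", ROLE_WAT, wat_entry[0]["O"], "HOH", wat_entry[0].id[1])
        if wat_entry is not None and len(waters) > 1:
            wp = wat_entry[1]
            others = [(r, p) for r, p in waters if r is not wat_entry[0]]
            dists = [np.linalg.norm(p - wp) for _, p in others]
            j = int(np.argmin(dists))
            if dists[j] <= HBOND_MAX:
                resx, posx = others[j]
                if dists[j] <= MAX_DIATOMIC_OO:
                    # two waters this close are one diatomic ligand
                    add("O1", "O", ROLE_O1, wat_entry[0]["O"], "HOH", wat_entry[0].id[1])
                    add("O2", "O", ROLE_O2, resx["O"], "HOH", resx.id[1])
                else:
                    add("OX", "O", ROLE_WATX, resx["O"], "HOH", resx.id[1])

        # explicit diatomic ligand residues (peroxo-like codes, or toy PEO)
        for res in bio_chain:
            if res.get_resname().strip() in ("PEO", "PER", "OXY", "HPO"):
                if "O1" in res and "O2" in res:
                    if np.linalg.norm(atom_xyz(res["O1"]) - fe_pos) < MAX_FE_WAT:
                        add("O1", "O", ROLE_O1, res["O1"], res.get_resname(), res.id[1])
                        add("O2", "O", ROLE_O2, res["O2"], res.get_resname(), res.id[1])

        # H-bond partners of the coordinating water (Arg NH1/NH2, Asp OD1/OD2)
        if wat_entry is not None:
            wp = wat_entry[1]
            for res in bio_chain:
                resname = res.get_resname().strip()
                if resname == "ARG":
                    names = ("NH1", "NH2", "NE")
                elif resname == "ASP":
                    names = ("OD1", "OD2")
                else:
                    continue
                for nm in names:
                    if nm in res and np.linalg.norm(atom_xyz(res[nm]) - wp) <= HBOND_MAX:
                        add(f"{resname}{res.id[1]}_{nm}", nm[0], ROLE_BYSTANDER,
                            res[nm], resname, res.id[1])

        structures[chain_id] = ToyStructure(atoms, cell, chain=chain_id)

    if not structures:
        raise GeometryError(
            "no heme found in any chain; het residues present: "
            + (", ".join(sorted(set(candidates))) or "none")
        )
    table = pd.DataFrame(rows, columns=["chain", "resname", "resseq", "atom", "role"])
    return structures, table
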