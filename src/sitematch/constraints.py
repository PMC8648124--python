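"""Geometric-constraint file writer for the external Rosetta matcher.

The relative placement of the ligand and each binding-site residue is
pinned by six anchor atoms.  On the ligand side: the heavy atom closest to
the protein residue, then the two ligand heavy atoms closest to that first
atom.  On the residue side, the mirror rule: the heavy atom closest to the
ligand, then the two residue heavy atoms closest to that first atom.  The
distance between the two first atoms is constrained at its observed value;
the four angles/torsions are constrained at their observed values and
sampled at the ideal value and +/-10 degrees.

This module only writes the file; running the matcher is external.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core import Atom, BindingSite, Residue
from .errors import ParameterError
from .geometry import dihedral

__all__ = ["write_constraint_file", "constraint_blocks"]

ANGLE_TOLERANCE = 10.0  # degrees sampled around the ideal value
DISTANCE_TOLERANCE = 0.1  # angstroms; distances sampled at ideal values only
FORCE_CONSTANT = 100.0


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _anchor_atoms(primary_pool: Sequence[Atom], other_coords: np.ndarray
                  ) -> list[Atom]:
    """First atom closest to the partner, then the two atoms closest to it."""
    coords = np.array([a.coord for a in primary_pool])
    first = int(cdist(coords, other_coords).min(axis=1).argmin())
    rest = [i for i in range(len(primary_pool)) if i != first]
    d_to_first = np.linalg.norm(coords[rest] - coords[first], axis=1)
    order = [rest[i] for i in np.argsort(d_to_first, kind="stable")[:2]]
    return [primary_pool[first]] + [primary_pool[i] for i in order]


def constraint_blocks(site: BindingSite) -> list[str]:
    """One CST block per site residue, as formatted text."""
    lig_atoms = site.ligand.atoms
    if len(lig_atoms) < 3:
        raise ParameterError(
            "constraint generation needs a ligand with at least 3 heavy atoms"
        )
    blocks = []
    for res in site.residues:
        blocks.append(_block_for_residue(site, res))
    return blocks


def _block_for_residue(site: BindingSite, res: Residue) -> str:
    res_atoms = res.heavy_atoms()
    if len(res_atoms) < 3:
        raise ParameterError(
            f"residue {res.chain_id}{res.seq_index} has fewer than 3 heavy atoms"
        )
    res_coords = np.array([a.coord for a in res_atoms])
    lig = _anchor_atoms(site.ligand.atoms, res_coords)
    prot = _anchor_atoms(res_atoms, site.ligand.coords())
    l1, l2, l3 = (a.coord for a in lig)
    p1, p2, p3 = (a.coord for a in prot)

    dist_ab = float(np.linalg.norm(l1 - p1))
    angle_a = _angle(l2, l1, p1)
    angle_b = _angle(l1, p1, p2)
    torsion_a = dihedral(l3, l2, l1, p1)
    torsion_ab = dihedral(l2, l1, p1, p2)
    torsion_b = dihedral(l1, p1, p2, p3)

    lines = [
        "CST::BEGIN",
        f"  TEMPLATE::   ATOM_MAP: 1 atom_name: {lig[0].name} {lig[1].name} {lig[2].name}",
        f"  TEMPLATE::   ATOM_MAP: 1 residue3: {site.ligand.resname}",
        "",
        f"  TEMPLATE::   ATOM_MAP: 2 atom_name: {prot[0].name} {prot[1].name} {prot[2].name}",
        f"  TEMPLATE::   ATOM_MAP: 2 residue3: {res.resname}",
        "",
        f"  CONSTRAINT:: distanceAB: {dist_ab:8.2f} {DISTANCE_TOLERANCE:6.2f} {FORCE_CONSTANT:7.2f}       0    0",
        f"  CONSTRAINT::    angle_A: {angle_a:8.2f} {ANGLE_TOLERANCE:6.2f} {FORCE_CONSTANT:7.2f}  360.00    1",
        f"  CONSTRAINT::    angle_B: {angle_b:8.2f} {ANGLE_TOLERANCE:6.2f} {FORCE_CONSTANT:7.2f}  360.00    1",
        f"  CONSTRAINT::  torsion_A: {torsion_a:8.2f} {ANGLE_TOLERANCE:6.2f} {FORCE_CONSTANT:7.2f}  360.00    1",
        f"  CONSTRAINT:: torsion_AB: {torsion_ab:8.2f} {ANGLE_TOLERANCE:6.2f} {FORCE_CONSTANT:7.2f}  360.00    1",
        f"  CONSTRAINT::  torsion_B: {torsion_b:8.2f} {ANGLE_TOLERANCE:6.2f} {FORCE_CONSTANT:7.2f}  360.00    1",
        "CST::END",
    ]
    return "\n".join(lines)


def write_constraint_file(site: BindingSite, path) -> None:
    """Write the matcher constraint file for a binding site."""
    text = "\n\n".join(constraint_blocks(site)) + "\n"
    with open(path, "w") as fh:
        fh.write(text)
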