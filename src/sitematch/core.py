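"""Data model: atoms, residues, ligands, structures and binding sites.

Coordinates are float64 numpy arrays in angstroms.  Protein residues are
renumbered sequentially (1..n per chain) on input, and all primary-sequence
distances use that sequential index.  Hydrogens are dropped on input; every
geometric threshold in the package operates on heavy atoms only.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .errors import ParameterError
from .geometry import RigidTransform

__all__ = [
    "Atom",
    "Residue",
    "Ligand",
    "Structure",
    "BindingSite",
    "construct_ideal_cb",
    "BACKBONE_ATOMS",
    "AA_THREE_TO_ONE",
    "AA_HEAVY_ATOM_COUNTS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Expected heavy-atom counts for complete residues (backbone + side chain).
AA_HEAVY_ATOM_COUNTS = {
    "G": 4, "A": 5, "S": 6, "C": 6, "V": 7, "T": 7, "P": 7,
    "L": 8, "I": 8, "N": 8, "D": 8, "M": 8, "Q": 9, "E": 9,
    "K": 9, "H": 10, "R": 11, "F": 11, "Y": 12, "W": 14,
}

IDEAL_CA_CB_LENGTH = 1.52  # angstroms


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.element = self.element.upper()
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ParameterError(
                f"atom {self.name}: coord must be 3 finite components"
            )
        self.coord = coord

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_index: int  # 1-based sequential position within the chain
    aa_type: str  # one-letter code ('X' for non-standard)
    resname: str  # three-letter code
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> Optional[np.ndarray]:
        a = self.atom(name)
        return None if a is None else a.coord

    @property
    def is_matchable(self) -> bool:
        """Residues lacking any of N, CA, C cannot anchor or be matched."""
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))

    @property
    def ca(self) -> Optional[np.ndarray]:
        return self.coord("CA")

    @property
    def cb(self) -> Optional[np.ndarray]:
        """Real CB when present, otherwise an ideal constructed CB.

        Glycine and residues with a truncated side chain still need a
        CA->CB direction for the cosine filter and the burial cone.
        """
        real = self.coord("CB")
        if real is not None:
            return real
        if not self.is_matchable:
            return None
        return construct_ideal_cb(self)

    def backbone_coords(self) -> np.ndarray:
        """(3, 3) array of N, CA, C coordinates."""
        if not self.is_matchable:
            raise ParameterError(
                f"residue {self.chain_id}{self.seq_index} is missing backbone atoms"
            )
        return np.array([self.coord("N"), self.coord("CA"), self.coord("C")])

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.heavy_atoms()]).reshape(-1, 3)

    def side_chain_heavy_atoms(self) -> list[Atom]:
        """Heavy atoms outside the fixed backbone set {N, CA, C, O}."""
        return [a for a in self.heavy_atoms() if a.name not in BACKBONE_ATOMS]

    def is_complete(self) -> bool:
        """True when no heavy atom expected for this residue type is missing."""
        expected = AA_HEAVY_ATOM_COUNTS.get(self.aa_type)
        if expected is None:
            return True
        return len(self.heavy_atoms()) >= expected

    def copy(self) -> "Residue":
        return copy.deepcopy(self)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_index)


@dataclass
class Ligand:
    resname: str
    atoms: list[Atom]
    source: str = ""

    def __post_init__(self) -> None:
        self.atoms = [a for a in self.atoms if a.is_heavy]

    @property
    def n_heavy(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms]).reshape(-1, 3)

    @property
    def mean_b_factor(self) -> float:
        if not self.atoms:
            return 0.0
        return float(np.mean([a.b_factor for a in self.atoms]))

    def copy(self) -> "Ligand":
        return copy.deepcopy(self)


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    ligands: list[Ligand] = field(default_factory=list)
    resolution: Optional[float] = None

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def matchable_residues(self) -> list[Residue]:
        return [r for r in self.residues() if r.is_matchable]

    def residue(self, chain_id: str, seq_index: int) -> Residue:
        for r in self.chains[chain_id]:
            if r.seq_index == seq_index:
                return r
        raise KeyError((chain_id, seq_index))

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def transformed(self, transform: RigidTransform) -> "Structure":
        out = self.copy()
        for r in out.residues():
            for a in r.atoms:
                a.coord = transform.apply(a.coord)
        for lig in out.ligands:
            for a in lig.atoms:
                a.coord = transform.apply(a.coord)
        return out


@dataclass
class BindingSite:
    """A ligand plus its interacting residues, carried as one rigid unit."""

    ligand: Ligand
    residues: list[Residue]
    source_id: str = ""
    per_residue_score: dict[tuple[str, int], float] = field(default_factory=dict)
    site_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ParameterError("a binding site needs at least two residues")

    @property
    def id(self) -> str:
        return self.site_id or f"{self.source_id}:{self.ligand.resname}"

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def copy(self) -> "BindingSite":
        return copy.deepcopy(self)

    def transformed(self, transform: RigidTransform) -> "BindingSite":
        """Apply a rigid transform jointly to the ligand and all residues."""
        out = self.copy()
        for r in out.residues:
            for a in r.atoms:
                a.coord = transform.apply(a.coord)
        for a in out.ligand.atoms:
            a.coord = transform.apply(a.coord)
        return out

    def all_heavy_coords(self) -> np.ndarray:
        parts = [r.heavy_coords() for r in self.residues]
        parts.append(self.ligand.coords())
        return np.vstack(parts)


def construct_ideal_cb(residue: Residue) -> np.ndarray:
    """Ideal tetrahedral CB position from the N, CA, C backbone atoms.

    Returns a point 1.52 angstroms from CA along the direction an L-amino
    acid side chain would take.  Deterministic and SE(3)-equivariant.
    """
    n, ca, c = (residue.coord(x) for x in ("N", "CA", "C"))
    if n is None or ca is None or c is None:
        raise ParameterError(
            f"residue {residue.chain_id}{residue.seq_index}: N, CA, C required"
        )
    b = ca - n
    cvec = c - ca
    a = np.cross(b, cvec)
    raw = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cvec
    return ca + IDEAL_CA_CB_LENGTH * raw / np.linalg.norm(raw)
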