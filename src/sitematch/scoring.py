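"""Residue-ligand interaction scoring.

Ligand binding-site residues are selected by the sign and size of their
pairwise interaction with the ligand.  The default scorer is a transparent
physics-motivated proxy with three favourable terms:

* ``attraction`` — a 6-12 Lennard-Jones well over heavy-atom pairs, with the
  per-pair energy capped at zero so the term is attractive by construction;
  the positive (overlap) part is accumulated separately as ``repulsion`` and
  used only for clash-quality filtering.
* ``electrostatic`` — Coulomb energy with a distance-dependent dielectric
  (eps = slope * d) over assigned formal charges.
* ``hbond`` — a distance- and angle-gated bonus between donor and acceptor
  heavy atoms.

``total = attraction + electrostatic + hbond``.  The scorer is a pluggable
interface (see :data:`SCORERS`); an external force-field-backed scorer can
be registered under a new name.  All terms depend only on interatomic
distances and internal angles, so scores are invariant under a joint rigid
transform of residue and ligand.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import Atom, Ligand, Residue
from .errors import ConfigurationError

__all__ = [
    "InteractionScore",
    "ScoringParams",
    "score_interaction",
    "LJ_RADII",
    "SCORERS",
]

# Per-element Lennard-Jones radii (angstroms).  Metals use ionic radii.
LJ_RADII = {
    "C": 2.0, "N": 1.75, "O": 1.55, "S": 1.9, "P": 2.1, "H": 1.0,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.9, "B": 1.92,
    "MG": 0.72, "ZN": 0.74, "NA": 1.02, "K": 1.38, "FE": 0.65,
    "MN": 0.83, "CA": 1.0, "CU": 0.7, "NI": 0.69, "CO": 0.75,
}

# Formal charges for titratable side-chain atoms, keyed (resname, atom name).
RESIDUE_CHARGES = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5, ("ARG", "NE"): 0.25,
    ("HIS", "ND1"): 0.25, ("HIS", "NE2"): 0.25,
}

# Formal charges for common ionic ligand elements.
ELEMENT_CHARGES = {
    "MG": 2.0, "ZN": 2.0, "CA": 2.0, "MN": 2.0, "FE": 2.0,
    "NA": 1.0, "K": 1.0, "CU": 1.0, "NI": 2.0, "CO": 2.0,
    "CL": -1.0, "BR": -1.0, "I": -1.0, "F": -1.0,
}

DONOR_ELEMENTS = {"N"}
ACCEPTOR_ELEMENTS = {"O", "N"}
HYDROXYL_ATOMS = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG")}


@dataclass(frozen=True)
class InteractionScore:
    attraction: float
    electrostatic: float
    hbond: float
    repulsion: float = 0.0  # diagnostic only; not part of total

    @property
    def total(self) -> float:
        return self.attraction + self.electrostatic + self.hbond


@dataclass(frozen=True)
class ScoringParams:
    lj_epsilon: float = 0.5  # well depth, energy units
    lj_cutoff: float = 6.0  # angstroms
    coulomb_constant: float = 332.0
    dielectric_slope: float = 10.0  # eps(d) = slope * d
    elec_cutoff: float = 8.0
    hbond_min: float = 2.5
    hbond_max: float = 3.4
    hbond_bonus: float = -1.0  # per donor/acceptor pair at ideal distance
    radii: dict = field(default_factory=lambda: dict(LJ_RADII))


def _radius(element: str, params: ScoringParams) -> float:
    try:
        return params.radii[element]
    except KeyError:
        raise ConfigurationError(
            f"no Lennard-Jones radius for element {element!r}"
        ) from None


def _residue_charge(residue: Residue, atom: Atom) -> float:
    q = RESIDUE_CHARGES.get((residue.resname, atom.name))
    if q is not None:
        return q
    return ELEMENT_CHARGES.get(atom.element, 0.0)


def _ligand_charge(atom: Atom) -> float:
    return ELEMENT_CHARGES.get(atom.element, 0.0)


def _is_donor(residue_name: str, atom: Atom) -> bool:
    return atom.element in DONOR_ELEMENTS or (residue_name, atom.name) in HYDROXYL_ATOMS


def _is_acceptor(atom: Atom) -> bool:
    return atom.element in ACCEPTOR_ELEMENTS


def _bonded_neighbor(atom: Atom, atoms: list[Atom]) -> Atom | None:
    """Nearest heavy atom within covalent range, used for the H-bond angle gate."""
    best, best_d = None, 1.9
    for other in atoms:
        if other is atom:
            continue
        d = float(np.linalg.norm(other.coord - atom.coord))
        if d < best_d:
            best, best_d = other, d
    return best


def _hbond_weight(d: float, params: ScoringParams) -> float:
    """Trapezoidal distance ramp: full bonus on [min+0.1, max-0.2], 0 at edges."""
    lo, hi = params.hbond_min, params.hbond_max
    if d <= lo or d >= hi:
        return 0.0
    if d < lo + 0.1:
        return (d - lo) / 0.1
    if d > hi - 0.2:
        return (hi - d) / 0.2
    return 1.0


def score_interaction(
    residue: Residue, ligand: Ligand, params: ScoringParams | None = None
) -> InteractionScore:
    """Score the pairwise interaction between one residue and a ligand."""
    params = params or ScoringParams()
    res_atoms = residue.heavy_atoms()
    lig_atoms = ligand.atoms
    if not res_atoms or not lig_atoms:
        return InteractionScore(0.0, 0.0, 0.0)

    attraction = repulsion = elec = hbond = 0.0
    for ra in res_atoms:
        qr = _residue_charge(residue, ra)
        for la in lig_atoms:
            d = float(np.linalg.norm(ra.coord - la.coord))
            if d < 1e-6:
                d = 1e-6
            if d < params.lj_cutoff:
                rsum = _radius(ra.element, params) + _radius(la.element, params)
                sigma = rsum * 2.0 ** (-1.0 / 6.0)
                sr6 = (sigma / d) ** 6
                e = 4.0 * params.lj_epsilon * (sr6 * sr6 - sr6)
                if e < 0.0:
                    attraction += e
                else:
                    repulsion += e
            ql = _ligand_charge(la)
            if qr != 0.0 and ql != 0.0 and d < params.elec_cutoff:
                elec += params.coulomb_constant * qr * ql / (
                    params.dielectric_slope * d * d
                )
            w = _hbond_weight(d, params)
            if w > 0.0 and (
                (_is_donor(residue.resname, ra) and _is_acceptor(la))
                or (_is_acceptor(ra) and _is_donor(ligand.resname, la))
            ):
                if _angle_gate(ra, la, res_atoms):
                    hbond += params.hbond_bonus * w
    return InteractionScore(attraction, elec, hbond, repulsion)


def _angle_gate(res_atom: Atom, lig_atom: Atom, res_atoms: list[Atom]) -> bool:
    """Require the H-bond partner to sit on the exposed side of the residue atom."""
    neighbor = _bonded_neighbor(res_atom, res_atoms)
    if neighbor is None:
        return True
    v1 = neighbor.coord - res_atom.coord
    v2 = lig_atom.coord - res_atom.coord
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return cosang < 0.0  # angle neighbor-atom-partner > 90 degrees


ScorerFn = Callable[[Residue, Ligand, ScoringParams], InteractionScore]

SCORERS: dict[str, ScorerFn] = {"proxy": score_interaction}


def get_scorer(name: str) -> ScorerFn:
    try:
        return SCORERS[name]
    except KeyError:
        raise ConfigurationError(f"unknown scorer {name!r}") from None
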