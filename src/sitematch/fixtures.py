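"""Deterministic synthetic structures for tests and examples.

The generators build idealised poly-alanine backbones (helix, strand, or a
two-helix bundle) with full N, CA, C, O, CB atoms and ideal bond geometry,
plant multi-residue binding sites with pseudo-carbon ligands onto them,
apply seeded rigid or Gaussian perturbations, and produce Bernoulli
site-by-scaffold match matrices.  They stand in for curated scaffold sets
so that every pipeline stage is exercisable without downloads; they make
no claim of physical designability.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .core import Atom, BindingSite, Ligand, Residue, Structure, construct_ideal_cb
from .errors import ParameterError, PlacementError
from .geometry import RigidTransform
from .match_stats import MatchMatrix

__all__ = [
    "Topology",
    "FixtureSpec",
    "make_scaffold",
    "plant_site",
    "perturb",
    "random_rigid_transform",
    "make_match_matrix",
]

# Engh-Huber-style ideal backbone internal coordinates.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0

DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
}

DEFAULT_B_FACTOR = 20.0
NOMINAL_RESOLUTION = 1.5  # synthetic fixtures carry a nominal resolution


class Topology(str, enum.Enum):
    HELIX = "helix"
    STRAND = "strand"
    TWO_HELIX_BUNDLE = "two_helix_bundle"


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_residues: int = 20
    topology: Topology = Topology.HELIX
    site_positions: tuple[int, ...] = ()
    ligand_atom_count: int = 1
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        pos = tuple(self.site_positions)
        if len(set(pos)) != len(pos):
            raise ParameterError("site positions must be pairwise distinct")
        if any(not 1 <= p <= self.n_residues for p in pos):
            raise ParameterError("site positions out of range")
        object.__setattr__(self, "site_positions", pos)
        object.__setattr__(self, "topology", Topology(self.topology))


def _place_atom(a, b, c, length, angle_deg, torsion_deg):
    """NeRF placement: point d with |dc| = length, angle(b,c,d), torsion(a,b,c,d)."""
    theta = math.radians(angle_deg)
    chi = -math.radians(torsion_deg)  # sign matches the dihedral() convention
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -length * math.cos(theta),
            length * math.sin(theta) * math.cos(chi),
            length * math.sin(theta) * math.sin(chi),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(n_residues: int, phi: float, psi: float) -> list[dict]:
    """Backbone atom coordinates for an ideal-geometry chain."""
    residues: list[dict] = []
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_residues):
        prev = residues[-1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi)
        ca = _place_atom(prev["CA"], prev["C"], n, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c = _place_atom(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        residues.append({"N": n, "CA": ca, "C": c})
    for res in residues:
        res["O"] = _place_atom(res["N"], res["CA"], res["C"], BOND_C_O,
                               ANGLE_CA_C_O, psi + 180.0)
    return residues


def _to_structure(backbones: list[dict], structure_id: str) -> Structure:
    chain = []
    for i, bb in enumerate(backbones, start=1):
        res = Residue(chain_id="A", seq_index=i, aa_type="A", resname="ALA",
                      atoms=[Atom(name, "O" if name == "O" else
                                  ("N" if name == "N" else "C"),
                                  bb[name], DEFAULT_B_FACTOR)
                             for name in ("N", "CA", "C", "O")])
        cb = construct_ideal_cb(res)
        res.atoms.append(Atom("CB", "C", cb, DEFAULT_B_FACTOR))
        chain.append(res)
    return Structure(id=structure_id, chains={"A": chain},
                     resolution=NOMINAL_RESOLUTION)


def _principal_axis(cas: np.ndarray) -> np.ndarray:
    centered = cas - cas.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if np.dot(axis, cas[-1] - cas[0]) < 0:
        axis = -axis
    return axis


def make_scaffold(spec: FixtureSpec) -> Structure:
    """Build an ideal poly-alanine scaffold for the given specification."""
    if spec.n_residues < 4:
        raise ParameterError("scaffolds need at least 4 residues")
    topo = spec.topology
    if topo in (Topology.HELIX, Topology.STRAND):
        phi, psi = DIHEDRALS[topo.value]
        backbones = _build_backbone(spec.n_residues, phi, psi)
    elif topo is Topology.TWO_HELIX_BUNDLE:
        phi, psi = DIHEDRALS["helix"]
        n1 = spec.n_residues // 2
        seg1 = _build_backbone(n1, phi, psi)
        seg2 = _build_backbone(spec.n_residues - n1, phi, psi)
        backbones = seg1 + _pack_antiparallel(seg1, seg2)
    else:  # pragma: no cover - enum coverage
        raise ParameterError(f"unknown topology {topo!r}")
    structure = _to_structure(backbones, f"{topo.value}_{spec.n_residues}_s{spec.seed}")
    if spec.noise_sigma > 0:
        structure = perturb(structure, spec.noise_sigma, spec.seed)
    return structure


def _pack_antiparallel(seg1: list[dict], seg2: list[dict],
                       offset: float = 10.0) -> list[dict]:
    """Place segment 2 antiparallel to segment 1 at a lateral offset."""
    cas1 = np.array([r["CA"] for r in seg1])
    cas2 = np.array([r["CA"] for r in seg2])
    a1 = _principal_axis(cas1)
    a2 = _principal_axis(cas2)
    # Rotate a2 onto -a1 about their mutual perpendicular.
    v = np.cross(a2, -a1)
    s = np.linalg.norm(v)
    c = float(np.dot(a2, -a1))
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else _flip_about_perpendicular(a1)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    perp = np.cross(a1, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(a1, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    translation = cas1.mean(axis=0) + offset * perp - rot @ cas2.mean(axis=0)
    transform = RigidTransform(rot, translation)
    return [{k: transform.apply(v) for k, v in res.items()} for res in seg2]


def _flip_about_perpendicular(axis: np.ndarray) -> np.ndarray:
    perp = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    return 2.0 * np.outer(perp, perp) - np.eye(3)


def plant_site(
    scaffold: Structure,
    positions: tuple[int, ...] | list[int],
    ligand_atom_count: int = 1,
    seed: int = 0,
    max_attempts: int = 1000,
) -> tuple[BindingSite, dict[int, tuple[str, int]]]:
    """Plant a binding site at the given scaffold positions.

    Copies the chosen residues, places a pseudo-carbon ligand so that every
    chosen residue has a ligand atom within 5 angstroms while keeping 3
    angstroms clearance from the backbone of all other residues, and
    returns the site (in the scaffold frame) with the ground-truth
    correspondence {site residue index -> scaffold residue key}.
    """
    positions = tuple(positions)
    if len(positions) < 2:
        raise ParameterError("a planted site needs at least 2 positions")
    if ligand_atom_count < 1:
        raise ParameterError("ligand needs at least one atom")
    chain_id = next(iter(scaffold.chains))
    chosen = [scaffold.residue(chain_id, p) for p in positions]
    others_bb = np.array(
        [
            a.coord
            for r in scaffold.residues()
            if r.seq_index not in positions
            for name in ("N", "CA", "C", "O")
            if (a := r.atom(name)) is not None
        ]
    ).reshape(-1, 3)
    chosen_coords = [r.heavy_coords() for r in chosen]
    all_chosen = np.vstack(chosen_coords)
    # Outward probes: one candidate anchor point per chosen residue.
    probes = []
    for res in chosen:
        u = res.cb - res.ca
        probes.append(res.ca + (np.linalg.norm(u) + 2.4) * u / np.linalg.norm(u))
    probes = np.array(probes)

    rng = np.random.default_rng(seed)
    lig_coords: list[np.ndarray] = []

    def valid(p: np.ndarray) -> bool:
        if not _clearance(p, others_bb, 3.0):
            return False
        if not _clearance(p, all_chosen, 3.3):
            return False
        if lig_coords and min(np.linalg.norm(p - q) for q in lig_coords) < 1.4:
            return False
        return True

    def covered_by(p: np.ndarray) -> set[int]:
        return {
            i
            for i, cc in enumerate(chosen_coords)
            if np.linalg.norm(cc - p, axis=1).min() <= 4.9
        }

    uncovered = set(range(len(chosen)))
    while uncovered:
        remaining_atoms = ligand_atom_count - len(lig_coords)
        if remaining_atoms == 0:
            raise PlacementError(
                f"{ligand_atom_count} ligand atoms cannot cover "
                f"{len(positions)} residues at these positions"
            )
        need = -(-len(uncovered) // remaining_atoms)  # ceil
        target = probes[sorted(uncovered)].mean(axis=0)
        focus = probes[min(uncovered)]
        placed = False
        for attempt in range(max_attempts):
            base = target if attempt % 2 == 0 else focus
            p = base + rng.normal(0.0, 1.0, 3)
            if valid(p):
                cov = covered_by(p) & uncovered
                if len(cov) >= min(need, len(uncovered)):
                    lig_coords.append(p)
                    uncovered -= cov
                    placed = True
                    break
        if not placed:
            raise PlacementError(
                f"could not place a covering ligand atom after {max_attempts} attempts"
            )
    # Remaining atoms extend the ligand as a loose chain near the site.
    while len(lig_coords) < ligand_atom_count:
        prev = lig_coords[-1]

        def propose():
            u = rng.normal(size=3)
            return prev + 1.5 * u / np.linalg.norm(u)

        def ok(p):
            return (np.linalg.norm(all_chosen - p, axis=1).min() <= 5.0
                    and valid(p))

        lig_coords.append(_sample_point(rng, max_attempts, propose, ok))

    ligand = Ligand(
        resname="LIG",
        atoms=[Atom(f"C{i+1}", "C", c, DEFAULT_B_FACTOR)
               for i, c in enumerate(lig_coords)],
        source=scaffold.id,
    )
    site = BindingSite(
        ligand=ligand,
        residues=[r.copy() for r in chosen],
        source_id=scaffold.id,
        site_id=f"{scaffold.id}:site{'-'.join(map(str, positions))}",
    )
    truth = {i: (chain_id, p) for i, p in enumerate(positions)}
    return site, truth


def _sample_point(rng, max_attempts, propose, accept) -> np.ndarray:
    for _ in range(max_attempts):
        p = propose()
        if accept(p):
            return p
    raise PlacementError(
        f"could not place a ligand atom after {max_attempts} attempts"
    )


def _clearance(point: np.ndarray, coords: np.ndarray, minimum: float) -> bool:
    if coords.size == 0:
        return True
    return float(np.linalg.norm(coords - point, axis=1).min()) >= minimum


def perturb(obj, sigma: float, seed: int = 0):
    """Add isotropic Gaussian noise to every atom; sigma = 0 is the identity."""
    if sigma < 0:
        raise ParameterError("sigma must be non-negative")
    out = obj.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    if isinstance(out, Structure):
        atoms = [a for r in out.residues() for a in r.atoms]
        atoms += [a for lig in out.ligands for a in lig.atoms]
    elif isinstance(out, BindingSite):
        atoms = [a for r in out.residues for a in r.atoms] + list(out.ligand.atoms)
    else:
        raise ParameterError(f"cannot perturb {type(obj).__name__}")
    for a in atoms:
        a.coord = a.coord + rng.normal(0.0, sigma, 3)
    return out


def random_rigid_transform(rng: np.random.Generator,
                           max_translation: float = 20.0) -> RigidTransform:
    """Uniform random rotation plus a bounded random translation."""
    q = rng.normal(size=4)
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    translation = rng.uniform(-max_translation, max_translation, 3)
    return RigidTransform(rot, translation)


def make_match_matrix(
    n_sites: int, n_scaffolds: int, p_match: float, seed: int = 0
) -> MatchMatrix:
    """Fully tested Bernoulli match matrix with consistent encounter numbers."""
    if not 0.0 <= p_match <= 1.0:
        raise ParameterError("p_match must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fast = (rng.random((n_sites, n_scaffolds)) < p_match).astype(np.int8)
    order = [int(j) for j in rng.permutation(n_scaffolds)]
    return MatchMatrix(
        sites=[f"site{i}" for i in range(n_sites)],
        scaffolds=[f"scaffold{j}" for j in range(n_scaffolds)],
        fast=fast,
        order=order,
    )
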