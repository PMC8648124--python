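"""Residue burial layers, depth scores and simplified secondary structure.

Burial is assigned side-chain-independently: each residue's weighted
neighbour count sums, over all other residues, a distance factor
``1 / (1 + exp(d - 9))`` (d = CA-CA distance in angstroms) times an angle
factor ``((cos(theta) + 0.5) / 1.5)^2`` (theta = angle between the
residue's CA->CB vector and the CA->neighbour-CA vector, clamped to zero
when cos(theta) <= -0.5).  Counts below 2 are surface, above 5.2 core,
otherwise boundary.  The depth score of a matched site is the number of
boundary positions plus twice the number of core positions among its
matched scaffold residues.

Secondary structure uses a dihedral-window 3-state assigner.  It is not a
hydrogen-bond-based (DSSP-equivalent) assignment; it is intended for
descriptive summaries of idealised backbones.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .core import Structure
from .errors import ParameterError
from .fast_match import MatchResult
from .geometry import dihedral

__all__ = [
    "Layer",
    "LayerConfig",
    "LayerAssignment",
    "DepthScore",
    "neighbor_weight",
    "assign_layers",
    "depth_score",
    "assign_secondary_structure",
]


class Layer(str, enum.Enum):
    SURFACE = "surface"
    BOUNDARY = "boundary"
    CORE = "core"


@dataclass(frozen=True)
class LayerConfig:
    surface_below: float = 2.0  # weighted count below -> surface
    core_above: float = 5.2  # weighted count above -> core
    distance_midpoint: float = 9.0  # angstroms
    angle_shift: float = 0.5


@dataclass
class LayerAssignment:
    """Per-residue weighted neighbour counts and surface/boundary/core labels."""

    counts: dict[tuple[str, int], float]
    layers: dict[tuple[str, int], Layer]

    def layer(self, key: tuple[str, int]) -> Layer:
        return self.layers[key]


@dataclass(frozen=True)
class DepthScore:
    value: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ParameterError("depth score cannot be negative")


def neighbor_weight(d: float, theta: float,
                    config: LayerConfig | None = None) -> float:
    """Weight of one neighbour: distance factor times angle factor.

    ``d`` is the CA-CA distance in angstroms, ``theta`` the cone angle in
    radians.  The angle factor is clamped to 0 when cos(theta) <= -0.5.
    """
    config = config or LayerConfig()
    if d < 0:
        raise ParameterError("distance must be non-negative")
    distance_factor = 1.0 / (1.0 + math.exp(d - config.distance_midpoint))
    cosang = math.cos(theta)
    s = config.angle_shift
    if cosang <= -s:
        return 0.0
    angle_factor = ((cosang + s) / (1.0 + s)) ** 2
    return distance_factor * angle_factor


def assign_layers(scaffold: Structure,
                  config: LayerConfig | None = None) -> LayerAssignment:
    """Weighted neighbour counts and layers for every residue of a scaffold."""
    config = config or LayerConfig()
    residues = [r for r in scaffold.residues() if r.is_matchable]
    if len(residues) < 2:
        raise ParameterError("layer assignment needs at least 2 residues")
    cas = np.array([r.ca for r in residues])
    cbs = np.array([r.cb for r in residues])
    counts: dict[tuple[str, int], float] = {}
    layers: dict[tuple[str, int], Layer] = {}
    for i, res in enumerate(residues):
        axis = cbs[i] - cas[i]
        axis = axis / np.linalg.norm(axis)
        total = 0.0
        for j in range(len(residues)):
            if j == i:
                continue
            v = cas[j] - cas[i]
            d = float(np.linalg.norm(v))
            if d < 1e-9:
                continue
            theta = float(np.arccos(np.clip(np.dot(axis, v / d), -1.0, 1.0)))
            total += neighbor_weight(d, theta, config)
        counts[res.key] = total
        if total < config.surface_below:
            layers[res.key] = Layer.SURFACE
        elif total > config.core_above:
            layers[res.key] = Layer.CORE
        else:
            layers[res.key] = Layer.BOUNDARY
    return LayerAssignment(counts=counts, layers=layers)


def depth_score(match: MatchResult, layers: LayerAssignment) -> DepthScore:
    """Boundary count plus twice the core count over matched scaffold positions."""
    n_boundary = n_core = 0
    for key in match.correspondence.values():
        layer = layers.layer(key)
        if layer is Layer.BOUNDARY:
            n_boundary += 1
        elif layer is Layer.CORE:
            n_core += 1
    return DepthScore(n_boundary + 2 * n_core)


# Dihedral windows (degrees) for the 3-state assigner.
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-180.0, -80.0)
STRAND_PSI = (90.0, 180.0)


def assign_secondary_structure(scaffold: Structure) -> dict[tuple[str, int], str]:
    """3-state labels {helix, strand, loop} from backbone dihedral windows.

    Chain termini (no phi or no psi) and chains shorter than 3 residues are
    labelled loop.
    """
    labels: dict[tuple[str, int], str] = {}
    for chain in scaffold.chains.values():
        if len(chain) < 3:
            for res in chain:
                labels[res.key] = "loop"
            continue
        for idx, res in enumerate(chain):
            phi = psi = None
            if idx > 0 and chain[idx - 1].is_matchable and res.is_matchable:
                prev = chain[idx - 1]
                phi = dihedral(prev.coord("C"), res.coord("N"),
                               res.coord("CA"), res.coord("C"))
            if idx < len(chain) - 1 and res.is_matchable and \
                    chain[idx + 1].atom("N") is not None:
                nxt = chain[idx + 1]
                psi = dihedral(res.coord("N"), res.coord("CA"),
                               res.coord("C"), nxt.coord("N"))
            labels[res.key] = _classify(phi, psi)
    return labels


def _classify(phi: float | None, psi: float | None) -> str:
    if phi is None or psi is None:
        return "loop"
    if HELIX_PHI[0] <= phi <= HELIX_PHI[1] and HELIX_PSI[0] <= psi <= HELIX_PSI[1]:
        return "helix"
    if STRAND_PHI[0] <= phi <= STRAND_PHI[1] and STRAND_PSI[0] <= psi <= STRAND_PSI[1]:
        return "strand"
    return "loop"
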