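"""Ligand clustering by 3D-fingerprint similarity.

Ligands are encoded as fixed-length bit-vector fingerprints (default 1024
bits) and clustered with the Butina leader algorithm at a Tanimoto-distance
cutoff (default 0.65, with distance defined as one minus the Tanimoto
coefficient).  The fingerprint backend is pluggable; the default is a
rotation-invariant 3D shell-hashing scheme computed from heavy-atom
elements and binned interatomic distances, so clustering is fully
deterministic and needs no external conformer machinery.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import Ligand
from .errors import ConfigurationError, ParameterError

__all__ = [
    "Fingerprint",
    "ClusterSet",
    "tanimoto_distance",
    "butina_cluster",
    "fingerprint_ligand",
    "FINGERPRINT_BACKENDS",
]

DEFAULT_N_BITS = 1024
DEFAULT_CUTOFF = 0.65

# Shell radii (angstroms) for the default 3D fingerprint backend.
SHELL_RADII = (1.5, 2.5, 4.0, 6.0, 8.0)
DISTANCE_BIN = 0.5  # angstroms


@dataclass(frozen=True)
class Fingerprint:
    bits: np.ndarray  # boolean, fixed length
    ligand_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    @property
    def n_bits(self) -> int:
        return self.bits.size


@dataclass
class ClusterSet:
    """Disjoint clusters covering all inputs, ordered by size descending."""

    clusters: list[tuple[str, list[str]]]  # (centroid id, member ids incl. centroid)
    cutoff: float = DEFAULT_CUTOFF

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, str]:
        return {m: c for c, members in self.clusters for m in members}


def tanimoto_distance(a: Fingerprint, b: Fingerprint) -> float:
    """1 - |a AND b| / |a OR b|; two empty fingerprints have distance 0."""
    if a.n_bits != b.n_bits:
        raise ParameterError("fingerprint lengths differ")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        return 0.0
    inter = int(np.logical_and(a.bits, b.bits).sum())
    return 1.0 - inter / union


def butina_cluster(
    fps: Sequence[Fingerprint], cutoff: float = DEFAULT_CUTOFF
) -> ClusterSet:
    """Butina leader clustering at a fixed distance cutoff.

    Neighbour lists are computed once; candidates are ranked by neighbour
    count descending (ties by ligand id), and the highest-ranked unassigned
    candidate repeatedly becomes a centroid, absorbing its unassigned
    neighbours.  Points left over become singleton clusters.
    """
    if not fps:
        raise ParameterError("need at least one fingerprint")
    if not 0 < cutoff <= 1:
        raise ParameterError("cutoff must be in (0, 1]")
    n = len(fps)
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if tanimoto_distance(fps[i], fps[j]) <= cutoff:
                neighbors[i].add(j)
                neighbors[j].add(i)
    order = sorted(range(n), key=lambda i: (-len(neighbors[i]), fps[i].ligand_id))
    assigned: set[int] = set()
    clusters: list[tuple[str, list[str]]] = []
    for i in order:
        if i in assigned:
            continue
        members = [i] + sorted(j for j in neighbors[i] if j not in assigned and j != i)
        assigned.update(members)
        clusters.append((fps[i].ligand_id, [fps[j].ligand_id for j in members]))
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    return ClusterSet(clusters=clusters, cutoff=cutoff)


def _shell_fingerprint(ligand: Ligand, n_bits: int = DEFAULT_N_BITS) -> np.ndarray:
    """Rotation-invariant 3D shell hashing over heavy atoms.

    For every atom and shell radius, the environment is the sorted multiset
    of (element, binned distance) pairs of atoms within the shell; each
    (centre element, radius, environment) key sets one bit.
    """
    coords = ligand.coords()
    elements = [a.element for a in ligand.atoms]
    bits = np.zeros(n_bits, dtype=bool)
    for i, el in enumerate(elements):
        dists = np.linalg.norm(coords - coords[i], axis=1)
        for radius in SHELL_RADII:
            env = sorted(
                (elements[j], int(round(dists[j], 3) / DISTANCE_BIN))
                for j in range(len(elements))
                if j != i and dists[j] <= radius
            )
            key = repr((el, radius, tuple(env)))
            digest = hashlib.sha1(key.encode()).hexdigest()
            bits[int(digest, 16) % n_bits] = True
    return bits


BackendFn = Callable[[Ligand, int], np.ndarray]

FINGERPRINT_BACKENDS: dict[str, BackendFn] = {"shell3d": _shell_fingerprint}


def fingerprint_ligand(
    ligand: Ligand,
    backend: str = "shell3d",
    n_bits: int = DEFAULT_N_BITS,
    ligand_id: str | None = None,
) -> Fingerprint:
    """Compute a fingerprint for one ligand conformer.

    Deterministic for a fixed backend and conformer.  An E3FP-compatible
    backend can be registered in :data:`FINGERPRINT_BACKENDS`.
    """
    if ligand.n_heavy < 1:
        raise ParameterError("ligand has no heavy atoms")
    try:
        fn = FINGERPRINT_BACKENDS[backend]
    except KeyError:
        raise ConfigurationError(f"unknown fingerprint backend {backend!r}") from None
    bits = fn(ligand, n_bits)
    return Fingerprint(bits=bits, ligand_id=ligand_id or ligand.source or ligand.resname)
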