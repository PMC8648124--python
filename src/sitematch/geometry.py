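"""Rigid-body transforms and least-squares superposition.

The matching pipeline treats a binding site as a rigid unit, so every
placement is an element of SE(3): a proper rotation plus a translation.
Superposition of corresponding atom sets uses the Kabsch algorithm, which
minimises the root-mean-square deviation over all proper rotations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


from .errors import DegenerateGeometryError, ParameterError

__all__ = ["RigidTransform", "superpose", "dihedral"]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body map ``x -> rotation @ x + translation``."""

    rotation: np.ndarray  # (3, 3) proper orthonormal
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or tr.shape != (3,):
            raise ParameterError("rotation must be 3x3 and translation length 3")
        if abs(np.linalg.det(rot) - 1.0) > 1e-6:
            raise ParameterError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array or a single 3-vector."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


def superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``target``.

    Parameters
    ----------
    mobile, target
        Corresponding (n, 3) coordinate arrays, n >= 3.

    Returns
    -------
    transform, rmsd
        The proper rigid transform achieving the global minimum RMSD, and
        that minimum RMSD in angstroms.
    """
    mob = np.asarray(mobile, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if mob.ndim != 2 or mob.shape[1] != 3 or mob.shape != tgt.shape:
        raise ParameterError("coordinate arrays must both be (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise ParameterError("superposition needs at least 3 points")
    mc, tc = mob.mean(axis=0), tgt.mean(axis=0)
    a, b = mob - mc, tgt - tc
    # Collinear sets leave the rotation about the line undetermined.
    if _rank2_deficient(a) or _rank2_deficient(b):
        raise DegenerateGeometryError("point set is collinear")
    # Kabsch: SVD of the cross-covariance, with a reflection guard.
    u, s, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    matrix = vt.T @ flip @ u.T
    residual = b - a @ matrix.T
    rmsd = float(np.sqrt((residual * residual).sum() / n))
    transform = RigidTransform(matrix, tc - matrix @ mc)
    return transform, rmsd


def _rank2_deficient(centered: np.ndarray) -> bool:
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= 1e-8 * max(s[0], 1.0)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))
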