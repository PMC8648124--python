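"""The fast-match protocol: rigid-body screening of binding sites onto scaffolds.

A binding site is treated as one rigid unit.  For every pair of (site
residue, scaffold residue) the site is anchored by least-squares
superposition of the residue's N, CA, C atoms onto the scaffold residue's,
and the whole site follows rigidly.  A placement is then accepted only if
it passes four gates in order:

1. every site residue finds a scaffold residue with CA-CA distance within
   2 angstroms, and the mapping is injective;
2. least-squares superposition of all site backbone N, CA, C atoms onto
   the corresponding scaffold atoms achieves RMSD within 1 angstrom;
3. the cosine between the CA->CB vectors of every corresponding pair
   exceeds 0.7 (ideal CB constructed for glycine);
4. the ligand and site side chains do not clash with scaffold backbone
   atoms of residues outside the correspondence, where two atoms clash
   when their distance is below 0.6 times the sum of their Lennard-Jones
   radii.

Accepted placements are deduplicated by correspondence, keeping the lowest
backbone RMSD.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core import BindingSite, Residue, Structure
from .errors import ConfigurationError, ParameterError
from .geometry import RigidTransform, superpose
from .match_stats import MATCHED, TESTED_NO_MATCH, UNTESTED, MatchMatrix
from .scoring import LJ_RADII

__all__ = [
    "FastMatchConfig",
    "MatchResult",
    "RejectStage",
    "anchor_align",
    "nearest_scaffold_residues",
    "clash_check",
    "fast_match_site",
    "match_library",
]

SCAFFOLD_BACKBONE = ("N", "CA", "C", "O")


class RejectStage(str, enum.Enum):
    NONE = "none"
    ANCHOR_DISTANCE = "anchor_distance"
    RMSD = "rmsd"
    COSINE = "cosine"
    CLASH = "clash"


@dataclass(frozen=True)
class FastMatchConfig:
    ca_distance_cutoff: float = 2.0  # angstroms
    backbone_rmsd_cutoff: float = 1.0  # angstroms
    cb_cosine_cutoff: float = 0.7
    clash_scale: float = 0.6
    lj_radii: dict = field(default_factory=lambda: dict(LJ_RADII))

    def __post_init__(self) -> None:
        if not 0 < self.clash_scale <= 1:
            raise ParameterError("clash_scale must be in (0, 1]")
        if self.ca_distance_cutoff <= 0 or self.backbone_rmsd_cutoff <= 0:
            raise ParameterError("distance cutoffs must be positive")
        if not -1 < self.cb_cosine_cutoff < 1:
            raise ParameterError("cosine cutoff must be in (-1, 1)")


@dataclass
class MatchResult:
    scaffold_id: str
    anchor: tuple[int, tuple[str, int]]  # (site residue index, scaffold residue key)
    correspondence: dict[int, tuple[str, int]]  # site residue index -> scaffold key
    backbone_rmsd: float
    cb_cosines: list[float]
    transform: RigidTransform
    rejected_stage: RejectStage = RejectStage.NONE

    @property
    def accepted(self) -> bool:
        return self.rejected_stage is RejectStage.NONE

    @property
    def min_cosine(self) -> float:
        return min(self.cb_cosines) if self.cb_cosines else float("nan")


def anchor_align(
    site: BindingSite, site_res: int, scaffold_res: Residue
) -> tuple[BindingSite, RigidTransform]:
    """Superpose one site residue's N, CA, C onto a scaffold residue's.

    The remainder of the site (all residues and the ligand) is transformed
    as a rigid body.  Returns the transformed copy and the transform.
    """
    res = site.residues[site_res]
    if not res.is_matchable or not scaffold_res.is_matchable:
        raise ParameterError("both residues need N, CA and C atoms")
    transform, _ = superpose(res.backbone_coords(), scaffold_res.backbone_coords())
    return site.transformed(transform), transform


def nearest_scaffold_residues(
    site: BindingSite, scaffold: Structure
) -> dict[int, tuple[Residue, float]]:
    """Closest scaffold residue (by CA-CA distance) for each site residue.

    The site must already be placed in the scaffold frame.  Ties are broken
    by the lower scaffold sequence index (scan order).
    """
    scaffold_res = scaffold.matchable_residues()
    if not scaffold_res:
        raise ParameterError(f"scaffold {scaffold.id} has no matchable residues")
    scaffold_ca = np.array([r.ca for r in scaffold_res])
    site_ca = np.array([r.ca for r in site.residues])
    dists = cdist(site_ca, scaffold_ca)
    out = {}
    for i in range(len(site.residues)):
        j = int(np.argmin(dists[i]))  # argmin keeps the lowest index on ties
        out[i] = (scaffold_res[j], float(dists[i, j]))
    return out


def clash_check(
    site: BindingSite,
    scaffold: Structure,
    correspondence: dict[int, tuple[str, int]],
    config: FastMatchConfig | None = None,
) -> bool:
    """True when the placed site is clash-free against the scaffold backbone.

    Compares ligand heavy atoms plus site side-chain heavy atoms against
    backbone heavy atoms (N, CA, C, O) of scaffold residues outside the
    correspondence.  CB is treated as a designable side-chain atom on the
    scaffold side and is not part of the backbone set.
    """
    config = config or FastMatchConfig()
    matched_keys = set(correspondence.values())
    mobile_atoms = list(site.ligand.atoms)
    for res in site.residues:
        mobile_atoms.extend(res.side_chain_heavy_atoms())
    scaffold_atoms = []
    for res in scaffold.residues():
        if res.key in matched_keys:
            continue
        for name in SCAFFOLD_BACKBONE:
            a = res.atom(name)
            if a is not None:
                scaffold_atoms.append(a)
    if not mobile_atoms or not scaffold_atoms:
        return True
    radii = config.lj_radii
    try:
        mob_r = np.array([radii[a.element] for a in mobile_atoms])
        sca_r = np.array([radii[a.element] for a in scaffold_atoms])
    except KeyError as exc:
        raise ConfigurationError(
            f"no Lennard-Jones radius for element {exc.args[0]!r}"
        ) from None
    mob = np.array([a.coord for a in mobile_atoms])
    sca = np.array([a.coord for a in scaffold_atoms])
    dists = cdist(mob, sca)
    limits = config.clash_scale * (mob_r[:, None] + sca_r[None, :])
    return bool((dists >= limits).all())


def fast_match_site(
    site: BindingSite,
    scaffold: Structure,
    config: FastMatchConfig | None = None,
    keep_rejected: bool = False,
) -> list[MatchResult]:
    """Run the full fast-match pipeline over all anchor pairs.

    Returns accepted placements (deduplicated by correspondence, lowest
    RMSD kept).  With ``keep_rejected`` the rejected attempts are included
    for diagnostics, tagged with the stage that rejected them.
    """
    config = config or FastMatchConfig()
    if site.n_residues < 2:
        raise ParameterError("site needs at least 2 residues")
    for res in site.residues:
        if not res.is_matchable:
            raise ParameterError("all site residues need full backbones")

    scaffold_residues = scaffold.matchable_residues()
    if not scaffold_residues:
        raise ParameterError(f"scaffold {scaffold.id} has no matchable residues")

    results: list[MatchResult] = []
    accepted: dict[frozenset, MatchResult] = {}
    for i in range(site.n_residues):
        for scaffold_res in scaffold_residues:
            result = _try_anchor(site, i, scaffold_res, scaffold, config)
            if result.accepted:
                key = frozenset(result.correspondence.items())
                prev = accepted.get(key)
                if prev is None or result.backbone_rmsd < prev.backbone_rmsd:
                    accepted[key] = result
            elif keep_rejected:
                results.append(result)
    results.extend(accepted.values())
    return results


def _try_anchor(
    site: BindingSite,
    site_res: int,
    scaffold_res: Residue,
    scaffold: Structure,
    config: FastMatchConfig,
) -> MatchResult:
    placed, t_anchor = anchor_align(site, site_res, scaffold_res)
    anchor = (site_res, scaffold_res.key)
    nearest = nearest_scaffold_residues(placed, scaffold)
    correspondence = {i: res.key for i, (res, _) in nearest.items()}

    def rejected(stage, rmsd=float("nan"), cosines=(), transform=t_anchor):
        return MatchResult(
            scaffold_id=scaffold.id,
            anchor=anchor,
            correspondence=correspondence,
            backbone_rmsd=rmsd,
            cb_cosines=list(cosines),
            transform=transform,
            rejected_stage=stage,
        )

    if any(d > config.ca_distance_cutoff for _, d in nearest.values()):
        return rejected(RejectStage.ANCHOR_DISTANCE)
    if len(set(correspondence.values())) < len(correspondence):
        return rejected(RejectStage.ANCHOR_DISTANCE)

    site_bb = np.vstack([r.backbone_coords() for r in placed.residues])
    scaf_bb = np.vstack([nearest[i][0].backbone_coords()
                         for i in range(site.n_residues)])
    t_refine, rmsd = superpose(site_bb, scaf_bb)
    transform = t_refine.compose(t_anchor)
    if rmsd > config.backbone_rmsd_cutoff:
        return rejected(RejectStage.RMSD, rmsd=rmsd, transform=transform)

    refined = placed.transformed(t_refine)
    cosines = []
    for i, res in enumerate(refined.residues):
        v_site = res.cb - res.ca
        target = nearest[i][0]
        v_scaf = target.cb - target.ca
        cosines.append(
            float(np.dot(v_site, v_scaf)
                  / (np.linalg.norm(v_site) * np.linalg.norm(v_scaf)))
        )
    if any(c <= config.cb_cosine_cutoff for c in cosines):
        return rejected(RejectStage.COSINE, rmsd=rmsd, cosines=cosines,
                        transform=transform)

    if not clash_check(refined, scaffold, correspondence, config):
        return rejected(RejectStage.CLASH, rmsd=rmsd, cosines=cosines,
                        transform=transform)

    return MatchResult(
        scaffold_id=scaffold.id,
        anchor=anchor,
        correspondence=correspondence,
        backbone_rmsd=rmsd,
        cb_cosines=cosines,
        transform=transform,
        rejected_stage=RejectStage.NONE,
    )


def match_library(
    sites: Sequence[BindingSite],
    scaffolds: Sequence[Structure],
    config: FastMatchConfig | None = None,
    stop_at_first: bool = False,
    seed: int = 0,
) -> MatchMatrix:
    """Match every site against a scaffold set.

    Scaffolds are tested in a seed-shuffled order (recorded in the result),
    and each site's first-encounter number is the 1-based position of its
    first successful scaffold in that order.  With ``stop_at_first``,
    scaffolds after the first success are skipped and marked untested.
    """
    if not sites or not scaffolds:
        raise ParameterError("sites and scaffolds must be non-empty")
    config = config or FastMatchConfig()
    rng = np.random.default_rng(seed)
    order = [int(j) for j in rng.permutation(len(scaffolds))]
    fast = np.full((len(sites), len(scaffolds)), UNTESTED, dtype=np.int8)
    encounter: list[Optional[int]] = []
    for i, site in enumerate(sites):
        enc = None
        for pos, j in enumerate(order, start=1):
            hits = fast_match_site(site, scaffolds[j], config)
            fast[i, j] = MATCHED if hits else TESTED_NO_MATCH
            if hits and enc is None:
                enc = pos
                if stop_at_first:
                    break
        encounter.append(enc)
    return MatchMatrix(
        sites=[s.id for s in sites],
        scaffolds=[s.id for s in scaffolds],
        fast=fast,
        order=order,
        encounter=encounter,
    )
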