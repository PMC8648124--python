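"""Binding-site library construction.

A binding site is a ligand plus the protein residues that interact
favourably with it.  Library construction applies quality filters:
resolution better than the cutoff, ligand heavy-atom count within range,
average ligand B-factor below the cutoff, a contact radius for candidate
residues, an inclusion threshold on the interaction score, and exclusion of
incomplete or clash-dominated residues.  Sites can then be reduced to the
k residues with the strongest interactions.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.spatial.distance import cdist

from .core import BindingSite, Ligand, Residue, Structure
from .errors import MultiChainSiteError, ParameterError
from .scoring import ScoringParams, get_scorer

__all__ = [
    "LibraryConfig",
    "extract_binding_sites",
    "select_top_k",
    "mean_sequence_distance",
    "aa_composition",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LibraryConfig:
    """Numeric filters for binding-site extraction.

    The inclusion and quality thresholds are expressed on the scale of the
    configured scorer; the defaults correspond to the proxy scorer shipped
    with the package.
    """

    max_ligand_heavy_atoms: int = 100
    max_avg_bfactor: float = 60.0  # angstrom^2
    resolution_cutoff: Optional[float] = 2.0  # angstroms; None disables
    contact_radius: float = 5.0  # angstroms
    include_threshold: float = -1.0  # residue kept when total score below this
    residue_quality_cutoff: float = 50.0  # residue dropped when repulsion above
    min_site_residues: int = 2
    scorer: str = "proxy"
    scoring_params: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self) -> None:
        if self.max_ligand_heavy_atoms < 1 or self.contact_radius <= 0:
            raise ParameterError("cutoffs must be strictly positive")
        if self.max_avg_bfactor <= 0 or self.residue_quality_cutoff <= 0:
            raise ParameterError("cutoffs must be strictly positive")
        if self.include_threshold >= 0:
            raise ParameterError("include_threshold must be negative")


def extract_binding_sites(
    structure: Structure, config: LibraryConfig | None = None
) -> list[BindingSite]:
    """Extract one binding site per qualifying ligand of a structure.

    Duplicate ligands (same residue name with an identical binding-residue
    composition, as happens with multiple copies of a chain in one
    asymmetric unit) yield a single site.
    """
    config = config or LibraryConfig()
    if config.resolution_cutoff is not None:
        if structure.resolution is None:
            logger.warning(
                "structure %s has no resolution record; skipping extraction",
                structure.id,
            )
            return []
        if structure.resolution > config.resolution_cutoff:
            return []

    scorer = get_scorer(config.scorer)
    sites: list[BindingSite] = []
    seen_keys: set[tuple] = set()
    for ligand in structure.ligands:
        if not 1 <= ligand.n_heavy <= config.max_ligand_heavy_atoms:
            continue
        if ligand.mean_b_factor > config.max_avg_bfactor:
            continue
        candidates = _contact_residues(structure, ligand, config.contact_radius)
        chosen: list[Residue] = []
        scores: dict[tuple[str, int], float] = {}
        for res in candidates:
            if not res.is_complete() or not res.is_matchable:
                continue
            score = scorer(res, ligand, config.scoring_params)
            if score.repulsion > config.residue_quality_cutoff:
                continue
            if score.total < config.include_threshold:
                chosen.append(res)
                scores[res.key] = score.total
        if len(chosen) < config.min_site_residues:
            continue
        key = (ligand.resname, tuple(sorted(r.aa_type for r in chosen)))
        if key in seen_keys:
            continue
        seen_keys.add(key)
        sites.append(
            BindingSite(
                ligand=ligand.copy(),
                residues=[r.copy() for r in chosen],
                source_id=structure.id,
                per_residue_score=scores,
                site_id=f"{structure.id}:{ligand.resname}:{len(sites)}",
            )
        )
    return sites


def _contact_residues(
    structure: Structure, ligand: Ligand, radius: float
) -> list[Residue]:
    """Residues with >= 1 heavy atom within ``radius`` of any ligand heavy atom."""
    lig = ligand.coords()
    out = []
    for res in structure.residues():
        coords = res.heavy_coords()
        if coords.size and cdist(coords, lig).min() <= radius:
            out.append(res)
    return out


def select_top_k(site: BindingSite, k: int) -> Optional[BindingSite]:
    """Reduce a site to its k strongest-interacting residues.

    Sites with fewer than k residues are rejected (returns None); sites with
    exactly k are returned unchanged.  Ties are broken by (score, seq_index)
    ascending.  The ligand is untouched.
    """
    if k < 2:
        raise ParameterError("k must be at least 2")
    if site.n_residues < k:
        return None
    if site.n_residues == k:
        return site
    ranked = sorted(
        site.residues,
        key=lambda r: (site.per_residue_score.get(r.key, 0.0), r.seq_index),
    )
    kept = sorted(ranked[:k], key=lambda r: (r.chain_id, r.seq_index))
    out = site.copy()
    out.residues = [r.copy() for r in kept]
    out.per_residue_score = {
        r.key: site.per_residue_score[r.key]
        for r in kept
        if r.key in site.per_residue_score
    }
    return out


def mean_sequence_distance(site: BindingSite) -> float:
    """Mean |i - j| over all unordered residue pairs of a single-chain site."""
    if site.n_residues < 2:
        raise ParameterError("sequence distance needs at least 2 residues")
    chains = {r.chain_id for r in site.residues}
    if len(chains) > 1:
        raise MultiChainSiteError(
            f"site {site.id} spans chains {sorted(chains)}; "
            "primary sequence distance is undefined"
        )
    idx = [r.seq_index for r in site.residues]
    pairs = list(itertools.combinations(idx, 2))
    return float(np.mean([abs(i - j) for i, j in pairs]))


def aa_composition(sites: Iterable[BindingSite]) -> dict[str, float]:
    """Amino-acid frequencies over all residues of the given sites."""
    counts: dict[str, int] = {}
    total = 0
    for site in sites:
        for res in site.residues:
            counts[res.aa_type] = counts.get(res.aa_type, 0) + 1
            total += 1
    if total == 0:
        raise ParameterError("aa_composition needs at least one site")
    return {aa: counts[aa] / total for aa in sorted(counts)}
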