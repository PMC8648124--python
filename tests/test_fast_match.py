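"""The rigid-body fast-match pipeline and its gates."""
import numpy as np
import pytest

from conftest import make_ligand, make_residue
from sitematch.core import Atom, BindingSite, Ligand, Structure
from sitematch.errors import ConfigurationError, ParameterError
from sitematch.fast_match import (
    FastMatchConfig,
    RejectStage,
    anchor_align,
    clash_check,
    fast_match_site,
    match_library,
    nearest_scaffold_residues,
)
from sitematch.fixtures import FixtureSpec, make_scaffold, plant_site, \
    random_rigid_transform


def correspondences(results):
    return {frozenset(r.correspondence.items()) for r in results}


class TestAnchorAlign:
    def test_self_anchor_is_identity(self, planted):
        scaffold, site, truth = planted
        placed, _ = anchor_align(site, 0, scaffold.residue(*truth[0]))
        assert np.abs(placed.all_heavy_coords()
                      - site.all_heavy_coords()).max() < 1e-9

    def test_internal_geometry_preserved(self, planted):
        scaffold, site, _ = planted
        placed, _ = anchor_align(site, 1, scaffold.residue("A", 20))
        orig = site.all_heavy_coords()
        new = placed.all_heavy_coords()
        d_orig = np.linalg.norm(orig[:, None] - orig[None], axis=-1)
        d_new = np.linalg.norm(new[:, None] - new[None], axis=-1)
        np.testing.assert_allclose(d_new, d_orig, atol=1e-9)

    def test_matches_explicit_transform_composition(self, planted):
        scaffold, site, _ = planted
        placed, transform = anchor_align(site, 0, scaffold.residue("A", 15))
        np.testing.assert_allclose(
            placed.ligand.coords(),
            transform.apply(site.ligand.coords()), atol=1e-9)


class TestNearestResidues:
    def test_self_mapping(self, planted):
        scaffold, site, truth = planted
        nearest = nearest_scaffold_residues(site, scaffold)
        for i, (res, dist) in nearest.items():
            assert res.key == truth[i]
            assert dist < 1e-9

    def test_equals_exhaustive_search(self, helix24):
        rng = np.random.default_rng(8)
        scaffold_res = helix24.matchable_residues()
        cas = np.array([r.ca for r in scaffold_res])
        for _ in range(50):
            site, _ = plant_site(helix24, (5, 9, 12), 2, seed=int(rng.integers(1e6)))
            moved = site.transformed(random_rigid_transform(rng, 5.0))
            nearest = nearest_scaffold_residues(moved, helix24)
            for i, res in enumerate(moved.residues):
                dists = np.linalg.norm(cas - res.ca, axis=1)
                j = int(np.argmin(dists))
                assert nearest[i][0].key == scaffold_res[j].key
                assert nearest[i][1] == pytest.approx(dists[j], abs=1e-12)

    def test_tie_breaks_to_lower_index(self):
        # Two scaffold residues exactly equidistant from one site residue.
        r1 = make_residue({"N": [-4.0, 1, 0], "CA": [-3.0, 0, 0],
                           "C": [-4.0, -1, 0]}, seq_index=1)
        r2 = make_residue({"N": [4.0, 1, 0], "CA": [3.0, 0, 0],
                           "C": [4.0, -1, 0]}, seq_index=2)
        scaffold = Structure(id="s", chains={"A": [r1, r2]})
        s1 = make_residue({"N": [-1.0, 1, 0], "CA": [0.0, 0, 0],
                           "C": [-1.0, -1, 0]}, seq_index=1)
        s2 = make_residue({"N": [9.0, 1, 0], "CA": [10.0, 0, 0],
                           "C": [9.0, -1, 0]}, seq_index=2)
        site = BindingSite(ligand=make_ligand([[0.0, 5, 0]]),
                           residues=[s1, s2])
        nearest = nearest_scaffold_residues(site, scaffold)
        assert nearest[0][0].seq_index == 1


class TestPipeline:
    def test_self_match_recovers_planted_site(self, planted):
        scaffold, site, truth = planted
        hits = fast_match_site(site, scaffold)
        truth_key = frozenset(truth.items())
        match = [h for h in hits
                 if frozenset(h.correspondence.items()) == truth_key]
        assert match and match[0].backbone_rmsd <= 1e-6
        assert min(match[0].cb_cosines) > 0.999

    def test_rigid_invariance_of_outcomes(self, planted):
        scaffold, site, _ = planted
        base = correspondences(fast_match_site(site, scaffold))
        rng = np.random.default_rng(13)
        for _ in range(10):
            moved = site.transformed(random_rigid_transform(rng))
            assert correspondences(fast_match_site(moved, scaffold)) == base

    def test_rejection_stage_reported(self, planted):
        # A short strand decoy cannot host a helix-face site: every anchor
        # fails a gate, and the first gate to fire is the CA distance.
        _, site, _ = planted
        decoy = make_scaffold(FixtureSpec(n_residues=8, topology="strand"))
        results = fast_match_site(site, decoy, keep_rejected=True)
        assert results and all(not r.accepted for r in results)
        assert RejectStage.ANCHOR_DISTANCE in {r.rejected_stage for r in results}

    def test_site_without_backbone_rejected(self, planted):
        scaffold, site, _ = planted
        broken = site.copy()
        broken.residues[0].atoms = [
            a for a in broken.residues[0].atoms if a.name != "CA"]
        with pytest.raises(ParameterError):
            fast_match_site(broken, scaffold)

    def test_loosening_cutoffs_never_loses_matches(self, planted):
        scaffold, site, _ = planted
        rng = np.random.default_rng(21)
        from sitematch.fixtures import perturb
        noisy = perturb(site, 0.15, seed=3)
        tight = FastMatchConfig()
        loose_variants = [
            FastMatchConfig(ca_distance_cutoff=3.0),
            FastMatchConfig(backbone_rmsd_cutoff=1.5),
            FastMatchConfig(cb_cosine_cutoff=0.5),
            FastMatchConfig(clash_scale=0.4),
        ]
        base = correspondences(fast_match_site(noisy, scaffold, tight))
        for cfg in loose_variants:
            assert correspondences(fast_match_site(noisy, scaffold, cfg)) >= base


class TestClashCheck:
    def scaffold_with_backbone_atom(self, coord):
        res = make_residue({"N": coord, "CA": [50.0, 0, 0], "C": [52.0, 0, 0],
                            "O": [53.0, 1, 0]}, seq_index=1)
        far = make_residue({"N": [60.0, 1, 0], "CA": [61.0, 0, 0],
                            "C": [62.0, 1, 0]}, seq_index=2)
        return Structure(id="s", chains={"A": [res, far]})

    def make_site(self, lig_coord):
        r1 = make_residue({"N": [0.0, 1, 0], "CA": [1.0, 0, 0],
                           "C": [2.0, 1, 0]}, seq_index=1)
        r2 = make_residue({"N": [4.0, 1, 0], "CA": [5.0, 0, 0],
                           "C": [6.0, 1, 0]}, seq_index=2)
        return BindingSite(ligand=make_ligand([lig_coord]), residues=[r1, r2])

    def test_threshold_arithmetic(self):
        # N radius 1.75 + C radius 2.0 scaled by 0.6 -> clash below 2.25.
        scaffold = self.scaffold_with_backbone_atom([10.0, 0, 0])
        site = self.make_site([10.0, 0, 2.24])
        assert clash_check(site, scaffold, {}) is False
        site_ok = self.make_site([10.0, 0, 2.26])
        assert clash_check(site_ok, scaffold, {}) is True

    def test_matched_residues_excluded(self):
        scaffold = self.scaffold_with_backbone_atom([10.0, 0, 0])
        site = self.make_site([10.0, 0, 0.5])
        assert clash_check(site, scaffold, {}) is False
        assert clash_check(site, scaffold, {0: ("A", 1)}) is True

    def test_distant_site_clash_free(self):
        scaffold = self.scaffold_with_backbone_atom([10.0, 0, 0])
        assert clash_check(self.make_site([10.0, 0, 30.0]), scaffold, {})

    def test_unknown_element_raises(self):
        scaffold = self.scaffold_with_backbone_atom([10.0, 0, 0])
        site = self.make_site([10.0, 0, 3.0])
        site.ligand.atoms[0].element = "XX"
        with pytest.raises(ConfigurationError) as err:
            clash_check(site, scaffold, {})
        assert "XX" in str(err.value)


class TestMatchLibrary:
    def test_self_scaffold_copies_encounter_one(self, planted):
        scaffold, site, _ = planted
        matrix = match_library([site], [scaffold.copy() for _ in range(5)],
                               stop_at_first=True, seed=1)
        assert matrix.encounter == [1]
        assert (matrix.fast == -1).sum() == 4  # remaining skipped

    def test_encounter_number_follows_seed_order(self, planted):
        scaffold, site, _ = planted
        decoy = make_scaffold(FixtureSpec(n_residues=8, topology="strand"))
        scaffolds = [decoy.copy() for _ in range(4)] + [scaffold]
        for i, s in enumerate(scaffolds):
            s.id = f"scaf{i}"
        matrix = match_library([site], scaffolds, seed=3)
        matched_pos = matrix.order.index(4) + 1
        assert matrix.encounter == [matched_pos]

    def test_full_testing_is_superset_of_stop_at_first(self, planted):
        scaffold, site, _ = planted
        scaffolds = [scaffold.copy() for _ in range(4)]
        full = match_library([site], scaffolds, seed=5, stop_at_first=False)
        lazy = match_library([site], scaffolds, seed=5, stop_at_first=True)
        assert full.encounter == lazy.encounter
        tested_full = set(zip(*np.where(full.fast != -1)))
        tested_lazy = set(zip(*np.where(lazy.fast != -1)))
        assert tested_full >= tested_lazy

    def test_empty_inputs_rejected(self, planted):
        scaffold, site, _ = planted
        with pytest.raises(ParameterError):
            match_library([], [scaffold])
        with pytest.raises(ParameterError):
            match_library([site], [])
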