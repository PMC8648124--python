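import numpy as np
import pytest

from sitematch.core import Atom, Ligand, Residue
from sitematch.fixtures import FixtureSpec, make_scaffold, plant_site


@pytest.fixture(scope="session")
def helix20():
    return make_scaffold(FixtureSpec(n_residues=20, topology="helix"))


@pytest.fixture(scope="session")
def helix24():
    return make_scaffold(FixtureSpec(n_residues=24, topology="helix"))


@pytest.fixture(scope="session")
def bundle40():
    return make_scaffold(FixtureSpec(n_residues=40, topology="two_helix_bundle"))


@pytest.fixture(scope="session")
def planted(helix24):
    """A 3-residue site with a 3-atom pseudo-ligand planted on the helix."""
    site, truth = plant_site(helix24, (5, 9, 12), ligand_atom_count=3, seed=7)
    return helix24, site, truth


def make_residue(coords_by_name, chain_id="A", seq_index=1, aa_type="A",
                 resname="ALA", elements=None):
    """Build a residue from a {atom name: coordinate} mapping."""
    default_el = {"N": "N", "O": "O"}
    atoms = []
    for name, coord in coords_by_name.items():
        el = (elements or {}).get(name, default_el.get(name, "C"))
        atoms.append(Atom(name, el, np.asarray(coord, dtype=float)))
    return Residue(chain_id=chain_id, seq_index=seq_index, aa_type=aa_type,
                   resname=resname, atoms=atoms)


def make_ligand(coords, elements="C", resname="LIG"):
    if isinstance(elements, str):
        elements = [elements] * len(coords)
    atoms = [Atom(f"{el}{i+1}", el, np.asarray(c, dtype=float))
             for i, (c, el) in enumerate(zip(coords, elements))]
    return Ligand(resname=resname, atoms=atoms)
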