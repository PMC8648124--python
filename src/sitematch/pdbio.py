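"""PDB reading and writing, backed by gemmi.

Reading applies the package's normalisation rules: hydrogens dropped,
alternate locations resolved to the highest-occupancy conformer, waters
excluded, protein residues renumbered 1..n per chain, and non-polymer
non-water HETATM groups collected as ligands.
"""
from __future__ import annotations

from pathlib import Path
from typing import Union

import gemmi

from .core import AA_THREE_TO_ONE, Atom, Ligand, Residue, Structure
from .errors import EmptyStructureError, ParameterError, ParseError

__all__ = ["read_pdb", "write_pdb"]

PathLike = Union[str, Path]


def read_pdb(path: PathLike) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Protein residues are renumbered sequentially per chain; author numbering
    (gaps, insertion codes) is discarded.  Ligands are non-polymer,
    non-water HETATM residue groups.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, SystemError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    model = st[0]

    structure = Structure(id=st.name or path.stem)
    if st.resolution and st.resolution > 0:
        structure.resolution = float(st.resolution)

    for chain in model:
        protein_residues: list[Residue] = []
        for res in chain:
            if res.is_water():
                continue
            atoms = _convert_atoms(res)
            if not atoms:
                continue
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            if is_aa:
                one = AA_THREE_TO_ONE.get(res.name.upper(), "X")
                protein_residues.append(
                    Residue(
                        chain_id=chain.name,
                        seq_index=0,  # assigned below
                        aa_type=one,
                        resname=res.name.upper(),
                        atoms=atoms,
                    )
                )
            else:
                structure.ligands.append(
                    Ligand(
                        resname=res.name.upper(),
                        atoms=atoms,
                        source=f"{structure.id}:{chain.name}",
                    )
                )
        if protein_residues:
            for i, r in enumerate(protein_residues, start=1):
                r.seq_index = i
            structure.chains[chain.name] = protein_residues

    if not structure.chains and not structure.ligands:
        raise EmptyStructureError(f"{path} contains no residues or ligands")
    return structure


def _convert_atoms(res: gemmi.Residue) -> list[Atom]:
    """Heavy atoms only, altlocs resolved to highest occupancy per name."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        if atom.element.is_hydrogen:
            continue
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    out = []
    for atom in best.values():
        out.append(
            Atom(
                name=atom.name,
                element=atom.element.name.upper(),
                coord=[atom.pos.x, atom.pos.y, atom.pos.z],
                b_factor=float(atom.b_iso),
            )
        )
    return out


def write_pdb(structure: Structure, path: PathLike) -> None:
    """Write a Structure as PDB; ATOM records first, ligand HETATM after."""
    if structure.n_residues == 0 and not structure.ligands:
        raise ParameterError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = structure.id
    if structure.resolution is not None:
        st.resolution = structure.resolution
    model = gemmi.Model(1)

    for chain_id, residues in structure.chains.items():
        chain = gemmi.Chain(chain_id)
        for res in residues:
            chain.add_residue(_to_gemmi_residue(res.resname, res.seq_index,
                                                res.atoms, het=False))
        model.add_chain(chain)

    if structure.ligands:
        used = set(structure.chains)
        lig_chain_id = next(c for c in "XYZWVUTSRQ0123456789" if c not in used)
        chain = gemmi.Chain(lig_chain_id)
        for i, lig in enumerate(structure.ligands, start=1):
            chain.add_residue(_to_gemmi_residue(lig.resname, i, lig.atoms,
                                                het=True))
        model.add_chain(chain)

    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def _to_gemmi_residue(resname: str, seq_index: int, atoms, het: bool) -> gemmi.Residue:
    res = gemmi.Residue()
    res.name = resname
    res.seqid = gemmi.SeqId(seq_index, " ")
    res.het_flag = "H" if het else "A"
    for a in atoms:
        ga = gemmi.Atom()
        ga.name = a.name
        ga.element = gemmi.Element(a.element.capitalize())
        ga.pos = gemmi.Position(*a.coord)
        ga.occ = 1.0
        ga.b_iso = a.b_factor
        res.add_atom(ga)
    return res
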