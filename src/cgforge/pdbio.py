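"""PDB reading and writing.

Atomistic PDB files come in (coordinates converted Angstrom -> nm, bonds
inferred from standard residue connectivity so constrained hydrogens can
be flagged); CG structures go out as ATOM records named N/CA/CB/C/O with
residue names preserved, coordinates nm -> Angstrom at format precision.
"""
from __future__ import annotations

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .topology import AtomisticTopology, CGTopology, ONE_TO_THREE
from .units import angstrom_to_nm, nm_to_angstrom

__all__ = ["read_pdb", "write_pdb"]


def read_pdb(path):
    """Read an atomistic (or CG) PDB; returns (AtomisticTopology, coords).

    ``coords`` is (models, atoms, 3) in nm.  Every X-H covalent bond is
    treated as constrained, matching the constrained-hydrogen dynamics of
    the source all-atom force fields.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    arr = stack[0]
    n_atoms = arr.array_length()

    res_starts = struc.get_residue_starts(arr)
    res_ids_per_atom = np.zeros(n_atoms, int)
    for r, start in enumerate(res_starts):
        end = res_starts[r + 1] if r + 1 < len(res_starts) else n_atoms
        res_ids_per_atom[start:end] = r
    residue_names = tuple(arr.res_name[s] for s in res_starts)
    chain_ids = tuple(arr.chain_id[s] for s in res_starts)

    elements = tuple(e if e else n[0] for e, n in zip(arr.element, arr.atom_name))
    bonds = struc.connect_via_residue_names(arr)
    h_parent = np.full(n_atoms, -1, int)
    constrained = np.zeros(n_atoms, bool)
    is_h = np.array([e.upper() == "H" for e in elements])
    for a, b, _ in bonds.as_array():
        for h, x in ((a, b), (b, a)):
            if is_h[h] and not is_h[x]:
                h_parent[h] = x
                constrained[h] = True

    top = AtomisticTopology(
        atom_names=tuple(arr.atom_name),
        residue_index=res_ids_per_atom,
        residue_names=residue_names,
        chain_id=chain_ids,
        elements=elements,
        constrained_h=constrained,
        h_parent=h_parent,
    )
    coords = angstrom_to_nm(np.asarray(stack.coord, float))
    return top, coords


def write_pdb(top: CGTopology, coords: np.ndarray, path) -> None:
    """Write a CG structure (or multi-model trajectory) as PDB.

    ``coords`` is (n_beads, 3) or (models, n_beads, 3) in nm.
    """
    coords = np.asarray(coords, float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[1] != top.n_beads:
        raise ValueError(f"coordinates have {coords.shape[1]} sites, topology "
                         f"has {top.n_beads} beads")
    arr = struc.AtomArray(top.n_beads)
    arr.atom_name = np.array(top.bead_names)
    arr.res_id = np.asarray(top.residue_index) + 1
    arr.res_name = np.array([ONE_TO_THREE[top.residue_names[r]]
                             for r in top.residue_index])
    arr.chain_id = np.array(top.chain_id)
    arr.element = np.array([n[0] for n in top.bead_names])
    arr.hetero = np.zeros(top.n_beads, bool)
    models = []
    for m in range(coords.shape[0]):
        a = arr.copy()
        a.coord = nm_to_angstrom(coords[m]).astype(np.float32)
        models.append(a)
    pdb = PDBFile()
    pdb.set_structure(struc.stack(models))
    pdb.write(str(path))
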