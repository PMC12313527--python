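"""Coarse-grained resolution, bead typing and force aggregation.

The CG resolution keeps five heavy atoms per residue — backbone N, CA, C, O
plus the side-chain CB — and four for glycine (no CB).  Exactly one bead per
residue carries a residue-dependent type id: the CB bead, or the CA bead for
glycine.  All remaining beads carry one of four generic backbone types.
Amino-acid identity therefore lives entirely in a single bead type, which is
what makes point mutations a pure retyping operation.

The force-aggregation operator ``M_F`` maps atomistic forces to beads: each
bead receives the force on its preserved heavy atom plus the forces on the
hydrogens attached to it through constrained bonds.  ``M_F`` is linear and
conserves the total force over the aggregated atoms.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CGTopology", "AtomisticTopology",
    "build_cg_topology", "map_coordinates", "aggregate_forces",
    "BACKBONE_TYPE_IDS", "RESIDUE_TYPE_IDS", "ONE_TO_THREE", "THREE_TO_ONE",
]

# Generic backbone bead types; the residue-dependent ids follow.
BACKBONE_TYPE_IDS = {"N": 0, "CA": 1, "C": 2, "O": 3}

_AA_CODES = "ACDEFGHIKLMNPQRSTVWY"  # 20 standard residues, alphabetical

# Residue-dependent type ids 4..23, assigned alphabetically by one-letter code.
RESIDUE_TYPE_IDS = {aa: 4 + i for i, aa in enumerate(_AA_CODES)}

N_BEAD_TYPES = 4 + len(_AA_CODES)

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}
# common protonation/tautomer variants collapse onto the parent residue type
THREE_TO_ONE.update({"HID": "H", "HIE": "H", "HIP": "H", "HSD": "H",
                     "HSE": "H", "HSP": "H", "CYX": "C", "CYM": "C",
                     "ASH": "D", "GLH": "E", "LYN": "K"})

_BEAD_ORDER = ("N", "CA", "CB", "C", "O")       # canonical within-residue order
_BEAD_ORDER_GLY = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class CGTopology:
    """Beads, types, aggregation map and bonded term lists for one or more chains.

    ``aggregation_map`` holds, per bead, the atomistic source-atom indices
    (preserved heavy atom first, then its constrained hydrogens); it is empty
    when the topology was built from a bare sequence.
    """

    n_beads: int
    bead_names: tuple[str, ...]
    bead_types: np.ndarray           # (n_beads,) int
    residue_index: np.ndarray        # (n_beads,) int, residue ordinal
    residue_names: tuple[str, ...]   # per residue, one-letter codes
    chain_id: tuple[str, ...]        # per bead
    aggregation_map: tuple[tuple[int, ...], ...] = ()
    bond_list: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    angle_list: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))
    dihedral_list: np.ndarray = field(default_factory=lambda: np.empty((0, 4), int))

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    def sequence(self) -> str:
        return "".join(self.residue_names)

    def bead_index(self, residue: int, name: str) -> int:
        """Index of the bead ``name`` in residue ``residue`` (ordinal)."""
        for i in range(self.n_beads):
            if self.residue_index[i] == residue and self.bead_names[i] == name:
                return i
        raise KeyError(f"no bead {name!r} in residue {residue}")

    def with_types(self, bead_types: np.ndarray) -> "CGTopology":
        return replace(self, bead_types=np.asarray(bead_types, int))


@dataclass(frozen=True)
class AtomisticTopology:
    """Just enough atomistic structure to map coordinates and forces.

    ``h_parent[i]`` is the index of the heavy atom that hydrogen ``i`` is
    bonded to (-1 for non-hydrogens); ``constrained_h`` flags hydrogens whose
    bond to that parent is treated as constrained.
    """

    atom_names: tuple[str, ...]
    residue_index: np.ndarray        # per atom
    residue_names: tuple[str, ...]   # per residue, three-letter codes
    chain_id: tuple[str, ...]        # per residue
    elements: tuple[str, ...]
    constrained_h: np.ndarray        # (n_atoms,) bool
    h_parent: np.ndarray             # (n_atoms,) int, -1 where not applicable

    def __post_init__(self):
        ch = np.asarray(self.constrained_h, bool)
        elems = np.array([e.upper() for e in self.elements])
        if np.any(ch & (elems != "H")):
            raise ValueError("constrained-bond flags are only valid on hydrogens")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)


def _bead_names_for(code: str) -> tuple[str, ...]:
    return _BEAD_ORDER_GLY if code == "G" else _BEAD_ORDER


def _type_for(code: str, bead: str) -> int:
    """Residue-dependent type on CB (CA for GLY); generic backbone otherwise."""
    if bead == "CB" or (code == "G" and bead == "CA"):
        return RESIDUE_TYPE_IDS[code]
    return BACKBONE_TYPE_IDS[bead]


def _bonded_terms(bead_names, residue_index, chain_id):
    """Covalent CG bond graph plus all angles and backbone dihedrals."""
    n = len(bead_names)
    index = {}
    for i in range(n):
        index[(chain_id[i], int(residue_index[i]), bead_names[i])] = i

    bonds = []

    def link(a, b):
        if a is not None and b is not None:
            bonds.append((a, b))

    residues = sorted({(c, int(r)) for c, r in zip(chain_id, residue_index)})
    for c, r in residues:
        get = lambda name: index.get((c, r, name))
        link(get("N"), get("CA"))
        link(get("CA"), get("CB"))
        link(get("CA"), get("C"))
        link(get("C"), get("O"))
        nxt = index.get((c, r + 1, "N"))
        link(get("C"), nxt)

    # angles: every pair of bonds sharing a bead
    adj = [[] for _ in range(n)]
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    angles = []
    for j in range(n):
        nb = sorted(adj[j])
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                angles.append((nb[x], j, nb[y]))

    # backbone dihedrals: consecutive quadruplets along N-CA-C-N-CA-C-...
    dihedrals = []
    for c in sorted({c for c, _ in residues}):
        backbone = []
        for cc, r in residues:
            if cc != c:
                continue
            for name in ("N", "CA", "C"):
                i = index.get((c, r, name))
                if i is not None:
                    backbone.append(i)
        for k in range(len(backbone) - 3):
            dihedrals.append(tuple(backbone[k:k + 4]))

    return (np.array(bonds, int).reshape(-1, 2),
            np.array(angles, int).reshape(-1, 3),
            np.array(dihedrals, int).reshape(-1, 4))


def _from_sequence(sequence: str, chain: str = "A") -> CGTopology:
    bead_names, bead_types, res_idx, chain_id = [], [], [], []
    res_names = []
    for r, code in enumerate(sequence):
        if code not in RESIDUE_TYPE_IDS:
            raise ValueError(f"unknown residue code {code!r} at position {r}")
        res_names.append(code)
        for bead in _bead_names_for(code):
            bead_names.append(bead)
            bead_types.append(_type_for(code, bead))
            res_idx.append(r)
            chain_id.append(chain)
    res_idx = np.array(res_idx, int)
    bonds, angles, dihedrals = _bonded_terms(bead_names, res_idx, chain_id)
    return CGTopology(
        n_beads=len(bead_names),
        bead_names=tuple(bead_names),
        bead_types=np.array(bead_types, int),
        residue_index=res_idx,
        residue_names=tuple(res_names),
        chain_id=tuple(chain_id),
        bond_list=bonds, angle_list=angles, dihedral_list=dihedrals,
    )


def _from_atomistic(top: AtomisticTopology) -> CGTopology:
    res_atoms: list[dict[str, int]] = [dict() for _ in range(top.n_residues)]
    for i, name in enumerate(top.atom_names):
        res_atoms[int(top.residue_index[i])].setdefault(name, i)

    codes = []
    for r, rn in enumerate(top.residue_names):
        code = THREE_TO_ONE.get(rn.upper())
        if code is None:
            raise ValueError(f"unknown residue code {rn!r} at position {r}")
        codes.append(code)

    # hydrogens grouped by constrained-bond parent
    h_of: dict[int, list[int]] = {}
    for i in range(top.n_atoms):
        if top.constrained_h[i]:
            p = int(top.h_parent[i])
            if p < 0:
                raise ValueError(
                    f"hydrogen {top.atom_names[i]!r} (atom {i}) is flagged as "
                    "constrained but bonded to no heavy atom")
            h_of.setdefault(p, []).append(i)

    bead_names, bead_types, res_idx, chain_id, agg = [], [], [], [], []
    for r, code in enumerate(codes):
        for bead in _bead_names_for(code):
            ai = res_atoms[r].get(bead)
            if ai is None:
                raise ValueError(
                    f"missing atom {bead!r} in residue {top.residue_names[r]}{r}")
            bead_names.append(bead)
            bead_types.append(_type_for(code, bead))
            res_idx.append(r)
            chain_id.append(top.chain_id[r])
            agg.append((ai, *sorted(h_of.get(ai, ()))))

    res_idx = np.array(res_idx, int)
    bonds, angles, dihedrals = _bonded_terms(bead_names, res_idx, chain_id)
    return CGTopology(
        n_beads=len(bead_names),
        bead_names=tuple(bead_names),
        bead_types=np.array(bead_types, int),
        residue_index=res_idx,
        residue_names=tuple(codes),
        chain_id=tuple(chain_id),
        aggregation_map=tuple(tuple(a) for a in agg),
        bond_list=bonds, angle_list=angles, dihedral_list=dihedrals,
    )


def build_cg_topology(sequence_or_topology) -> CGTopology:
    """Build the five-bead-per-residue CG topology (four for glycine).

    Accepts either a one-letter amino-acid sequence or an
    :class:`AtomisticTopology`; in the latter case the aggregation map
    (preserved atom + constrained hydrogens per bead) is filled in.
    """
    if isinstance(sequence_or_topology, str):
        return _from_sequence(sequence_or_topology)
    if isinstance(sequence_or_topology, AtomisticTopology):
        return _from_atomistic(sequence_or_topology)
    raise TypeError(
        "expected a one-letter sequence or an AtomisticTopology, got "
        f"{type(sequence_or_topology).__name__}")


def map_coordinates(coords: np.ndarray, top: CGTopology) -> np.ndarray:
    """Slice CG coordinates: each bead sits on its preserved heavy atom.

    ``coords`` is (n_frames, n_atoms, 3) or an object with a ``coords``
    attribute; returns (n_frames, n_beads, 3).
    """
    if not top.aggregation_map:
        raise ValueError("topology has no aggregation map (built from sequence?)")
    coords = np.asarray(getattr(coords, "coords", coords))
    preserved = np.array([m[0] for m in top.aggregation_map], int)
    if preserved.max(initial=-1) >= coords.shape[-2]:
        raise IndexError(
            f"aggregation map addresses atom {preserved.max()} but frames have "
            f"only {coords.shape[-2]} atoms")
    return coords[..., preserved, :]


def aggregate_forces(forces: np.ndarray, top: CGTopology) -> np.ndarray:
    """Apply ``M_F``: bead force = preserved-atom force + constrained-H forces.

    Atoms that are neither preserved nor flagged contribute nothing.  Linear
    in the input and exactly total-force conserving over aggregated atoms.
    """
    if not top.aggregation_map:
        raise ValueError("topology has no aggregation map (built from sequence?)")
    forces = np.asarray(getattr(forces, "forces", forces))
    single = forces.ndim == 2
    if single:
        forces = forces[None]
    atom_idx = np.array([a for m in top.aggregation_map for a in m], int)
    bead_idx = np.array([b for b, m in enumerate(top.aggregation_map) for _ in m], int)
    if atom_idx.size and atom_idx.max() >= forces.shape[1]:
        raise IndexError(
            f"aggregation map addresses atom {atom_idx.max()} but frames have "
            f"only {forces.shape[1]} atoms")
    # accumulate with the atom axis leading so duplicate bead indices add up
    src = forces.transpose(1, 0, 2)[atom_idx]
    out = np.zeros((top.n_beads, forces.shape[0], 3))
    np.add.at(out, bead_idx, src)
    out = out.transpose(1, 0, 2)
    return out[0] if single else out
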