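"""CG mapping: bead counts, typing, coordinate slicing, force aggregation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgforge.topology import (AtomisticTopology, BACKBONE_TYPE_IDS,
                              RESIDUE_TYPE_IDS, build_cg_topology,
                              map_coordinates, aggregate_forces)
from cgforge.framesets import map_frameset

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_bead_count(seq: str) -> int:
    """Independent enumeration oracle: 5 beads per residue, 4 for GLY."""
    return sum(4 if c == "G" else 5 for c in seq)


@pytest.mark.parametrize("seq,expected", [
    ("A", 5),
    ("SLEAGGRG", 37),
    ("DYGCSIHP", 39),
])
def test_bead_counts_worked_examples(seq, expected):
    assert brute_force_bead_count(seq) == expected
    top = build_cg_topology(seq)
    assert top.n_beads == expected
    assert top.n_residues == len(seq)


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet=AA, min_size=1, max_size=30))
def test_bead_count_formula(seq):
    """n_beads = 5 n_residues - n_GLY, against the enumeration oracle."""
    top = build_cg_topology(seq)
    assert top.n_beads == 5 * len(seq) - seq.count("G")
    assert top.n_beads == brute_force_bead_count(seq)


def test_residue_identity_lives_in_one_bead():
    top = build_cg_topology("AGV")
    # non-GLY: CB carries the residue type, backbone beads are generic
    for r, code in enumerate("AGV"):
        beads = [i for i in range(top.n_beads) if top.residue_index[i] == r]
        names = [top.bead_names[i] for i in beads]
        types = [int(top.bead_types[i]) for i in beads]
        if code == "G":
            assert names == ["N", "CA", "C", "O"]
            assert types[1] == RESIDUE_TYPE_IDS["G"]
            assert types[0] == BACKBONE_TYPE_IDS["N"]
        else:
            assert names == ["N", "CA", "CB", "C", "O"]
            assert types[2] == RESIDUE_TYPE_IDS[code]
            assert [types[0], types[1], types[3], types[4]] == [
                BACKBONE_TYPE_IDS[n] for n in ("N", "CA", "C", "O")]


def test_unknown_residue_rejected():
    with pytest.raises(ValueError, match="X"):
        build_cg_topology("AXA")


def test_bonded_term_lists_cover_chain():
    top = build_cg_topology("AAA")
    # 5 beads/residue: 4 intra bonds + 1 peptide bond per junction
    assert len(top.bond_list) == 3 * 4 + 2
    assert len(top.dihedral_list) == 3 * 3 - 3  # N-CA-C backbone quadruplets
    # angles: every bond pair sharing a bead, all indices valid
    assert top.angle_list.min() >= 0 and top.angle_list.max() < top.n_beads


def _tiny_atomistic():
    """3 atoms: CA with one constrained H, plus O (no H); 1 GLY residue."""
    return AtomisticTopology(
        atom_names=("N", "CA", "HA", "C", "O"),
        residue_index=np.array([0, 0, 0, 0, 0]),
        residue_names=("GLY",),
        chain_id=("A",),
        elements=("N", "C", "H", "C", "O"),
        constrained_h=np.array([False, False, True, False, False]),
        h_parent=np.array([-1, -1, 1, -1, -1]),
    )


def test_map_coordinates_slices_preserved_atoms():
    atop = _tiny_atomistic()
    top = build_cg_topology(atop)
    coords = np.arange(2 * 5 * 3, dtype=float).reshape(2, 5, 3)
    cg = map_coordinates(coords, top)
    assert cg.shape == (2, 4, 3)
    # CA bead sits exactly on the CA atom, every frame, order preserved
    np.testing.assert_array_equal(cg[:, 1], coords[:, 1])
    np.testing.assert_array_equal(cg[0], coords[0][[0, 1, 3, 4]])


def test_mapping_is_name_resolved_not_order_resolved():
    atop = _tiny_atomistic()
    perm = [4, 2, 0, 1, 3]
    atop2 = AtomisticTopology(
        atom_names=tuple(atop.atom_names[i] for i in perm),
        residue_index=atop.residue_index[perm],
        residue_names=atop.residue_names,
        chain_id=atop.chain_id,
        elements=tuple(atop.elements[i] for i in perm),
        constrained_h=atop.constrained_h[perm],
        h_parent=np.array([{-1: -1, 1: perm.index(1)}.get(int(p), -1)
                           for p in atop.h_parent[perm]]),
    )
    coords = np.random.default_rng(0).normal(size=(3, 5, 3))
    cg1 = map_coordinates(coords, build_cg_topology(atop))
    cg2 = map_coordinates(coords[:, perm], build_cg_topology(atop2))
    np.testing.assert_allclose(cg1, cg2)


def test_aggregation_sums_preserved_and_hydrogens():
    atop = _tiny_atomistic()
    top = build_cg_topology(atop)
    f = np.zeros((1, 5, 3))
    f[0, 1] = [1.0, 0.0, 0.0]   # CA
    f[0, 2] = [0.0, 1.0, 0.0]   # HA, constrained to CA
    f[0, 4] = [0.5, 0.5, 0.5]   # O, no hydrogens
    out = aggregate_forces(f, top)
    np.testing.assert_array_equal(out[0, 1], [1.0, 1.0, 0.0])
    np.testing.assert_array_equal(out[0, 3], [0.5, 0.5, 0.5])
    # N bead receives only the (zero) N force
    np.testing.assert_array_equal(out[0, 0], [0.0, 0.0, 0.0])


def test_aggregation_matches_bruteforce_loop(toy_frameset, toy_tops):
    _, ctop = toy_tops
    out = aggregate_forces(toy_frameset.forces, ctop)
    ref = np.zeros_like(out)
    for b, members in enumerate(ctop.aggregation_map):
        for a in members:
            ref[:, b] += toy_frameset.forces[:, a]
    np.testing.assert_allclose(out, ref, rtol=0, atol=0)


def test_aggregation_linearity_and_conservation(toy_tops, rng):
    _, ctop = toy_tops
    n_atoms = max(a for m in ctop.aggregation_map for a in m) + 1
    f = rng.normal(size=(4, n_atoms, 3))
    g = rng.normal(size=(4, n_atoms, 3))
    a, b = 1.7, -0.3
    lhs = aggregate_forces(a * f + b * g, ctop)
    rhs = a * aggregate_forces(f, ctop) + b * aggregate_forces(g, ctop)
    np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-12)
    used = sorted(a for m in ctop.aggregation_map for a in m)
    np.testing.assert_allclose(lhs.sum(axis=1),
                               (a * f + b * g)[:, used].sum(axis=1),
                               rtol=1e-12, atol=1e-12)


def test_flagged_hydrogen_without_parent_rejected():
    with pytest.raises(ValueError, match="bonded to no heavy atom|constrained"):
        atop = AtomisticTopology(
            atom_names=("N", "CA", "HA", "C", "O"),
            residue_index=np.array([0] * 5),
            residue_names=("GLY",),
            chain_id=("A",),
            elements=("N", "C", "H", "C", "O"),
            constrained_h=np.array([False, False, True, False, False]),
            h_parent=np.array([-1, -1, -1, -1, -1]),
        )
        build_cg_topology(atop)


def test_missing_backbone_atom_named_in_error():
    atop = AtomisticTopology(
        atom_names=("N", "CA", "C"),       # O missing
        residue_index=np.array([0, 0, 0]),
        residue_names=("GLY",),
        chain_id=("A",),
        elements=("N", "C", "C"),
        constrained_h=np.array([False] * 3),
        h_parent=np.array([-1] * 3),
    )
    with pytest.raises(ValueError, match="'O'.*GLY"):
        build_cg_topology(atop)
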