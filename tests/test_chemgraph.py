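"""Graph primitives: reduction, duplicate expansion, distances, handedness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ncaatools import fixtures
from ncaatools.chemgraph import (
    Atom,
    Bond,
    BackboneNotFoundError,
    ChemGraphError,
    DegenerateGeometryError,
    MolecularGraph,
    bond_distances,
    chirality_sign,
    expand_unsaturation,
    find_backbone,
    heavy_atom_subgraph,
)


def chain(*elements, orders=None):
    atoms = [Atom(i + 1, f"{el}{i + 1}", el) for i, el in enumerate(elements)]
    orders = orders or [1] * (len(atoms) - 1)
    bonds = [Bond(i + 1, i + 2, o) for i, o in enumerate(orders)]
    return MolecularGraph(atoms, bonds)


class TestHeavyAtomSubgraph:
    def test_methane_reduces_to_lone_carbon(self):
        g = fixtures.toy("methane")
        heavy = heavy_atom_subgraph(g)
        assert len(heavy) == 1
        assert heavy.atoms[0].element == "C"

    def test_cysteine_side_chain_reduces_to_ca_cb_sg_chain(self, residue_graphs):
        heavy = heavy_atom_subgraph(residue_graphs["CYS"])
        names = {a.name for a in heavy.atoms}
        assert names == {"N", "CA", "C", "O", "OXT", "CB", "SG"}
        ca = heavy.atom_by_name("CA").serial
        cb = heavy.atom_by_name("CB").serial
        sg = heavy.atom_by_name("SG").serial
        assert cb in heavy.neighbors(ca) and sg in heavy.neighbors(cb)

    def test_ethene_keeps_double_bond_order(self):
        heavy = heavy_atom_subgraph(fixtures.toy("ethene"))
        assert len(heavy) == 2
        assert heavy.bonds[0].order == 2

    def test_serials_preserved(self, residue_graphs):
        g = residue_graphs["SER"]
        heavy = heavy_atom_subgraph(g)
        for a in heavy.atoms:
            assert g.atom(a.serial).name == a.name


class TestExpandUnsaturation:
    def test_ethene_gains_one_duplicate_per_carbon(self):
        heavy = heavy_atom_subgraph(fixtures.toy("ethene"))
        exp = expand_unsaturation(heavy)
        assert len(exp) == 4
        dups = [a for a in exp.atoms if a.is_duplicate]
        assert len(dups) == 2
        assert all(a.element == "C" for a in dups)
        assert all(exp.degree(a.serial) == 1 for a in dups)

    def test_carbonyl_duplicates_cross_elements(self):
        g = chain("C", "O", orders=[2])
        exp = expand_unsaturation(g)
        by_parent = {exp.neighbors(d.serial)[0]: d.element
                     for d in exp.atoms if d.is_duplicate}
        assert by_parent == {1: "O", 2: "C"}

    def test_aromatic_ring_one_self_duplicate_per_atom(self, residue_graphs):
        heavy = heavy_atom_subgraph(residue_graphs["PHE"])
        exp = expand_unsaturation(heavy)
        ring = [heavy.atom_by_name(n).serial
                for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")]
        for s in ring:
            dups = [t for t in exp.neighbors(s) if exp.atom(t).is_duplicate]
            assert len(dups) == 1
            assert exp.atom(dups[0]).element == "C"

    def test_unknown_order_is_an_error_naming_the_bond(self):
        g = chain("C", "C", orders=["weird"])
        with pytest.raises(ChemGraphError, match="1-2"):
            expand_unsaturation(g)

    def test_original_distances_unchanged(self, residue_graphs):
        heavy = heavy_atom_subgraph(residue_graphs["TRP"])
        before = bond_distances(heavy, heavy.atom_by_name("CA").serial)
        exp = expand_unsaturation(heavy)
        after = bond_distances(exp, heavy.atom_by_name("CA").serial)
        assert all(after[s] == d for s, d in before.items())


class TestBondDistances:
    def test_linear_chain(self):
        g = chain("C", "C", "C")
        assert bond_distances(g, 1) == {1: 0, 2: 1, 3: 2}

    def test_phenylalanine_ring_closure_distance(self, residue_graphs):
        heavy = heavy_atom_subgraph(residue_graphs["PHE"])
        dist = bond_distances(heavy, heavy.atom_by_name("CA").serial)
        assert dist[heavy.atom_by_name("CZ").serial] == 5

    def test_disconnected_atom_absent(self):
        g = MolecularGraph([Atom(1, "A", "C"), Atom(2, "B", "C")], [])
        assert bond_distances(g, 1) == {1: 0}

    def test_unknown_source_errors(self):
        with pytest.raises(ChemGraphError):
            bond_distances(chain("C", "C"), 99)


UNIT_TET = dict(
    p_high=(1.0, 1.0, 1.0), p_low=(1.0, -1.0, -1.0),
    center=(0.0, 0.0, 0.0), anchor=(-1.0, 1.0, -1.0))


class TestChiralitySign:
    def test_swap_flips_sign(self):
        s1 = chirality_sign(**UNIT_TET)
        s2 = chirality_sign(UNIT_TET["p_low"], UNIT_TET["p_high"],
                            UNIT_TET["center"], UNIT_TET["anchor"])
        assert s1 == -s2

    def test_mirror_flips_sign(self):
        flipped = {k: (-v[0], v[1], v[2]) for k, v in UNIT_TET.items()}
        assert chirality_sign(**UNIT_TET) == -chirality_sign(**flipped)

    def test_coplanar_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            chirality_sign((1, 0, 0), (0, 1, 0), (0, 0, 0), (1, 1, 0))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-math.pi, math.pi), min_size=3, max_size=3),
           st.lists(st.floats(-5, 5), min_size=3, max_size=3))
    def test_invariant_under_rigid_motion(self, angles, shift):
        ax, ay, az = angles
        rx = np.array([[1, 0, 0], [0, math.cos(ax), -math.sin(ax)],
                       [0, math.sin(ax), math.cos(ax)]])
        ry = np.array([[math.cos(ay), 0, math.sin(ay)], [0, 1, 0],
                       [-math.sin(ay), 0, math.cos(ay)]])
        rz = np.array([[math.cos(az), -math.sin(az), 0],
                       [math.sin(az), math.cos(az), 0], [0, 0, 1]])
        rot = rx @ ry @ rz
        moved = {k: tuple(rot @ np.array(v) + np.array(shift))
                 for k, v in UNIT_TET.items()}
        assert chirality_sign(**moved) == chirality_sign(**UNIT_TET)


class TestFindBackbone:
    def test_named_glycine(self, residue_graphs):
        g = residue_graphs["GLY"]
        bb = find_backbone(g)
        assert g.atom(bb.n).name == "N"
        assert g.atom(bb.ca).name == "CA"
        assert g.atom(bb.c).name == "C"
        assert g.atom(bb.o).name == "O"

    def test_scrambled_names_found_by_motif(self, residue_graphs):
        g = residue_graphs["ALA"].copy()
        named = find_backbone(g)
        for i, a in enumerate(g.atoms):
            a.name = f"X{i}"
        bb = find_backbone(g)
        assert (bb.n, bb.ca, bb.c) == (named.n, named.ca, named.c)

    def test_ethanol_has_no_backbone(self):
        with pytest.raises(BackboneNotFoundError, match="no backbone motif"):
            find_backbone(fixtures.toy("ethanol"))
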