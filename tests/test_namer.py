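"""Side-chain naming: positional labels, CIP priorities, chain numbers,
hydrogen and pseudoatom names."""

import pytest
from hypothesis import given, settings, strategies as st

from ncaatools import fixtures, namer
from ncaatools.chemgraph import expand_unsaturation, find_backbone, heavy_atom_subgraph
from ncaatools.namer import (
    NamingError,
    assign_chains,
    cip_compare,
    distance_for_label,
    label_sequence,
    position_label,
    rename,
)


class TestPositionLabels:
    @pytest.mark.parametrize("distance,label", [
        (1, "B"),      # beta: one bond from C-alpha
        (2, "G"),      # gamma
        (14, "O"),     # omicron
        (23, "W"),     # omega, last single letter
        (24, "AA"),    # first two-letter code
        (599, "WW"),   # omega-omega, last supported position
    ])
    def test_known_labels(self, distance, label):
        assert position_label(distance) == label

    def test_sequence_has_600_unique_labels(self):
        seq = label_sequence()
        assert len(seq) == 600
        assert len(set(seq)) == 600

    def test_two_letter_codes_start_at_position_25(self):
        seq = label_sequence()
        first_two = next(i for i, lab in enumerate(seq) if len(lab) == 2)
        assert first_two + 1 == 25  # 1-based, alpha counted as position 1

    def test_bijective_over_supported_range(self):
        for d in range(1, 600):
            assert distance_for_label(position_label(d)) == d

    @pytest.mark.parametrize("bad", [0, -3, 600, 1000])
    def test_out_of_range_distance_rejected(self, bad):
        with pytest.raises(NamingError):
            position_label(bad)


def _expanded_side(graph):
    bb = find_backbone(graph)
    heavy = heavy_atom_subgraph(graph)
    drop = {bb.n, bb.c}
    side = heavy.subgraph(a.serial for a in heavy.atoms
                          if a.serial not in drop)
    return expand_unsaturation(side), bb


class TestCipCompare:
    def test_oxygen_branch_beats_carbon_branch(self):
        g = fixtures.toy("o_vs_c_branch")
        exp, _ = _expanded_side(g)
        cb = g.atom_by_name("CB").serial
        c1 = g.atom_by_name("CG1").serial  # -CH2-OH
        c2 = g.atom_by_name("CG2").serial  # -CH2-CH3
        assert cip_compare(exp, c1, c2, cb) == "a_first"
        assert cip_compare(exp, c2, c1, cb) == "b_first"

    def test_valine_methyls_tie(self, residue_graphs):
        g = residue_graphs["VAL"]
        exp, _ = _expanded_side(g)
        cb = g.atom_by_name("CB").serial
        g1 = g.atom_by_name("CG1").serial
        g2 = g.atom_by_name("CG2").serial
        assert cip_compare(exp, g1, g2, cb) == "tie"

    def test_ile_ethyl_beats_methyl_at_sphere_two(self, residue_graphs):
        g = residue_graphs["ILE"]
        exp, _ = _expanded_side(g)
        cb = g.atom_by_name("CB").serial
        g1 = g.atom_by_name("CG1").serial
        g2 = g.atom_by_name("CG2").serial
        assert cip_compare(exp, g1, g2, cb) == "a_first"


class TestAssignChains:
    def test_phenylalanine_ring_join_takes_chain_one(self, residue_graphs):
        g = residue_graphs["PHE"]
        bb = find_backbone(g)
        asg = assign_chains(g, bb)
        cz = g.atom_by_name("CZ").serial
        assert asg.distance[cz] == 5
        assert asg.chain[cz] == 1

    def test_oxygen_chain_outranks_carbon_chain(self):
        g = fixtures.toy("o_vs_c_branch")
        bb = find_backbone(g)
        asg = assign_chains(g, bb)
        od = g.atom_by_name("OD").serial
        cd = g.atom_by_name("CD").serial
        assert asg.chain[od] == 1
        assert asg.chain[cd] == 2

    def test_valine_methyls_resolved_geometrically(self, residue_graphs):
        g = residue_graphs["VAL"]
        asg = assign_chains(g, find_backbone(g))
        g1 = g.atom_by_name("CG1").serial
        g2 = g.atom_by_name("CG2").serial
        assert {asg.chain[g1], asg.chain[g2]} == {1, 2}
        assert asg.resolved_by[g1] == "geometric"
        # mirroring the coordinates swaps the two chains
        gm = fixtures.mirror(g)
        masg = assign_chains(gm, find_backbone(gm))
        assert masg.chain[g1] == asg.chain[g2]
        assert masg.chain[g2] == asg.chain[g1]

    def test_twin_rings_get_consecutive_chain_blocks(self):
        g = fixtures.toy("twin_rings")
        asg = assign_chains(g, find_backbone(g))
        ring_a = {asg.chain[a.serial] for a in g.atoms
                  if a.name.startswith("a")}
        ring_b = {asg.chain[a.serial] for a in g.atoms
                  if a.name.startswith("b")}
        assert (ring_a, ring_b) == ({1, 2}, {3, 4}) \
            or (ring_a, ring_b) == ({3, 4}, {1, 2})

    def test_disconnected_side_chain_atom_rejected(self, residue_graphs):
        from ncaatools.chemgraph import Atom
        g = residue_graphs["ALA"].copy()
        g.add_atom(Atom(g.new_serial(), "CX", "C"))
        with pytest.raises(NamingError, match="unreachable"):
            assign_chains(g, find_backbone(g))


class TestNameAtoms:
    def test_cysteine_heavy_names(self, residue_graphs):
        res = rename(residue_graphs["CYS"])
        names = set(res.heavy_names.values())
        assert {"CB", "SG"} <= names

    def test_sole_occupant_on_chain_one_unnumbered(self, residue_graphs):
        res = rename(residue_graphs["SER"])
        assert "OG" in res.heavy_names.values()

    def test_sole_occupant_off_chain_one_keeps_number(self, residue_graphs):
        # tryptophan eta carbon is the only atom six bonds out but sits on
        # chain 2, so it keeps the number (the conventional CH2)
        res = rename(residue_graphs["TRP"])
        assert "CH2" in res.heavy_names.values()

    def test_methylene_pair_swaps_under_mirror(self, residue_graphs):
        g = residue_graphs["CYS"]
        r1 = rename(g)
        r2 = rename(fixtures.mirror(g))
        changed = sorted(r1.hydrogen_names[s] for s in r1.hydrogen_names
                         if r1.hydrogen_names[s] != r2.hydrogen_names[s])
        assert changed == ["HB2", "HB3"]

    def test_sticky_suffix_restores_ile_cd1(self, residue_graphs):
        g = residue_graphs["ILE"]
        assert "CD" in rename(g).heavy_names.values()
        sticky = rename(g, sticky_suffix=True)
        assert "CD1" in sticky.heavy_names.values()
        # unbranched side chains stay unnumbered even with the option on
        lys = rename(residue_graphs["LYS"], sticky_suffix=True)
        assert "NZ" in lys.heavy_names.values()

    def test_pseudoatoms_cover_methyls_and_aromatic_pairs(self, residue_graphs):
        res = rename(residue_graphs["PHE"])
        assert {"QB", "QD", "QE"} <= set(res.pseudoatoms)
        val = rename(residue_graphs["VAL"])
        assert {"QG1", "QG2"} <= set(val.pseudoatoms)

    def test_all_names_unique_and_complete(self, residue_graphs):
        for code, g in residue_graphs.items():
            res = rename(g)
            names = list(res.names.values())
            assert len(names) == len(set(names)), code
            real = [a.serial for a in g.atoms if not a.is_pseudo]
            assert sorted(res.names) == sorted(real), code


class TestRenameProperties:
    @pytest.mark.parametrize("code", ["ORN", "LEU", "TRP", "PRO"])
    def test_permutation_invariance_up_to_rotational_classes(self, code,
                                                             residue_graphs):
        g = residue_graphs[code]
        base = rename(g)
        by_old = {g.atom(s).name: n for s, n in base.heavy_names.items()}
        for seed in range(10):
            gp, _ = fixtures.permute_serials(g, seed)
            rp = rename(gp)
            assert {gp.atom(s).name: n
                    for s, n in rp.heavy_names.items()} == by_old
            # the full name multiset is stable even where rotationally
            # equivalent hydrogens trade indices
            assert sorted(rp.names.values()) == sorted(base.names.values())

    def test_ornithine_side_chain(self, residue_graphs):
        res = rename(residue_graphs["ORN"])
        heavy = {res.heavy_names[s] for s in res.assignment.distance}
        assert heavy == {"CB", "CG", "CD", "NE"}

    def test_d_residue_mirror_swaps_only_stereo_pairs(self, residue_graphs):
        g = residue_graphs["ORN"]
        r1, r2 = rename(g), rename(fixtures.mirror(g))
        assert r1.heavy_names == r2.heavy_names
        changed = {r1.hydrogen_names[s]
                   for s in r1.hydrogen_names
                   if r1.hydrogen_names[s] != r2.hydrogen_names[s]}
        # every change is a 2/3 methylene swap, never a heavy atom
        assert changed and all(n[-1] in "23" for n in changed)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_random_side_chains_always_get_unique_complete_names(self, seed):
        g = fixtures.random_side_chain(seed)
        res = rename(g)
        names = list(res.names.values())
        assert len(names) == len(set(names))
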