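"""CNS building-block patching: charge bookkeeping and type management."""

import pytest

from ncaatools.cnspatch import (
    BondedTerm,
    CnsPatchError,
    ResidueTopology,
    TopologyAtom,
    build_cns_patch,
    parameter_text,
    resolve_type_clashes,
    topology_text,
)

STANDARD_BACKBONE = {
    "N": ("NH1", -0.36), "HN": ("H", 0.26), "CA": ("CT1", 0.07),
    "HA": ("HB", 0.09), "CB": ("CT2", -0.18), "O": ("O", -0.51),
    "C": ("C", 0.51),
}


def toy_residue(side_charges, name="TOY"):
    atoms = [TopologyAtom("N", "nA", -0.36), TopologyAtom("HN", "hA", 0.26),
             TopologyAtom("CA", "cA", 0.07), TopologyAtom("HA", "hB", 0.09),
             TopologyAtom("CB", "cB", -0.18), TopologyAtom("O", "oA", -0.51),
             TopologyAtom("C", "cC", 0.51)]
    atoms += [TopologyAtom(f"S{i+1}", f"t{i+1}", q)
              for i, q in enumerate(side_charges)]
    return ResidueTopology(name=name, atoms=atoms)


class TestBuildCnsPatch:
    def test_zero_residual_leaves_charges_unchanged(self):
        topo = toy_residue([0.30, -0.18])
        net = sum(a.charge for a in topo.atoms)
        block = build_cns_patch(topo, STANDARD_BACKBONE, net)
        by_name = {a.name: a.charge for a in block.atoms}
        assert by_name["S1"] == pytest.approx(0.30)
        assert by_name["S2"] == pytest.approx(-0.18)
        assert not any("residual" in line for line in block.audit)

    def test_residual_lands_on_largest_magnitude_side_atom(self):
        # target the documented arithmetic: residual +0.05 e onto an atom
        # at -0.30 gives -0.25, with the total landing on the net charge
        topo = toy_residue([-0.30, 0.10])
        net = sum(a.charge for a in topo.atoms) + 0.05
        block = build_cns_patch(topo, STANDARD_BACKBONE, net, retain_c=True)
        by_name = {a.name: a.charge for a in block.atoms}
        assert by_name["S1"] == pytest.approx(-0.25)
        assert block.total_charge() == pytest.approx(net, abs=1e-6)

    def test_tie_broken_by_atom_name_order(self):
        topo = toy_residue([0.30, -0.30])
        net = sum(a.charge for a in topo.atoms) + 0.02
        block = build_cns_patch(topo, STANDARD_BACKBONE, net, retain_c=True)
        by_name = {a.name: a.charge for a in block.atoms}
        assert by_name["S1"] == pytest.approx(0.32)
        assert by_name["S2"] == pytest.approx(-0.30)

    def test_no_absorber_is_an_error(self):
        topo = toy_residue([])  # glycine-like: no side-chain atom at all
        with pytest.raises(CnsPatchError, match="no non-backbone atom"):
            build_cns_patch(topo, STANDARD_BACKBONE, 1.0, retain_c=True)

    def test_backbone_keeps_standard_types_and_charges(self):
        topo = toy_residue([0.1])
        net = sum(a.charge for a in topo.atoms)
        block = build_cns_patch(topo, STANDARD_BACKBONE, net)
        by_name = {a.name: (a.type_name, a.charge) for a in block.atoms}
        for bb in ("N", "HN", "CA", "HA", "CB", "O"):
            assert by_name[bb] == STANDARD_BACKBONE[bb]
        # carbonyl C is NOT retained by default (it is absent from the
        # retained list) and gets a fresh type
        assert by_name["C"][0] not in {t for t, _ in STANDARD_BACKBONE.values()}

    def test_retain_c_flag_keeps_carbonyl_standard(self):
        topo = toy_residue([0.1])
        net = sum(a.charge for a in topo.atoms)
        block = build_cns_patch(topo, STANDARD_BACKBONE, net, retain_c=True)
        by_name = {a.name: a.type_name for a in block.atoms}
        assert by_name["C"] == "C"

    def test_missing_backbone_atom_configurable(self):
        topo = toy_residue([0.1])
        topo.atoms = [a for a in topo.atoms if a.name != "HN"]  # N-methylated
        with pytest.raises(CnsPatchError, match="HN"):
            build_cns_patch(topo, STANDARD_BACKBONE, 0.0)
        block = build_cns_patch(topo, STANDARD_BACKBONE,
                                sum(a.charge for a in topo.atoms) + 0.26,
                                allow_missing_backbone=True)
        assert "HN" not in {a.name for a in block.atoms}

    def test_fresh_type_names_unique_within_block(self):
        topo = toy_residue([0.1, -0.2, 0.3, -0.4])
        net = sum(a.charge for a in topo.atoms)
        block = build_cns_patch(topo, STANDARD_BACKBONE, net)
        fresh = [a.type_name for a in block.atoms
                 if a.name not in STANDARD_BACKBONE]
        assert len(fresh) == len(set(fresh))


class TestResolveTypeClashes:
    def make_block(self, name, params):
        topo = toy_residue([0.1], name=name)
        topo.type_params = params
        net = sum(a.charge for a in topo.atoms)
        return build_cns_patch(topo, STANDARD_BACKBONE, net)

    def test_equal_parameters_merge_silently(self):
        # both blocks produce the same fresh names from the same prefix;
        # identical parameters must merge without renames
        b1 = self.make_block("TOA", {"t1": (0.45, 3.5)})
        b2 = self.make_block("TOA", {"t1": (0.45, 3.5)})
        _, report = resolve_type_clashes([b1, b2])
        assert report == []

    def test_conflicting_parameters_renamed_and_reported(self):
        b1 = self.make_block("TOA", {"t1": (0.45, 3.5)})
        b2 = self.make_block("TOA", {"t1": (0.99, 3.0)})
        blocks, report = resolve_type_clashes([b1, b2])
        assert len(report) == 1
        _, old, new = report[0]
        assert new != old
        all_types = [t for b in blocks for t in b.type_params]
        assert len(all_types) == len(set(all_types))

    def test_three_way_clash_two_renames_all_unique(self):
        bs = [self.make_block("TOA", {"t1": (float(i), 3.0)})
              for i in range(3)]
        blocks, report = resolve_type_clashes(bs)
        assert len(report) == 2
        clashing = [next(iter(b.type_params)) for b in blocks]
        assert len(set(clashing)) == 3

    def test_renaming_never_touches_parameters(self):
        b1 = self.make_block("TOA", {"t1": (0.45, 3.5)})
        b2 = self.make_block("TOA", {"t1": (0.99, 3.0)})
        blocks, _ = resolve_type_clashes([b1, b2])
        assert sorted(p for b in blocks for p in b.type_params.values()) == \
            sorted([(0.45, 3.5), (0.99, 3.0)])


class TestSerialisation:
    def test_topology_and_parameter_text(self):
        topo = toy_residue([-0.30, 0.10])
        topo.terms = [BondedTerm("bond", ("CB", "S1"), (230.0, 1.81)),
                      BondedTerm("angle", ("CA", "CB", "S1"))]
        topo.type_params = {"t1": (0.45, 3.56)}
        net = sum(a.charge for a in topo.atoms)
        block = build_cns_patch(topo, STANDARD_BACKBONE, net)
        top = topology_text(block)
        assert top.startswith("RESIdue TOY")
        assert "ATOM CB   TYPE=CT2" in top
        assert "BOND CB   S1" in top
        par = parameter_text(block)
        assert "NONBonded" in par and "230" in par
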