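"""Library linking: DUMMY retyping, overlap restraints, finalisation."""

import pytest

from conftest import disulfide_spec
from ncaatools import fixtures, formats, linker
from ncaatools.linker import (
    DummyAtom,
    LinkError,
    LinkSpec,
    OverlapPair,
    finalize_structure,
    link_templates,
)


@pytest.fixture()
def cysx_template(cysx_lib):
    (tpl,) = formats.read_lib(cysx_lib)
    return tpl


@pytest.fixture()
def van_templates(tmp_path):
    p = tmp_path / "van.lib"
    p.write_text(fixtures.vancomycin_link3_lib_text())
    return formats.read_lib(p)


def van_link3_spec(v5, v7):
    """The third vancomycin side-chain link (residues 5 and 7), using the
    published overlap-atom mapping verbatim."""
    return LinkSpec(
        template_a=v5, template_b=v7, res_index_a=5, res_index_b=7,
        linking_bond=("CD1", "CG3"),
        overlap_pairs=[
            OverlapPair("a", "CZ3", "CD1"),
            OverlapPair("a", "CZ4", "CB"),
            OverlapPair("b", "CE5", "CG1"),
            OverlapPair("b", "CE3", "CE1"),
        ])


class TestLinkTemplates:
    def test_disulfide_gives_four_short_restraints(self, cysx_template):
        result = link_templates(disulfide_spec(cysx_template))
        assert len(result.restraints) == 4
        for r in result.restraints:
            assert r.limit == pytest.approx(0.04)
            assert r.weight == pytest.approx(10)
        pairs = {(r.res_i, r.atom_i, r.res_j, r.atom_j)
                 for r in result.restraints}
        assert (3, "SGX", 12, "SG") in pairs
        assert (12, "CBX", 3, "CB") in pairs

    def test_extension_and_its_hydrogens_retyped_dummy(self, cysx_template):
        result = link_templates(disulfide_spec(cysx_template))
        for tpl in (result.template_a, result.template_b):
            for name in ("SGX", "CBX", "HBX2", "HBX3"):
                assert tpl.atom(name).type_code == "DUMMY"
            # the real side chain and the pseudoatoms are untouched
            assert tpl.atom("SG").type_code == "S_RED"
            assert tpl.atom("QBX").type_code == "PSEUDO"
            assert tpl.atom("QB").type_code == "PSEUDO"

    def test_only_type_code_column_changes(self, cysx_template, cysx_lib):
        result = link_templates(disulfide_spec(cysx_template))
        original = cysx_lib.read_text().splitlines()
        modified = result.template_a.lines()
        assert len(original) == len(modified)
        for before, after in zip(original, modified):
            if before == after:
                continue
            assert len(before) == len(after)
            diff_cols = [i for i, (x, y) in enumerate(zip(before, after))
                         if x != y]
            span = result.template_a.atom(after.split()[1])._type_span
            assert diff_cols
            assert all(span[0] <= i < span[1] for i in diff_cols)

    def test_inputs_not_mutated(self, cysx_template):
        before = cysx_template.lines()
        link_templates(disulfide_spec(cysx_template))
        assert cysx_template.lines() == before

    def test_relinking_own_output_changes_nothing(self, cysx_template):
        result = link_templates(disulfide_spec(cysx_template))
        again = link_templates(LinkSpec(
            template_a=result.template_a, template_b=result.template_b,
            res_index_a=3, res_index_b=12, linking_bond=("SG", "SG"),
            overlap_pairs=disulfide_spec(cysx_template).overlap_pairs))
        assert again.template_a.lines() == result.template_a.lines()

    def test_statement_names_linking_atoms_and_residues(self, cysx_template):
        stmt = link_templates(disulfide_spec(cysx_template)).statement
        assert stmt.render().split() == ["link", "SG", "3", "SG", "12"]

    def test_restraint_count_equals_pair_count(self, cysx_template):
        spec = disulfide_spec(cysx_template)
        for n in (1, 2, 3, 4):
            sub = LinkSpec(spec.template_a, spec.template_b, 3, 12,
                           ("SG", "SG"), spec.overlap_pairs[:n])
            try:
                result = link_templates(sub)
            except LinkError:
                continue  # partial mappings may leave extension atoms bare
            assert len(result.restraints) == n

    def test_vancomycin_link3_published_mapping(self, van_templates):
        v5, v7 = van_templates
        result = link_templates(van_link3_spec(v5, v7))
        assert len(result.restraints) == 4  # one per mapped pair per direction
        touched = {(r.res_i, r.atom_i) for r in result.restraints}
        assert {(5, "CZ3"), (5, "CZ4"), (7, "CE5"), (7, "CE3")} == touched
        reals = {(r.res_j, r.atom_j) for r in result.restraints}
        assert {(7, "CD1"), (7, "CB"), (5, "CG1"), (5, "CE1")} == reals

    def test_unmapped_extension_atom_named_in_error(self, van_templates):
        v5, v7 = van_templates
        spec = van_link3_spec(v5, v7)
        spec.overlap_pairs = [p for p in spec.overlap_pairs
                              if p.ext_atom != "CZ4"]
        with pytest.raises(LinkError, match="CZ4"):
            link_templates(spec)

    def test_nonexistent_overlap_atom_rejected(self, cysx_template):
        spec = disulfide_spec(cysx_template)
        spec.overlap_pairs = spec.overlap_pairs + [
            OverlapPair("a", "ZZ9", "SG")]
        with pytest.raises((LinkError, formats.FormatError), match="ZZ9"):
            link_templates(spec)

    def test_configurable_limit_and_weight(self, cysx_template):
        result = link_templates(disulfide_spec(cysx_template),
                                limit=0.1, weight=2.5)
        assert all(r.limit == 0.1 and r.weight == 2.5
                   for r in result.restraints)


class TestFinalizeStructure:
    def test_dummy_atoms_removed_from_every_model(self):
        pdb = fixtures.multi_model_pdb_text(2)
        registry = [DummyAtom(3, "CYSX", n) for n in ("SGX", "CBX", "HBX2")]
        out = finalize_structure(pdb, registry, {"CYSX": "CYS"})
        assert out.count("ATOM") == pdb.count("ATOM") - 6
        for name in ("SGX", "CBX", "HBX2"):
            assert name not in out

    def test_residue_renamed_everywhere(self):
        pdb = fixtures.multi_model_pdb_text(1)
        out = finalize_structure(
            pdb, [DummyAtom(3, "CYSX", "SGX")], {"CYSX": "CYS"})
        assert "CYSX" not in out
        assert "CYS " in out

    def test_serials_repacked_contiguously(self):
        pdb = fixtures.multi_model_pdb_text(1)
        out = finalize_structure(
            pdb, [DummyAtom(3, "CYSX", "SGX")], {"CYSX": "CYS"})
        serials = [int(line[6:11]) for line in out.splitlines()
                   if line.startswith("ATOM")]
        assert serials == list(range(1, len(serials) + 1))

    def test_noop_is_byte_preserving(self):
        pdb = fixtures.multi_model_pdb_text(2)
        assert finalize_structure(pdb, [], {}) == pdb

    def test_registry_miss_is_an_error(self):
        pdb = fixtures.multi_model_pdb_text(1)
        with pytest.raises(LinkError, match="absent"):
            finalize_structure(pdb, [DummyAtom(99, "CYSX", "SGX")], {})
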