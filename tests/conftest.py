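import pytest

from ncaatools import fixtures, linker


ALL_RESIDUES = fixtures.CANONICAL_RESIDUES + ["ORN", "ABU"]


@pytest.fixture(scope="session")
def residue_graphs():
    """One built graph per canonical residue recipe (session-cached)."""
    return {code: fixtures.residue(code) for code in ALL_RESIDUES}


@pytest.fixture()
def cysx_lib(tmp_path):
    path = tmp_path / "cysx.lib"
    path.write_text(fixtures.cysx_lib_text())
    return path


def disulfide_spec(template):
    """The symmetric disulfide link spec: one extended-cysteine template
    used as both inputs, Sg-Sg linking bond, Cb/Sg overlap each way."""
    pairs = [linker.OverlapPair(side, ext, real)
             for side in ("a", "b")
             for ext, real in (("SGX", "SG"), ("CBX", "CB"))]
    return linker.LinkSpec(
        template_a=template, template_b=template,
        res_index_a=3, res_index_b=12,
        linking_bond=("SG", "SG"), overlap_pairs=pairs)
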