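"""CYANA library linking: side-chain cross-links via DUMMY-overlap templates.

Two residue templates, each extended at least one atom beyond the covalent
bond that will link their side chains, are turned into link-ready
templates: every atom of the extension (and its hydrogens, but never
PSEUDO atoms) is retyped DUMMY so it drops out of non-bonded interactions,
short upper-distance restraints pin each extension copy onto the real atom
it duplicates in the partner template, and a sequence-file link statement
removes the repulsion between the two linking-bond atoms.  After structure
calculation :func:`finalize_structure` strips the DUMMY atoms from the
resulting models and restores standard residue names.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .formats import (
    FormatError,
    LinkStatement,
    ResidueTemplate,
    TemplateAtom,
    UplRestraint,
)

__all__ = [
    "OverlapPair",
    "LinkSpec",
    "LinkResult",
    "DummyAtom",
    "link_templates",
    "finalize_structure",
    "LinkError",
    "DEFAULT_LIMIT",
    "DEFAULT_WEIGHT",
]

logger = logging.getLogger(__name__)

#: Default restraint limit in Angstrom; any positive value within
#: experimental uncertainty works, this is the conventional choice.
DEFAULT_LIMIT = 0.04
#: Default restraint weight (equivalent to this many NOEs).
DEFAULT_WEIGHT = 10.0

DUMMY_TYPE = "DUMMY"
PSEUDO_TYPE = "PSEUDO"


class LinkError(ValueError):
    pass


@dataclass(frozen=True)
class OverlapPair:
    """One overlap atom: its extension copy and the real atom it duplicates.

    ``ext_side`` is ``"a"`` or ``"b"`` — the template holding the extension
    copy named ``ext_atom``; ``real_atom`` is the corresponding atom in the
    other template.
    """

    ext_side: str
    ext_atom: str
    real_atom: str

    def __post_init__(self):
        if self.ext_side not in ("a", "b"):
            raise LinkError(f"ext_side must be 'a' or 'b', got {self.ext_side!r}")


@dataclass
class LinkSpec:
    """User definition of one side-chain link between two residues."""

    template_a: ResidueTemplate
    template_b: ResidueTemplate
    res_index_a: int
    res_index_b: int
    #: (atom name in template_a, atom name in template_b)
    linking_bond: Tuple[str, str]
    overlap_pairs: List[OverlapPair]


@dataclass(frozen=True)
class DummyAtom:
    """Registry entry for one atom retyped DUMMY, for post-calculation removal."""

    res_index: int
    resname: str
    atom_name: str


@dataclass
class LinkResult:
    template_a: ResidueTemplate
    template_b: ResidueTemplate
    restraints: List[UplRestraint]
    statement: LinkStatement
    dummy_registry: List[DummyAtom] = field(default_factory=list)


def _is_pseudo(rec: TemplateAtom) -> bool:
    return rec.type_code.upper() == PSEUDO_TYPE or rec.name.startswith("Q")


def _is_hydrogen(rec: TemplateAtom) -> bool:
    return (not _is_pseudo(rec)
            and (rec.type_code.upper().startswith("H_")
                 or rec.name.startswith("H")))


def _extension_atoms(tpl: ResidueTemplate, linking_atom: str,
                     mapped_ext: Set[str]) -> List[TemplateAtom]:
    """Heavy extension atoms: the connected components beyond the linking
    bond, located from the user-mapped extension atoms and validated
    against them (every heavy extension atom must be mapped exactly once)."""
    link = tpl.atom(linking_atom)
    adj = tpl.adjacency()
    for name in mapped_ext:
        tpl.atom(name)  # existence check, raises with the atom's name
    # components of the template graph with the linking atom removed
    seen: Set[int] = {link.serial}
    ext_serials: Set[int] = set()
    for name in mapped_ext:
        start = tpl.atom(name).serial
        if start in ext_serials:
            continue
        if start == link.serial:
            raise LinkError(
                f"template {tpl.name}: linking atom {name} cannot be its own "
                "extension copy")
        stack = [start]
        comp = set()
        while stack:
            cur = stack.pop()
            if cur in comp or cur == link.serial:
                continue
            comp.add(cur)
            stack.extend(adj[cur])
        ext_serials |= comp
    # the extension must hang off the linking atom, not contain the backbone
    if any(tpl.by_serial(s).name in ("N", "CA") for s in ext_serials):
        raise LinkError(
            f"template {tpl.name}: mapped extension reaches the backbone; "
            "check the linking bond and overlap mapping")
    heavy = [tpl.by_serial(s) for s in sorted(ext_serials)
             if not _is_hydrogen(tpl.by_serial(s))
             and not _is_pseudo(tpl.by_serial(s))]
    unmapped = [r.name for r in heavy
                if r.name not in mapped_ext and r.type_code != DUMMY_TYPE]
    if unmapped:
        raise LinkError(
            f"template {tpl.name}: extension atoms left unmapped: {unmapped}")
    if not ext_serials:
        raise LinkError(
            f"template {tpl.name}: no extension beyond the linking bond; "
            "templates must extend at least one atom past it")
    if link.serial not in {n for s in ext_serials for n in adj[s]}:
        raise LinkError(
            f"template {tpl.name}: mapped extension is not bonded to the "
            f"linking atom {linking_atom}")
    return [tpl.by_serial(s) for s in sorted(ext_serials)]


def link_templates(spec: LinkSpec, limit: float = DEFAULT_LIMIT,
                   weight: float = DEFAULT_WEIGHT,
                   restrain_hydrogens: bool = False,
                   link_dialect: str = "link") -> LinkResult:
    """Produce link-ready templates, overlap restraints and a link statement.

    In each template every atom beyond the linking bond, together with the
    hydrogens attached to those atoms, is retyped ``DUMMY`` (``PSEUDO``
    atoms are never altered); nothing else about the templates changes.
    One upper-distance restraint of ``limit`` (default 0.04 A) and
    ``weight`` (default 10) is generated per mapped overlap pair, tying the
    extension copy to the real atom it duplicates in the partner template.
    Hydrogens retyped along with their heavy atom get restraints only if
    ``restrain_hydrogens`` is set.
    """
    tpl_a = copy.deepcopy(spec.template_a)
    tpl_b = copy.deepcopy(spec.template_b)
    name_a, name_b = spec.linking_bond
    tpl_a.atom(name_a)
    tpl_b.atom(name_b)

    sides = {
        "a": (tpl_a, name_a, spec.res_index_a),
        "b": (tpl_b, name_b, spec.res_index_b),
    }
    registry: List[DummyAtom] = []
    restraints: List[UplRestraint] = []

    for side in ("a", "b"):
        tpl, link_name, res_idx = sides[side]
        mapped = {p.ext_atom for p in spec.overlap_pairs if p.ext_side == side}
        ext = _extension_atoms(tpl, link_name, mapped)
        adj = tpl.adjacency()
        ext_serials = {r.serial for r in ext}
        to_retype = list(ext)
        for rec in ext:
            for nbr in adj[rec.serial]:
                nrec = tpl.by_serial(nbr)
                if _is_hydrogen(nrec) and nbr not in ext_serials:
                    to_retype.append(nrec)
        for rec in to_retype:
            if _is_pseudo(rec):
                continue
            if rec.type_code != DUMMY_TYPE:
                rec.set_type(DUMMY_TYPE)
            registry.append(DummyAtom(res_idx, tpl.name, rec.name))

    for pair in spec.overlap_pairs:
        ext_tpl, _, ext_idx = sides[pair.ext_side]
        other = "b" if pair.ext_side == "a" else "a"
        real_tpl, _, real_idx = sides[other]
        real_rec = real_tpl.atom(pair.real_atom)
        ext_rec = ext_tpl.atom(pair.ext_atom)
        if _is_hydrogen(ext_rec) and not restrain_hydrogens:
            continue
        restraints.append(UplRestraint(
            res_i=ext_idx, resname_i=ext_tpl.name, atom_i=ext_rec.name,
            res_j=real_idx, resname_j=real_tpl.name, atom_j=real_rec.name,
            limit=limit, weight=weight))

    statement = LinkStatement(atom_i=name_a, res_i=spec.res_index_a,
                              atom_j=name_b, res_j=spec.res_index_b,
                              dialect=link_dialect)
    logger.info("linked %s(%d)-%s(%d): %d restraints, %d DUMMY atoms",
                tpl_a.name, spec.res_index_a, tpl_b.name, spec.res_index_b,
                len(restraints), len(registry))
    return LinkResult(template_a=tpl_a, template_b=tpl_b,
                      restraints=restraints, statement=statement,
                      dummy_registry=registry)


# ---------------------------------------------------------------------------
# post-calculation finalisation
# ---------------------------------------------------------------------------

def finalize_structure(pdb_text: str, registry: Sequence[DummyAtom] = (),
                       rename: Optional[Dict[str, str]] = None) -> str:
    """Strip DUMMY atoms from calculated models and restore residue names.

    ``pdb_text`` holds one or more models; every atom matching a registry
    entry (residue index + atom name) is deleted from every model, residue
    codes are rewritten per ``rename`` (e.g. ``{"CYSX": "CYS"}``), and atom
    serials are repacked.  With an empty registry and no renames the input
    text is returned byte-identical.
    """
    rename = rename or {}
    if not registry and not rename:
        return pdb_text
    targets = {(r.res_index, r.atom_name) for r in registry}
    hits = {t: 0 for t in targets}
    out_lines: List[str] = []
    serial = 0
    for line in pdb_text.splitlines(keepends=True):
        rec = line[:6]
        if rec in ("MODEL ", "MODEL"):
            serial = 0
        if rec in ("ATOM  ", "HETATM"):
            atom_name = line[12:16].strip()
            resname = line[17:21].strip()
            try:
                res_index = int(line[22:26])
            except ValueError:
                raise LinkError(f"unparsable residue number in: {line!r}")
            key = (res_index, atom_name)
            if key in targets:
                hits[key] += 1
                continue
            serial += 1
            new_res = rename.get(resname, resname)
            line = (line[:6] + f"{serial:5d}" + line[11:17]
                    + f"{new_res:<4.4s}" + line[21:])
        elif rec == "TER   " or line.rstrip("\n") == "TER":
            serial += 1
            if len(line) >= 26:
                resname = line[17:21].strip()
                new_res = rename.get(resname, resname)
                line = (line[:6] + f"{serial:5d}" + line[11:17]
                        + f"{new_res:<4.4s}" + line[21:])
        out_lines.append(line)
    missing = sorted(k for k, n in hits.items() if n == 0)
    if missing:
        raise LinkError(
            f"registry references atoms absent from the models: {missing}")
    return "".join(out_lines)
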