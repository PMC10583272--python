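"""Recognition of capped submission templates and excision of the residue
of interest.

A group X is parameterised inside a capped peptide so its chemical
environment is realistic: Ace-Ala-X-Ala-NMe for an internal residue,
X-Ala-NMe for an N-terminal one, Ace-Ala-X for a C-terminal one (Ace =
acetyl cap, NMe = N-methyl amide cap, Ala = flanking alanine).  This
module identifies which construct a molecule is, splits it at the backbone
peptide bonds, and excises X as a standalone residue with IUPAC-named
atoms ready for component output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .chemgraph import (
    Backbone,
    BackboneNotFoundError,
    ChemGraphError,
    MolecularGraph,
    heavy_atom_subgraph,
)
from . import namer as _namer

__all__ = [
    "TemplateClassification",
    "classify_template",
    "ExcisedResidue",
    "excise_residue",
    "TemplateError",
]


class TemplateError(ChemGraphError):
    pass


@dataclass
class TemplateClassification:
    """Result of matching a molecule against the capped-template forms."""

    kind: str  # internal | n_terminal | c_terminal | not_template
    #: cap/flank label -> heavy+H serial set (labels: ace, nme, ala1, ala2)
    cap_atoms: Dict[str, Set[int]] = field(default_factory=dict)
    x_atoms: Set[int] = field(default_factory=set)

    @property
    def all_cap_serials(self) -> Set[int]:
        out: Set[int] = set()
        for s in self.cap_atoms.values():
            out |= s
        return out


def _fragment_with_hydrogens(g: MolecularGraph, heavy_frag: Set[int]) -> Set[int]:
    out = set(heavy_frag)
    for s in heavy_frag:
        for nbr in g.neighbors(s):
            if g.atom(nbr).is_hydrogen:
                out.add(nbr)
    return out


def _h_count(g: MolecularGraph, serial: int) -> int:
    return sum(1 for nbr in g.neighbors(serial) if g.atom(nbr).is_hydrogen)


def _carbonyl_carbons(g: MolecularGraph) -> Set[int]:
    """Carbons bearing a terminal or double-bonded oxygen."""
    out = set()
    for a in g.atoms:
        if a.element.upper() != "C":
            continue
        for nbr in g.neighbors(a.serial):
            n = g.atom(nbr)
            if n.element.upper() != "O":
                continue
            bond = g.bond_between(a.serial, nbr)
            if bond.order in (2, "2", "ar", 1.5) or g.degree(nbr) == 1:
                out.add(a.serial)
                break
    return out


def _peptide_bonds(heavy: MolecularGraph) -> List[Tuple[int, int]]:
    """Backbone amide bonds as (carbonyl C, amide N) pairs.

    A cuttable amide requires the nitrogen to continue into another heavy
    atom, which leaves primary side-chain amides (Asn, Gln) intact.
    """
    carbonyls = _carbonyl_carbons(heavy)
    cuts = []
    for c in sorted(carbonyls):
        for nbr in heavy.neighbors(c):
            n = heavy.atom(nbr)
            if n.element.upper() != "N":
                continue
            if heavy.bond_between(c, nbr).order not in (1, "1"):
                continue
            onward = [s for s in heavy.neighbors(nbr) if s != c]
            if onward:
                cuts.append((c, nbr))
    return cuts


def _fragments(heavy: MolecularGraph,
               cuts: Sequence[Tuple[int, int]]) -> List[Set[int]]:
    cut_set = {frozenset(c) for c in cuts}
    comp: Dict[int, int] = {}
    frags: List[Set[int]] = []
    for a in heavy.atoms:
        if a.serial in comp:
            continue
        members = {a.serial}
        stack = [a.serial]
        while stack:
            cur = stack.pop()
            for nbr in heavy.neighbors(cur):
                if frozenset((cur, nbr)) in cut_set or nbr in members:
                    continue
                members.add(nbr)
                stack.append(nbr)
        for s in members:
            comp[s] = len(frags)
        frags.append(members)
    return frags


def _is_ace(heavy: MolecularGraph, g: MolecularGraph, frag: Set[int]) -> bool:
    if len(frag) != 3:
        return False
    elements = sorted(heavy.atom(s).element.upper() for s in frag)
    if elements != ["C", "C", "O"]:
        return False
    methyls = [s for s in frag if heavy.atom(s).element.upper() == "C"
               and _h_count(g, s) == 3]
    return len(methyls) == 1


def _is_nme(heavy: MolecularGraph, g: MolecularGraph, frag: Set[int]) -> bool:
    if len(frag) != 2:
        return False
    elements = sorted(heavy.atom(s).element.upper() for s in frag)
    if elements != ["C", "N"]:
        return False
    c = next(s for s in frag if heavy.atom(s).element.upper() == "C")
    return _h_count(g, c) == 3


def _frag_backbone(heavy: MolecularGraph, frag: Set[int]) -> Optional[Backbone]:
    """Backbone motif N-CA-C(=O) restricted to one fragment; either
    alpha-carbon stereochemistry accepted."""
    carbonyls = _carbonyl_carbons(heavy) & frag
    for ca in sorted(frag):
        atom = heavy.atom(ca)
        if atom.element.upper() != "C" or ca in carbonyls:
            continue
        nbrs = [s for s in heavy.neighbors(ca) if s in frag]
        ns = [s for s in nbrs if heavy.atom(s).element.upper() == "N"]
        cs = [s for s in nbrs if s in carbonyls]
        if not ns or not cs:
            continue
        c = cs[0]
        oxys = [s for s in heavy.neighbors(c)
                if heavy.atom(s).element.upper() == "O"]
        return Backbone(n=ns[0], ca=ca, c=c, o=sorted(oxys)[0])
    return None


def _is_ala(heavy: MolecularGraph, g: MolecularGraph, frag: Set[int]) -> bool:
    if len(frag) != 5:
        return False
    bb = _frag_backbone(heavy, frag)
    if bb is None:
        return False
    side = frag - {bb.n, bb.ca, bb.c} - {
        s for s in heavy.neighbors(bb.c) if heavy.atom(s).element.upper() == "O"}
    if len(side) != 1:
        return False
    cb = next(iter(side))
    return (heavy.atom(cb).element.upper() == "C"
            and _h_count(g, cb) == 3
            and cb in heavy.neighbors(bb.ca))


def classify_template(g: MolecularGraph) -> TemplateClassification:
    """Match a molecule against the capped-template constructs.

    Splits the molecule at backbone amide bonds and checks the resulting
    fragment chain against the three accepted forms.  Molecules without a
    peptide bond are ``not_template``; a fragment chain that has peptide
    bonds but fits none of the forms (for instance two candidate residues
    of interest) is an error.
    """
    heavy = heavy_atom_subgraph(g)
    cuts = _peptide_bonds(heavy)
    if not cuts:
        return TemplateClassification(kind="not_template")
    frags = _fragments(heavy, cuts)
    frag_of = {s: i for i, frag in enumerate(frags) for s in frag}
    # order fragments along the chain, N-to-C: carbonyl side precedes amide side
    order_edges = [(frag_of[c], frag_of[n]) for c, n in cuts]
    succ: Dict[int, int] = {}
    pred: Dict[int, int] = {}
    for a, b in order_edges:
        if a in succ or b in pred or a == b:
            raise TemplateError("branched or cyclic peptide-bond pattern; "
                                "not a linear capped template")
        succ[a] = b
        pred[b] = a
    starts = [i for i in range(len(frags)) if i not in pred]
    if len(starts) != 1:
        raise TemplateError("disconnected fragments; not a single peptide chain")
    chain = [starts[0]]
    while chain[-1] in succ:
        chain.append(succ[chain[-1]])
    if len(chain) != len(frags):
        raise TemplateError("peptide-bond pattern is not a single linear chain")
    seq = [frags[i] for i in chain]

    def build(kind: str, labels_frags: Dict[str, Set[int]],
              x_frag: Set[int]) -> TemplateClassification:
        bb = _frag_backbone(heavy, x_frag)
        if bb is None:
            raise TemplateError("candidate residue of interest lacks a "
                                "backbone motif")
        caps = {lab: _fragment_with_hydrogens(g, f)
                for lab, f in labels_frags.items()}
        return TemplateClassification(
            kind=kind, cap_atoms=caps,
            x_atoms=_fragment_with_hydrogens(g, x_frag))

    if (len(seq) == 5 and _is_ace(heavy, g, seq[0])
            and _is_ala(heavy, g, seq[1]) and _is_ala(heavy, g, seq[3])
            and _is_nme(heavy, g, seq[4])):
        return build("internal", {"ace": seq[0], "ala1": seq[1],
                                  "ala2": seq[3], "nme": seq[4]}, seq[2])
    if (len(seq) == 3 and _is_ala(heavy, g, seq[1])
            and _is_nme(heavy, g, seq[2]) and not _is_ace(heavy, g, seq[0])):
        return build("n_terminal", {"ala1": seq[1], "nme": seq[2]}, seq[0])
    if (len(seq) == 3 and _is_ace(heavy, g, seq[0])
            and _is_ala(heavy, g, seq[1]) and not _is_nme(heavy, g, seq[2])):
        return build("c_terminal", {"ace": seq[0], "ala1": seq[1]}, seq[2])
    residue_like = [i for i, f in enumerate(seq)
                    if _frag_backbone(heavy, f) is not None
                    and not _is_ala(heavy, g, f)]
    if len(residue_like) > 1:
        raise TemplateError(
            f"ambiguous template: {len(residue_like)} candidate residues of "
            "interest")
    return TemplateClassification(kind="not_template")


@dataclass
class ExcisedResidue:
    """The excised group of interest, renamed and ready for output."""

    graph: MolecularGraph
    naming: _namer.NamingResult
    #: serials (in the excised graph) whose peptide bonds were severed
    attachment_points: List[int]


def excise_residue(g: MolecularGraph, cls: TemplateClassification,
                   **rename_kwargs) -> ExcisedResidue:
    """Cut the classified residue of interest out of its capped template.

    The returned graph keeps the input coordinates; backbone atoms are
    named N, H, CA, HA, C, O (terminal variants keep their terminal
    groups), the side chain is named by the naming algorithm, and the
    backbone atoms that lost a peptide bond are listed as attachment
    points.
    """
    if cls.kind == "not_template":
        raise TemplateError("cannot excise from a non-template molecule")
    sub = g.subgraph(cls.x_atoms)
    naming = _namer.rename(sub, **rename_kwargs)
    renamed = naming.apply(sub)
    attach = []
    for s in cls.x_atoms:
        outside = [t for t in g.neighbors(s) if t not in cls.x_atoms]
        if outside:
            attach.append(s)
    return ExcisedResidue(graph=renamed, naming=naming,
                          attachment_points=sorted(attach))
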