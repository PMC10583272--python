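"""CNS building-block patching for non-canonical residues.

To stay compatible with the standard CNS protein force field, a new
residue keeps the standard atom types, charges and parameters for the
backbone atoms involved in the stock linkage statements (N, HN, CA, HA,
CB, O), while every other atom receives a fresh type name carrying its own
geometry and charges.  Because splicing standard backbone charges into an
independently derived charge set breaks neutrality, the residual charge is
folded into the non-backbone atom with the largest charge magnitude.

The retained-backbone list deliberately omits the carbonyl carbon; pass
``retain_c=True`` to keep it standard as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

__all__ = [
    "TopologyAtom",
    "BondedTerm",
    "ResidueTopology",
    "CnsBuildingBlock",
    "build_cns_patch",
    "resolve_type_clashes",
    "topology_text",
    "parameter_text",
    "CnsPatchError",
    "BACKBONE_ATOMS",
]

#: Backbone atoms whose standard types/charges are retained.
BACKBONE_ATOMS = ("N", "HN", "CA", "HA", "CB", "O")

CHARGE_TOL = 1e-6


class CnsPatchError(ValueError):
    pass


@dataclass(frozen=True)
class TopologyAtom:
    name: str
    type_name: str
    charge: float


@dataclass(frozen=True)
class BondedTerm:
    """One bonded term (bond / angle / dihedral / improper) over atom names,
    with optional force-field parameters."""

    kind: str
    atoms: Tuple[str, ...]
    params: Tuple[float, ...] = ()

    _ARITY = {"bond": 2, "angle": 3, "dihedral": 4, "improper": 4}

    def __post_init__(self):
        if self.kind not in self._ARITY:
            raise CnsPatchError(f"unknown term kind {self.kind!r}")
        if len(self.atoms) != self._ARITY[self.kind]:
            raise CnsPatchError(
                f"{self.kind} needs {self._ARITY[self.kind]} atoms, "
                f"got {self.atoms}")


@dataclass
class ResidueTopology:
    """Simple residue topology: atoms with types and charges, bonded terms,
    and per-type non-bonded parameters."""

    name: str
    atoms: List[TopologyAtom]
    terms: List[BondedTerm] = field(default_factory=list)
    #: type name -> non-bonded parameters (e.g. epsilon, sigma)
    type_params: Dict[str, Tuple[float, ...]] = field(default_factory=dict)

    def atom(self, name: str) -> TopologyAtom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise CnsPatchError(f"residue {self.name}: no atom {name!r}")


@dataclass
class CnsBuildingBlock:
    """A patched residue ready for CNS topology/parameter output."""

    name: str
    atoms: List[TopologyAtom]
    terms: List[BondedTerm]
    type_params: Dict[str, Tuple[float, ...]]
    retained_backbone: Set[str]
    net_charge: float
    audit: List[str] = field(default_factory=list)

    def total_charge(self) -> float:
        return sum(a.charge for a in self.atoms)


def _fresh_type(resname: str, index: int) -> str:
    # CNS type names are short; two residue letters + 2-digit counter
    return f"{resname[:2].upper()}{index:02d}"


def build_cns_patch(topology: ResidueTopology,
                    backbone_charges: Mapping[str, Tuple[str, float]],
                    net_charge: float,
                    retain_c: bool = False,
                    allow_missing_backbone: bool = False) -> CnsBuildingBlock:
    """Patch a residue topology into a CNS-compatible building block.

    ``backbone_charges`` maps each retained backbone atom name to its
    standard (type, charge) pair.  Backbone atoms keep those values; every
    other atom gets a fresh residue-scoped type name.  The residual
    ``net_charge - (sum of standard backbone charges + sum of input
    non-backbone charges)`` is added to the non-backbone atom of largest
    charge magnitude (ties broken by atom-name order).  Residues with a
    modified backbone can pass ``allow_missing_backbone=True`` to retain
    whatever subset of the standard names they do carry.
    """
    retained_names = list(BACKBONE_ATOMS) + (["C"] if retain_c else [])
    present = {a.name for a in topology.atoms}
    missing = [n for n in retained_names if n not in present]
    if missing and not allow_missing_backbone:
        raise CnsPatchError(
            f"residue {topology.name}: missing backbone atoms {missing} "
            "(modified backbones need allow_missing_backbone and manual "
            "linkage statements)")
    retained = [n for n in retained_names if n in present]
    for n in retained:
        if n not in backbone_charges:
            raise CnsPatchError(f"no standard type/charge supplied for {n}")

    audit: List[str] = []
    new_atoms: List[TopologyAtom] = []
    type_map: Dict[str, str] = {}
    type_params: Dict[str, Tuple[float, ...]] = {}
    counter = 1
    for a in topology.atoms:
        if a.name in retained:
            std_type, std_q = backbone_charges[a.name]
            new_atoms.append(TopologyAtom(a.name, std_type, std_q))
        else:
            if a.type_name not in type_map:
                type_map[a.type_name] = _fresh_type(topology.name, counter)
                counter += 1
                if a.type_name in topology.type_params:
                    type_params[type_map[a.type_name]] = \
                        topology.type_params[a.type_name]
            new_atoms.append(replace(a, type_name=type_map[a.type_name]))
    if type_map:
        audit.append(f"new types: {type_map}")

    non_backbone = [i for i, a in enumerate(new_atoms)
                    if a.name not in retained]
    backbone_sum = sum(new_atoms[i].charge for i in range(len(new_atoms))
                       if i not in non_backbone)
    side_sum = sum(new_atoms[i].charge for i in non_backbone)
    residual = net_charge - (backbone_sum + side_sum)
    if abs(residual) > CHARGE_TOL:
        if not non_backbone:
            raise CnsPatchError(
                f"residue {topology.name}: residual charge {residual:+.4f} e "
                "but no non-backbone atom to absorb it")
        absorber = min(
            non_backbone,
            key=lambda i: (-abs(new_atoms[i].charge), new_atoms[i].name))
        a = new_atoms[absorber]
        new_atoms[absorber] = replace(a, charge=a.charge + residual)
        audit.append(
            f"residual {residual:+.4f} e added to {a.name} "
            f"({a.charge:+.4f} -> {new_atoms[absorber].charge:+.4f})")

    block = CnsBuildingBlock(
        name=topology.name, atoms=new_atoms, terms=list(topology.terms),
        type_params=type_params, retained_backbone=set(retained),
        net_charge=net_charge, audit=audit)
    if abs(block.total_charge() - net_charge) > CHARGE_TOL:
        raise CnsPatchError(
            f"charge bookkeeping failed: {block.total_charge():.6f} != "
            f"{net_charge:.6f}")
    return block


def resolve_type_clashes(
        blocks: Sequence[CnsBuildingBlock],
) -> Tuple[List[CnsBuildingBlock], List[Tuple[str, str, str]]]:
    """Make type names unique across independently generated blocks.

    Identical type names with identical parameters are merged silently;
    a name reused with different parameters is renamed in the later block
    by a deterministic letter suffix.  Returns the rewritten blocks and a
    report of ``(block name, old type, new type)`` renames.  Numeric
    parameters are never altered.
    """
    seen: Dict[str, Tuple[float, ...]] = {}
    taken: Set[str] = set()
    report: List[Tuple[str, str, str]] = []
    out: List[CnsBuildingBlock] = []
    for block in blocks:
        rename: Dict[str, str] = {}
        block_types = sorted({a.type_name for a in block.atoms}
                             | set(block.type_params))
        for tname in block_types:
            params = block.type_params.get(tname)
            if tname not in seen and tname not in taken:
                seen[tname] = params
                taken.add(tname)
                continue
            if seen.get(tname) == params:
                continue  # parameter-identical duplicate: merge silently
            suffix = 0
            new = tname
            while new in taken or new in seen:
                new = f"{tname}{chr(ord('A') + suffix)}"
                suffix += 1
            rename[tname] = new
            seen[new] = params
            taken.add(new)
            report.append((block.name, tname, new))
        if not rename:
            out.append(block)
            continue
        new_atoms = [replace(a, type_name=rename.get(a.type_name, a.type_name))
                     for a in block.atoms]
        new_params = {rename.get(t, t): p for t, p in block.type_params.items()}
        out.append(replace_block(block, new_atoms, new_params))
    return out, report


def replace_block(block: CnsBuildingBlock, atoms, type_params) -> CnsBuildingBlock:
    return CnsBuildingBlock(
        name=block.name, atoms=atoms, terms=block.terms,
        type_params=type_params, retained_backbone=block.retained_backbone,
        net_charge=block.net_charge, audit=list(block.audit))


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def topology_text(block: CnsBuildingBlock) -> str:
    """CNS-style RESIdue topology block."""
    lines = [f"RESIdue {block.name}", "GROUP"]
    for a in block.atoms:
        lines.append(
            f"  ATOM {a.name:<4s} TYPE={a.type_name:<4s} "
            f"CHARge={a.charge:+.4f} END")
    kw = {"bond": "BOND", "angle": "ANGLe", "dihedral": "DIHEdral",
          "improper": "IMPRoper"}
    for term in block.terms:
        lines.append(f"  {kw[term.kind]} " + " ".join(
            f"{n:<4s}" for n in term.atoms))
    lines.append("END")
    return "\n".join(lines) + "\n"


def parameter_text(block: CnsBuildingBlock) -> str:
    """Parameter statements for the block's new atom types and any bonded
    terms that carry explicit parameters."""
    lines = [f"! parameters for residue {block.name}"]
    types = {a.name: a.type_name for a in block.atoms}
    kw = {"bond": "BOND", "angle": "ANGLe", "dihedral": "DIHEdral",
          "improper": "IMPRoper"}
    for term in block.terms:
        if not term.params:
            continue
        tnames = " ".join(f"{types.get(n, n):<4s}" for n in term.atoms)
        pvals = " ".join(f"{v:g}" for v in term.params)
        lines.append(f"{kw[term.kind]} {tnames} {pvals}")
    for tname, params in sorted(block.type_params.items()):
        pvals = " ".join(f"{v:g}" for v in params)
        lines.append(f"NONBonded {tname:<4s} {pvals}")
    return "\n".join(lines) + "\n"
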