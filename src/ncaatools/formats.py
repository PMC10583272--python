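"""Readers and writers for the file dialects the pipeline touches.

Covers structures with explicit connectivity (PDB with CONECT, Mol2),
CYANA residue-library entries (.lib), upper-distance-limit restraints
(.upl), sequence-file link statements, and CCD-style chemical-component
CIF blocks.  Library entries round-trip byte-faithfully: every record
keeps its raw line and only an explicit type-code substitution rewrites
anything.

The .lib dialect is the CYLIB-style layout::

    RESIDUE   CYS     2    11    1    11
         1 CHI1     0    0   1.0000    2    5    6    7
         ...
         1 N     N_AMI     0.0000  -1.2000   0.0000     0    2
         2 CA    C_ALI     0.0000   0.0000   0.0000     1    3    5

An atom record is serial, name, type code, x, y, z, then the serials it is
bonded to; a ``PSEUDO`` type code marks pseudoatoms.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import gemmi

from .chemgraph import Atom, Bond, MolecularGraph, ChemGraphError

__all__ = [
    "read_structure",
    "write_pdb",
    "ResidueTemplate",
    "TemplateAtom",
    "read_lib",
    "write_lib",
    "UplRestraint",
    "write_upl",
    "read_upl",
    "LinkStatement",
    "write_link_statement",
    "write_component_cif",
    "FormatError",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# structures: PDB (CONECT) and Mol2
# ---------------------------------------------------------------------------

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3}


def _check_hydrogens(g: MolecularGraph) -> None:
    """Warn (and flag the graph) when heavy-atom valences suggest missing H."""
    suspicious = []
    for a in g.atoms:
        if a.is_hydrogen:
            continue
        want = _VALENCE.get(a.element.upper())
        if want is not None and g.degree(a.serial) < want - 1:
            suspicious.append(a.name or str(a.serial))
    g.missing_hydrogens = bool(suspicious)  # type: ignore[attr-defined]
    if suspicious:
        logger.warning(
            "input appears to lack explicit hydrogens (undercoordinated: %s); "
            "all hydrogens must be present for naming and linking",
            ", ".join(suspicious[:8]))


def _read_pdb(path: Path) -> MolecularGraph:
    st = gemmi.read_pdb(str(path))
    if not st.conect_map:
        raise FormatError(
            f"{path}: no connectivity (PDB input requires CONECT records)")
    g = MolecularGraph()
    st.setup_entities()
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                el = atom.element.name.upper() or atom.name.strip()[0]
                g.add_atom(Atom(atom.serial, atom.name.strip(), el,
                                (atom.pos.x, atom.pos.y, atom.pos.z)))
    seen = set()
    for a, nbrs in st.conect_map.items():
        for b in nbrs:
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            if a in g and b in g:
                g.add_bond(Bond(key[0], key[1], 1))
    _check_hydrogens(g)
    return g


_MOL2_ORDERS = {"1": 1, "2": 2, "3": 3, "ar": "ar", "am": 1, "du": 1}


def _read_mol2(path: Path) -> MolecularGraph:
    section = None
    g = MolecularGraph()
    n_bonds = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[9:].strip().upper()
            continue
        if not line or line.startswith("#") or section is None:
            continue
        if section == "ATOM":
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: short ATOM record")
            serial, name = int(parts[0]), parts[1]
            x, y, z = (float(v) for v in parts[2:5])
            element = parts[5].split(".")[0].upper()
            charge = float(parts[8]) if len(parts) > 8 else None
            g.add_atom(Atom(serial, name, element, (x, y, z), charge=charge))
        elif section == "BOND":
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: short BOND record")
            order = _MOL2_ORDERS.get(parts[3].lower())
            if order is None:
                raise FormatError(
                    f"{path}:{lineno}: unknown bond type {parts[3]!r}")
            g.add_bond(Bond(int(parts[1]), int(parts[2]), order))
            n_bonds += 1
    if len(g) == 0:
        raise FormatError(f"{path}: no ATOM section found")
    if n_bonds == 0:
        raise FormatError(f"{path}: no connectivity (BOND section empty)")
    _check_hydrogens(g)
    return g


def read_structure(path: Union[str, Path], format: Optional[str] = None) -> MolecularGraph:
    """Read a small-molecule/peptide structure with explicit bonds.

    ``format`` is ``"pdb"`` or ``"mol2"``; inferred from the suffix when
    omitted.  PDB bond orders default to single (CONECT carries no order);
    Mol2 orders are taken from the bond table.  Inputs without connectivity
    are a hard error; inputs that appear to lack hydrogens are flagged via
    ``graph.missing_hydrogens`` and a logged warning.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "mol2":
        return _read_mol2(path)
    raise FormatError(f"unsupported structure format {fmt!r}")


def write_pdb(g: MolecularGraph, path: Union[str, Path],
              resname: str = "UNK", resseq: int = 1) -> None:
    """Write a single-residue graph as PDB with CONECT records."""
    lines = []
    for a in g.atoms:
        x, y, z = a.coords
        name = a.name[:4]
        pad = name if len(name) == 4 else f" {name:<3s}"
        lines.append(
            f"HETATM{a.serial:5d} {pad} {resname:<3s} A{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
            f"{a.element.upper():>2s}")
    for b in g.bonds:
        lines.append(f"CONECT{b.a:5d}{b.b:5d}")
        lines.append(f"CONECT{b.b:5d}{b.a:5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CYANA residue library (.lib)
# ---------------------------------------------------------------------------

@dataclass
class TemplateAtom:
    """One atom record of a library entry, with its raw line preserved."""

    serial: int
    name: str
    type_code: str
    coords: Tuple[float, float, float]
    bonded: List[int]
    raw: str
    #: (start, end) character span of the type-code token inside ``raw``
    _type_span: Tuple[int, int] = (0, 0)

    @property
    def is_pseudo(self) -> bool:
        return self.type_code.upper() == "PSEUDO"

    def set_type(self, new_type: str) -> None:
        """Substitute the type code, padding so later columns keep their
        positions whenever the new code is not longer than the field."""
        start, end = self._type_span
        width = max(end - start, len(new_type))
        self.raw = self.raw[:start] + f"{new_type:<{width}}" + self.raw[end:]
        self.type_code = new_type
        m = _atom_line_re(self.raw)
        if m:
            self._type_span = m.span("type")


@dataclass
class ResidueTemplate:
    """A parsed CYANA library entry; untouched entries re-serialise to the
    exact input bytes."""

    name: str
    header_counts: List[int]
    angle_records: List[List[str]]
    atom_records: List[TemplateAtom]
    header_raw: str = ""
    angle_raws: List[str] = field(default_factory=list)
    prefix_lines: List[str] = field(default_factory=list)

    def atom(self, name: str) -> TemplateAtom:
        for rec in self.atom_records:
            if rec.name == name:
                return rec
        raise FormatError(f"template {self.name}: no atom named {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(rec.name == name for rec in self.atom_records)

    def adjacency(self) -> Dict[int, List[int]]:
        """Symmetric bonded-serial adjacency over the entry's atoms."""
        adj: Dict[int, List[int]] = {rec.serial: [] for rec in self.atom_records}
        for rec in self.atom_records:
            for b in rec.bonded:
                if b == 0:
                    continue
                if b not in adj:
                    raise FormatError(
                        f"template {self.name}: atom {rec.name} bonded to "
                        f"unknown serial {b}")
                if b not in adj[rec.serial]:
                    adj[rec.serial].append(b)
                if rec.serial not in adj[b]:
                    adj[b].append(rec.serial)
        return adj

    def by_serial(self, serial: int) -> TemplateAtom:
        for rec in self.atom_records:
            if rec.serial == serial:
                return rec
        raise FormatError(f"template {self.name}: no atom serial {serial}")

    def lines(self) -> List[str]:
        return (self.prefix_lines + [self.header_raw] + self.angle_raws
                + [rec.raw for rec in self.atom_records])


_ATOM_RE = re.compile(
    r"^\s*(?P<serial>\d+)\s+(?P<name>\S+)\s+(?P<type>\S+)\s+"
    r"(?P<x>-?\d+\.\d+)\s+(?P<y>-?\d+\.\d+)\s+(?P<z>-?\d+\.\d+)"
    r"(?P<rest>(?:\s+-?\d+)*)\s*$")


def _atom_line_re(line: str):
    return _ATOM_RE.match(line)


def read_lib(path: Union[str, Path]) -> List[ResidueTemplate]:
    """Parse a CYANA residue-library file into template entries."""
    path = Path(path)
    lines = path.read_text().splitlines()
    templates: List[ResidueTemplate] = []
    prefix: List[str] = []
    i = 0
    while i < len(lines):
        line = lines[i]
        if not line.strip().startswith("RESIDUE"):
            prefix.append(line)
            i += 1
            continue
        parts = line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{i + 1}: malformed RESIDUE header")
        name = parts[1]
        try:
            counts = [int(p) for p in parts[2:]]
        except ValueError:
            raise FormatError(f"{path}:{i + 1}: non-integer header count")
        n_angles, n_atoms = counts[0], counts[1]
        tpl = ResidueTemplate(name=name, header_counts=counts,
                              angle_records=[], atom_records=[],
                              header_raw=line, prefix_lines=prefix)
        prefix = []
        i += 1
        for _ in range(n_angles):
            if i >= len(lines):
                raise FormatError(
                    f"{path}:{i}: truncated entry {name} (angle records)")
            tpl.angle_raws.append(lines[i])
            tpl.angle_records.append(lines[i].split())
            i += 1
        for _ in range(n_atoms):
            if i >= len(lines):
                raise FormatError(
                    f"{path}:{i}: truncated entry {name} (atom records)")
            m = _atom_line_re(lines[i])
            if not m:
                raise FormatError(
                    f"{path}:{i + 1}: malformed atom record: {lines[i]!r}")
            rec = TemplateAtom(
                serial=int(m.group("serial")),
                name=m.group("name"),
                type_code=m.group("type"),
                coords=(float(m.group("x")), float(m.group("y")),
                        float(m.group("z"))),
                bonded=[int(v) for v in m.group("rest").split()],
                raw=lines[i],
                _type_span=m.span("type"),
            )
            tpl.atom_records.append(rec)
            i += 1
        names = [r.name for r in tpl.atom_records]
        if len(names) != len(set(names)):
            raise FormatError(f"{path}: duplicate atom names in {name}")
        tpl.adjacency()  # validates bonded serials
        templates.append(tpl)
    if not templates:
        raise FormatError(f"{path}: no RESIDUE entries found")
    templates[-1].trailing = prefix  # type: ignore[attr-defined]
    return templates


def write_lib(templates: Sequence[ResidueTemplate], path: Union[str, Path]) -> None:
    out: List[str] = []
    for tpl in templates:
        out.extend(tpl.lines())
        out.extend(getattr(tpl, "trailing", []))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# restraints and link statements
# ---------------------------------------------------------------------------

@dataclass
class UplRestraint:
    """One upper-distance-limit restraint between two named atoms."""

    res_i: int
    resname_i: str
    atom_i: str
    res_j: int
    resname_j: str
    atom_j: str
    limit: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.limit <= 0:
            raise FormatError("upper distance limit must be larger than 0")
        if self.weight <= 0:
            raise FormatError("restraint weight must be positive")


def write_upl(restraints: Sequence[UplRestraint], path: Union[str, Path],
              weight_style: str = "column") -> None:
    """Write .upl restraints with fixed-width columns.

    ``weight_style`` selects how the weight is encoded: ``"column"`` (bare
    trailing numeric column, the default) or ``"option"`` (a trailing
    ``weight := W`` clause).
    """
    lines = []
    for r in restraints:
        base = (f"{r.res_i:4d} {r.resname_i:<5s} {r.atom_i:<5s} "
                f"{r.res_j:4d} {r.resname_j:<5s} {r.atom_j:<5s} "
                f"{r.limit:8.2f}")
        if weight_style == "column":
            lines.append(base + f" {r.weight:8.2f}")
        elif weight_style == "option":
            lines.append(base + f"  weight := {r.weight:g}")
        else:
            raise FormatError(f"unknown weight style {weight_style!r}")
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_upl(path: Union[str, Path]) -> List[UplRestraint]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise FormatError(f"{path}:{lineno}: short restraint line")
        weight = 1.0
        if len(parts) >= 8:
            weight = float(parts[9]) if parts[7] == "weight" else float(parts[7])
        out.append(UplRestraint(
            int(parts[0]), parts[1], parts[2],
            int(parts[3]), parts[4], parts[5],
            float(parts[6]), weight))
    return out


@dataclass
class LinkStatement:
    """Sequence-file directive removing the repulsion between the two
    linking-bond atoms."""

    atom_i: str
    res_i: int
    atom_j: str
    res_j: int
    dialect: str = "link"

    def render(self) -> str:
        if self.dialect == "link":
            return f"link {self.atom_i} {self.res_i} {self.atom_j} {self.res_j}"
        raise FormatError(f"unknown link-statement dialect {self.dialect!r}")


def write_link_statement(stmt: LinkStatement, path: Union[str, Path]) -> None:
    Path(path).write_text(stmt.render() + "\n")


# ---------------------------------------------------------------------------
# CCD-style component CIF
# ---------------------------------------------------------------------------

def write_component_cif(g: MolecularGraph, path: Union[str, Path],
                        comp_id: str = "UNK") -> None:
    """Write a chemical-component block (atom + bond tables) for an excised
    residue whose atoms have all been named (backbone as N, CA, C, O)."""
    unnamed = [a.serial for a in g.atoms if not a.name]
    if unnamed:
        raise FormatError(f"unnamed atoms: {unnamed}")
    for key in ("N", "CA", "C", "O"):
        if not any(a.name == key for a in g.atoms):
            raise FormatError(f"missing backbone atom {key}")
    doc = gemmi.cif.Document()
    block = doc.add_new_block(f"comp_{comp_id}")
    block.set_pair("_chem_comp.id", comp_id)
    block.set_pair("_chem_comp.type", "L-PEPTIDE LINKING")
    atom_loop = block.init_loop("_chem_comp_atom.", [
        "comp_id", "atom_id", "type_symbol",
        "model_Cartn_x", "model_Cartn_y", "model_Cartn_z"])
    for a in g.atoms:
        x, y, z = a.coords
        atom_loop.add_row([comp_id, a.name, a.element.upper(),
                           f"{x:.3f}", f"{y:.3f}", f"{z:.3f}"])
    order_names = {1: "SING", 2: "DOUB", 3: "TRIP", "ar": "AROM"}
    bond_loop = block.init_loop("_chem_comp_bond.", [
        "comp_id", "atom_id_1", "atom_id_2", "value_order"])
    for b in g.bonds:
        bond_loop.add_row([comp_id, g.atom(b.a).name, g.atom(b.b).name,
                           order_names.get(b.order, "SING")])
    doc.write_file(str(path))
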