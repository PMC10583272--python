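"""Molecular-graph data model and the graph primitives shared by the pipeline.

Molecules are plain graphs of :class:`Atom` records connected by explicit
:class:`Bond` records.  All downstream algorithms (side-chain naming,
template recognition, library linking) operate on this representation;
nothing here perceives bonds or aromaticity from coordinates — connectivity
must be explicit in the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "DUPLICATE_ELEMENT",
    "ATOMIC_NUMBERS",
    "atomic_number",
    "heavy_atom_subgraph",
    "expand_unsaturation",
    "bond_distances",
    "chirality_sign",
    "find_backbone",
    "Backbone",
    "ChemGraphError",
    "DegenerateGeometryError",
    "BackboneNotFoundError",
]

#: Element marker used for CIP phantom duplicate atoms.
DUPLICATE_ELEMENT = "DU"

# Periodic table subset covering everything a peptide template can carry.
ATOMIC_NUMBERS: Dict[str, int] = {
    "H": 1, "D": 1, "HE": 2,
    "LI": 3, "BE": 4, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "NE": 10,
    "NA": 11, "MG": 12, "AL": 13, "SI": 14, "P": 15, "S": 16, "CL": 17,
    "AR": 18, "K": 19, "CA": 20, "FE": 26, "ZN": 30, "SE": 34, "BR": 35,
    "I": 53,
}


class ChemGraphError(ValueError):
    """Base error for molecular-graph operations."""


class DegenerateGeometryError(ChemGraphError):
    """Raised when four points are too close to coplanar/collinear to orient."""


class BackboneNotFoundError(ChemGraphError):
    """Raised when no (or no unambiguous) amino-acid backbone motif is found."""


def atomic_number(element: str) -> int:
    """Atomic number of ``element``; duplicate markers count as 0."""
    el = element.strip().upper()
    if el == DUPLICATE_ELEMENT:
        return 0
    try:
        return ATOMIC_NUMBERS[el]
    except KeyError:
        raise ChemGraphError(f"unknown element symbol: {element!r}") from None


@dataclass
class Atom:
    """A single atom.

    ``serial`` is the stable identity used throughout the pipeline; atom
    names are mutable labels (the naming algorithm rewrites them).
    ``is_duplicate`` marks CIP phantom atoms introduced to represent
    unsaturated bonds; such atoms always have exactly one bond.
    """

    serial: int
    name: str
    element: str
    coords: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    is_pseudo: bool = False
    is_duplicate: bool = False
    charge: Optional[float] = None

    @property
    def atomic_number(self) -> int:
        return atomic_number(self.element)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.strip().upper() in ("H", "D")


@dataclass(frozen=True)
class Bond:
    """Undirected bond between two atom serials.

    ``order`` is 1, 2, 3 or the string ``"ar"`` for aromatic bonds.
    """

    a: int
    b: int
    order: object = 1

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ChemGraphError(f"self-bond on serial {self.a}")

    @property
    def key(self) -> Tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class Backbone:
    """Serials of the amino-acid backbone atoms of one residue."""

    n: int
    ca: int
    c: int
    o: int


class MolecularGraph:
    """Atoms plus explicit bonds; the substrate of every algorithm here."""

    def __init__(self, atoms: Iterable[Atom] = (), bonds: Iterable[Bond] = (),
                 net_charge: Optional[int] = None):
        self._atoms: Dict[int, Atom] = {}
        self._adj: Dict[int, Dict[int, Bond]] = {}
        self.net_charge = net_charge
        for atom in atoms:
            self.add_atom(atom)
        for bond in bonds:
            self.add_bond(bond)

    # -- construction -------------------------------------------------

    def add_atom(self, atom: Atom) -> Atom:
        if atom.serial in self._atoms:
            raise ChemGraphError(f"duplicate atom serial {atom.serial}")
        if atom.serial <= 0:
            raise ChemGraphError(f"atom serial must be positive, got {atom.serial}")
        atomic_number(atom.element)  # validate symbol
        self._atoms[atom.serial] = atom
        self._adj[atom.serial] = {}
        return atom

    def add_bond(self, bond: Bond) -> Bond:
        for s in (bond.a, bond.b):
            if s not in self._atoms:
                raise ChemGraphError(f"bond references unknown serial {s}")
        if bond.b in self._adj[bond.a]:
            raise ChemGraphError(f"duplicate bond {bond.a}-{bond.b}")
        self._adj[bond.a][bond.b] = bond
        self._adj[bond.b][bond.a] = bond
        return bond

    def new_serial(self) -> int:
        return max(self._atoms, default=0) + 1

    # -- queries -------------------------------------------------------

    def __contains__(self, serial: int) -> bool:
        return serial in self._atoms

    def __len__(self) -> int:
        return len(self._atoms)

    @property
    def atoms(self) -> List[Atom]:
        return [self._atoms[s] for s in sorted(self._atoms)]

    @property
    def bonds(self) -> List[Bond]:
        seen = {}
        for nbrs in self._adj.values():
            for bond in nbrs.values():
                seen[bond.key] = bond
        return [seen[k] for k in sorted(seen)]

    def atom(self, serial: int) -> Atom:
        try:
            return self._atoms[serial]
        except KeyError:
            raise ChemGraphError(f"no atom with serial {serial}") from None

    def atom_by_name(self, name: str) -> Atom:
        hits = [a for a in self._atoms.values() if a.name == name]
        if len(hits) != 1:
            raise ChemGraphError(
                f"atom name {name!r} matches {len(hits)} atoms (need exactly 1)")
        return hits[0]

    def neighbors(self, serial: int) -> List[int]:
        self.atom(serial)
        return sorted(self._adj[serial])

    def bond_between(self, a: int, b: int) -> Optional[Bond]:
        return self._adj.get(a, {}).get(b)

    def degree(self, serial: int) -> int:
        return len(self._adj[serial])

    def coords(self, serial: int) -> np.ndarray:
        return np.asarray(self.atom(serial).coords, dtype=float)

    def copy(self) -> "MolecularGraph":
        return MolecularGraph(
            (replace(a) for a in self.atoms), self.bonds, self.net_charge)

    def subgraph(self, serials: Iterable[int]) -> "MolecularGraph":
        """Induced subgraph on ``serials``; original serials preserved."""
        keep = set(serials)
        atoms = [replace(self._atoms[s]) for s in sorted(keep)]
        bonds = [b for b in self.bonds if b.a in keep and b.b in keep]
        return MolecularGraph(atoms, bonds, self.net_charge)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.serial, atom=a)
        for b in self.bonds:
            g.add_edge(b.a, b.b, order=b.order)
        return g

    def validate(self) -> None:
        """Check structural invariants (H degree 1, duplicate degree 1)."""
        for a in self.atoms:
            if a.is_duplicate and self.degree(a.serial) != 1:
                raise ChemGraphError(
                    f"duplicate atom {a.serial} has degree {self.degree(a.serial)}")
            if a.is_hydrogen and not a.is_duplicate and self.degree(a.serial) > 1:
                raise ChemGraphError(
                    f"hydrogen {a.serial} ({a.name}) has degree > 1")


# ---------------------------------------------------------------------------
# graph primitives
# ---------------------------------------------------------------------------

def heavy_atom_subgraph(g: MolecularGraph) -> MolecularGraph:
    """Reduce ``g`` to its heavy (non-hydrogen, non-pseudo) atoms.

    Bonds among the retained atoms survive with their orders; serials are
    preserved so results map straight back onto the parent graph.
    """
    keep = [a.serial for a in g.atoms
            if not a.is_hydrogen and not a.is_pseudo]
    return g.subgraph(keep)


def expand_unsaturation(g: MolecularGraph) -> MolecularGraph:
    """Add CIP phantom duplicate atoms representing unsaturated bonds.

    For every bond of order ``k`` in {2, 3} each end atom gains ``k - 1``
    leaf duplicates carrying the element of the atom across the bond.
    Aromatic systems are handled Kekule-free: every atom incident to at
    least one aromatic bond gains exactly one duplicate of its own element
    (order 1.5 per bond; symmetric, so graph-equivalent ring branches stay
    equivalent).  Original atoms and bonds are untouched.
    """
    out = g.copy()

    def add_dup(end: int, element: str) -> None:
        serial = out.new_serial()
        dup = Atom(serial=serial, name=f"DU{serial}", element=element,
                   coords=g.atom(end).coords, is_duplicate=True)
        out.add_atom(dup)
        out.add_bond(Bond(end, serial, 1))

    aromatic_atoms = set()
    for bond in g.bonds:
        order = bond.order
        if order in (1, "1"):
            continue
        if order in ("ar", "aromatic", 1.5):
            aromatic_atoms.update((bond.a, bond.b))
            continue
        if order in (2, "2"):
            extra = 1
        elif order in (3, "3"):
            extra = 2
        else:
            raise ChemGraphError(
                f"unknown bond order {order!r} on bond {bond.a}-{bond.b}")
        for _ in range(extra):
            add_dup(bond.a, g.atom(bond.b).element)
            add_dup(bond.b, g.atom(bond.a).element)
    for s in sorted(aromatic_atoms):
        add_dup(s, g.atom(s).element)
    return out


def bond_distances(g: MolecularGraph, source: int) -> Dict[int, int]:
    """Shortest path length in bonds from ``source`` to every reachable atom."""
    g.atom(source)
    return dict(nx.single_source_shortest_path_length(g.to_networkx(), source))


def chirality_sign(p_high: Sequence[float], p_low: Sequence[float],
                   center: Sequence[float], anchor: Sequence[float],
                   rel_tol: float = 1e-9) -> int:
    """Handedness of two substituents around a centre, as a determinant sign.

    The 4x4 determinant of homogeneous coordinates with rows ordered
    ``(p_high, p_low, center, anchor)`` — the candidate pair on top, the
    central atom filling the third row and the highest-priority substituent
    (the atom on the path back to the alpha carbon) at the bottom — is
    positive for one arrangement and negative for its mirror image.  Which
    arrangement is "clockwise" is a pure convention; what matters is that
    swapping the pair, or reflecting all coordinates, flips the sign.

    Raises :class:`DegenerateGeometryError` when the four points are
    coplanar within ``rel_tol`` relative to the spread of the points.
    """
    pts = np.array([p_high, p_low, center, anchor], dtype=float)
    m = np.hstack([pts, np.ones((4, 1))])
    det = float(np.linalg.det(m))
    # scale reference: product of the three edge vectors from the centre
    edges = [np.linalg.norm(pts[i] - pts[2]) for i in (0, 1, 3)]
    scale = math.prod(edges) or 1.0
    if abs(det) < rel_tol * scale:
        raise DegenerateGeometryError(
            f"near-planar arrangement, |det|={abs(det):.3e} below tolerance")
    return 1 if det > 0 else -1


def _motif_backbones(g: MolecularGraph) -> List[Backbone]:
    """All N-CA-C(=O) motifs found by pure connectivity."""
    found = []
    for ca in g.atoms:
        if ca.element.upper() != "C" or ca.is_duplicate:
            continue
        nbrs = g.neighbors(ca.serial)
        n_cands = [s for s in nbrs if g.atom(s).element.upper() == "N"]
        c_cands = []
        for s in nbrs:
            if g.atom(s).element.upper() != "C":
                continue
            # carbonyl carbon: bears an oxygen
            oxys = [t for t in g.neighbors(s)
                    if g.atom(t).element.upper() == "O"]
            if oxys:
                c_cands.append((s, oxys))
        # alpha carbon carries at least one H in an all-H input, but the
        # heavy-only motif (N, C', O) is what identifies it
        for n in n_cands:
            for c, oxys in c_cands:
                # prefer a double-bonded/terminal O for the carbonyl slot
                o = None
                for t in sorted(oxys):
                    b = g.bond_between(c, t)
                    if b is not None and b.order in (2, "2", "ar", 1.5):
                        o = t
                        break
                if o is None:
                    term = [t for t in sorted(oxys) if g.degree(t) == 1]
                    o = term[0] if term else sorted(oxys)[0]
                found.append(Backbone(n=n, ca=ca.serial, c=c, o=o))
    return found


def find_backbone(g: MolecularGraph, residue_hint: Optional[int] = None) -> Backbone:
    """Locate the amino-acid backbone N, CA, C, O of a single residue.

    Name-based lookup ("N"/"CA"/"C"/"O" all present) takes precedence since
    library and CCD inputs carry reliable names; otherwise the
    N-C(alpha)-C(=O) motif is matched on connectivity alone.
    ``residue_hint`` selects the motif whose CA has that serial when several
    candidates exist.
    """
    names = {a.name: a.serial for a in g.atoms}
    if all(k in names for k in ("N", "CA", "C", "O")):
        counts = {k: sum(1 for a in g.atoms if a.name == k)
                  for k in ("N", "CA", "C", "O")}
        if all(v == 1 for v in counts.values()):
            return Backbone(n=names["N"], ca=names["CA"],
                            c=names["C"], o=names["O"])
    motifs = _motif_backbones(g)
    if residue_hint is not None:
        motifs = [m for m in motifs if m.ca == residue_hint]
    if not motifs:
        raise BackboneNotFoundError("no backbone motif (N-CA-C=O) found")
    if len(motifs) > 1:
        cas = sorted({m.ca for m in motifs})
        if len(cas) > 1:
            raise BackboneNotFoundError(
                f"ambiguous backbone: candidate alpha carbons {cas}; "
                "pass residue_hint to select one")
        motifs = [m for m in motifs if m.ca == cas[0]]
    return motifs[0]
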