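"""Programmatic generation of every test input used by the package.

All molecules are built from internal coordinates (ideal tetrahedral /
trigonal angles and a small element-pair bond-length table), so the package
needs no chemistry toolkit and no downloaded data.  The geometry is
idealised, not energy-minimised: it exists to make connectivity explicit
and to give stereocentres a well-defined handedness, which is all the
naming and linking algorithms consume.  Ring closures that the tree
embedder cannot close geometrically (proline) still carry the closing bond;
only local geometry around tetrahedral centres matters downstream.

Recipes cover the 20 canonical residues plus ornithine and
alpha-aminobutyrate, capped peptide templates (Ace-Ala-X-Ala-NMe and the
terminal forms), an extended-cysteine disulfide template, branched and
fused-ring toys, and seeded random side chains.
"""

from __future__ import annotations

import math
import random
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..chemgraph import Atom, Bond, MolecularGraph

__all__ = [
    "Mol",
    "residue",
    "capped_template",
    "toy",
    "random_side_chain",
    "mirror",
    "permute_serials",
    "CANONICAL_RESIDUES",
    "reference_side_chain_names",
    "NAMING_DEVIATIONS",
]

# -- geometry tables --------------------------------------------------------

_BOND_LENGTHS = {
    frozenset(("C",)): 1.52,
    frozenset(("C", "N")): 1.46,
    frozenset(("C", "O")): 1.41,
    frozenset(("C", "S")): 1.81,
    frozenset(("S",)): 2.05,
    frozenset(("N",)): 1.40,
    frozenset(("N", "O")): 1.36,
    frozenset(("O",)): 1.45,
    frozenset(("C", "H")): 1.09,
    frozenset(("N", "H")): 1.01,
    frozenset(("O", "H")): 0.96,
    frozenset(("S", "H")): 1.34,
    frozenset(("C", "CL")): 1.77,
    frozenset(("C", "BR")): 1.94,
    frozenset(("C", "F")): 1.35,
}

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "H": 1,
            "CL": 1, "BR": 1, "F": 1, "I": 1, "SE": 2}

_TET = math.acos(-1.0 / 3.0)  # 109.47 deg


def _bond_length(el_a: str, el_b: str, order=1) -> float:
    base = _BOND_LENGTHS.get(frozenset((el_a.upper(), el_b.upper())), 1.50)
    if order in (2, "2"):
        base -= 0.13
    elif order in (3, "3"):
        base -= 0.22
    elif order in ("ar", 1.5):
        base -= 0.09
    return base


def _perp(a: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, ref)
    if np.linalg.norm(v) < 1e-6:
        v = np.cross(a, np.array([1.0, 0.0, 0.0]))
    return v / np.linalg.norm(v)


def _fan(axis: np.ndarray, angle: float, azimuths: Sequence[float]) -> List[np.ndarray]:
    """Unit vectors at ``angle`` from ``-axis`` fanned around the axis."""
    a = axis / np.linalg.norm(axis)
    e1 = _perp(a)
    e2 = np.cross(a, e1)
    out = []
    for phi in azimuths:
        d = (math.cos(angle) * (-a)
             + math.sin(angle) * (math.cos(phi) * e1 + math.sin(phi) * e2))
        out.append(d / np.linalg.norm(d))
    return out


class Mol:
    """Incremental molecule builder with idealised internal-coordinate
    placement.  ``grow`` appends one atom bonded to an existing one, taking
    the parent's next free direction slot, which makes stereochemistry a
    deterministic function of growth order."""

    def __init__(self):
        self.g = MolecularGraph()
        self._frames: Dict[int, dict] = {}
        self._explicit_h: Dict[int, int] = {}
        self._order_sum: Dict[int, float] = {}

    # -- core placement ------------------------------------------------

    def _register(self, serial: int, pos: np.ndarray, axis: np.ndarray,
                  geometry: str) -> None:
        if geometry == "sp3":
            slots = _fan(axis, _TET, [0.0, 2 * math.pi / 3, 4 * math.pi / 3])
        elif geometry == "sp2":
            slots = _fan(axis, math.radians(120.0), [0.0, math.pi])
        elif geometry == "root":
            t = 1.0 / math.sqrt(3.0)
            slots = [np.array(v) * t for v in
                     [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]]
        else:
            raise ValueError(f"unknown geometry {geometry!r}")
        self._frames[serial] = {"pos": pos, "axis": axis, "slots": slots}

    def _take_slot(self, serial: int) -> np.ndarray:
        fr = self._frames[serial]
        if not fr["slots"]:
            # fall back: opposite the growth axis (over-coordinated input)
            return -fr["axis"] / np.linalg.norm(fr["axis"])
        return fr["slots"].pop(0)

    def root(self, element: str, name: str = "", h: Optional[int] = None) -> int:
        serial = self.g.new_serial()
        self.g.add_atom(Atom(serial, name or f"{element}{serial}", element,
                             (0.0, 0.0, 0.0)))
        self._register(serial, np.zeros(3), np.array([0.0, 0.0, 1.0]), "root")
        self._order_sum[serial] = 0.0
        if h is not None:
            self._explicit_h[serial] = h
        return serial

    def grow(self, parent: int, element: str, name: str = "", order=1,
             geometry: str = "sp3", h: Optional[int] = None) -> int:
        d = self._take_slot(parent)
        ppos = self._frames[parent]["pos"]
        pos = ppos + d * _bond_length(self.g.atom(parent).element, element, order)
        serial = self.g.new_serial()
        self.g.add_atom(Atom(serial, name or f"{element}{serial}", element,
                             tuple(pos)))
        self.g.add_bond(Bond(parent, serial, order))
        onum = {1: 1.0, 2: 2.0, 3: 3.0, "ar": 1.5}.get(order, 1.0)
        self._order_sum[parent] = self._order_sum.get(parent, 0) + onum
        self._order_sum[serial] = onum
        self._register(serial, pos, d, geometry)
        if h is not None:
            self._explicit_h[serial] = h
        return serial

    def bond(self, a: int, b: int, order=1) -> None:
        self.g.add_bond(Bond(a, b, order))
        onum = {1: 1.0, 2: 2.0, 3: 3.0, "ar": 1.5}.get(order, 1.0)
        self._order_sum[a] = self._order_sum.get(a, 0) + onum
        self._order_sum[b] = self._order_sum.get(b, 0) + onum

    def ring(self, parent: int, spec: Sequence[Tuple[str, str, Optional[int]]],
             order="ar", bond_len: float = 1.39) -> List[int]:
        """Grow a planar regular ring; ``spec`` lists (element, name, h) for
        each vertex, the first vertex bonding to ``parent``."""
        n = len(spec)
        d = self._take_slot(parent)
        ppos = self._frames[parent]["pos"]
        el0 = spec[0][0]
        p1 = ppos + d * _bond_length(self.g.atom(parent).element, el0)
        radius = bond_len / (2.0 * math.sin(math.pi / n))
        center = p1 + d * radius
        f1 = -d
        normal = np.cross(d, _perp(d))
        normal /= np.linalg.norm(normal)
        f2 = np.cross(normal, f1)
        serials = []
        for k, (el, name, h) in enumerate(spec):
            theta = 2.0 * math.pi * k / n
            pos = center + radius * (math.cos(theta) * f1 + math.sin(theta) * f2)
            serial = self.g.new_serial()
            self.g.add_atom(Atom(serial, name or f"{el}{serial}", el, tuple(pos)))
            self._order_sum[serial] = 0.0
            radial = (pos - center)
            radial /= np.linalg.norm(radial)
            self._frames[serial] = {
                "pos": pos, "axis": radial, "slots": [radial],
                "ring_center": center, "ring_normal": normal,
            }
            if h is not None:
                self._explicit_h[serial] = h
            serials.append(serial)
        self.bond(parent, serials[0], 1)
        for i in range(n):
            self.bond(serials[i], serials[(i + 1) % n], order)
        return serials

    def fused_ring(self, a: int, b: int,
                   spec: Sequence[Tuple[str, str, Optional[int]]],
                   order="ar", bond_len: float = 1.39) -> List[int]:
        """Fuse a new ring onto the existing bonded ring atoms ``a``-``b``;
        ``spec`` lists the new vertices walking from ``b``'s side to ``a``'s."""
        n = len(spec) + 2
        fa, fb = self._frames[a], self._frames[b]
        c1 = fa["ring_center"]
        normal = fa["ring_normal"]
        mid = (fa["pos"] + fb["pos"]) / 2.0
        out = mid - c1
        out /= np.linalg.norm(out)
        apothem = bond_len / (2.0 * math.tan(math.pi / n))
        radius = bond_len / (2.0 * math.sin(math.pi / n))
        c2 = mid + out * apothem
        u = fb["pos"] - c2
        u /= np.linalg.norm(u)
        v = np.cross(normal, u)
        # walk from b around the new ring away from a
        vb = fb["pos"] - c2
        va = fa["pos"] - c2
        sign = 1.0 if np.dot(np.cross(vb, va), normal) > 0 else -1.0
        serials = []
        for k, (el, name, h) in enumerate(spec, start=1):
            theta = sign * 2.0 * math.pi * k / n
            pos = c2 + radius * (math.cos(theta) * u + math.sin(theta) * v)
            serial = self.g.new_serial()
            self.g.add_atom(Atom(serial, name or f"{el}{serial}", el, tuple(pos)))
            self._order_sum[serial] = 0.0
            radial = pos - c2
            radial /= np.linalg.norm(radial)
            self._frames[serial] = {
                "pos": pos, "axis": radial, "slots": [radial],
                "ring_center": c2, "ring_normal": normal,
            }
            if h is not None:
                self._explicit_h[serial] = h
            serials.append(serial)
        chain = [b] + serials + [a]
        for x, y in zip(chain, chain[1:]):
            self.bond(x, y, order)
        return serials

    def add_hydrogens(self) -> None:
        """Fill every heavy atom's remaining valence with hydrogens."""
        for atom in list(self.g.atoms):
            if atom.is_hydrogen:
                continue
            el = atom.element.upper()
            want = self._explicit_h.get(atom.serial)
            if want is None:
                want = _VALENCE.get(el, 4) - int(round(
                    self._order_sum.get(atom.serial, 0)))
            for _ in range(max(0, want)):
                d = self._take_slot(atom.serial)
                pos = self._frames[atom.serial]["pos"] + d * _bond_length(el, "H")
                serial = self.g.new_serial()
                self.g.add_atom(Atom(serial, f"H{serial}", "H", tuple(pos)))
                self.g.add_bond(Bond(atom.serial, serial, 1))


# ---------------------------------------------------------------------------
# residue recipes
# ---------------------------------------------------------------------------

def _ring6(mol: Mol, parent: int, prefix: str = "", names=None, h_last=1):
    names = names or ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    hs = [0, 1, 1, h_last, 1, 1]
    spec = [("C", prefix + nm, hh) for nm, hh in zip(names, hs)]
    return mol.ring(parent, spec)


def _build_side_chain(mol: Mol, code: str, ca: int, n: int) -> None:
    code = code.upper()
    if code == "GLY":
        return
    if code == "PRO":
        cb = mol.grow(ca, "C", "CB")
        cg = mol.grow(cb, "C", "CG")
        cd = mol.grow(cg, "C", "CD")
        mol.bond(cd, n)
        return
    cb = mol.grow(ca, "C", "CB")
    if code == "ALA":
        return
    if code == "SER":
        mol.grow(cb, "O", "OG")
    elif code == "CYS":
        mol.grow(cb, "S", "SG")
    elif code == "THR":
        mol.grow(cb, "O", "OG1")
        mol.grow(cb, "C", "CG2")
    elif code == "VAL":
        mol.grow(cb, "C", "CG1")
        mol.grow(cb, "C", "CG2")
    elif code == "LEU":
        cg = mol.grow(cb, "C", "CG")
        mol.grow(cg, "C", "CD1")
        mol.grow(cg, "C", "CD2")
    elif code == "ILE":
        cg1 = mol.grow(cb, "C", "CG1")
        mol.grow(cb, "C", "CG2")
        mol.grow(cg1, "C", "CD1")
    elif code == "MET":
        cg = mol.grow(cb, "C", "CG")
        sd = mol.grow(cg, "S", "SD")
        mol.grow(sd, "C", "CE")
    elif code == "ABU":
        mol.grow(cb, "C", "CG")
    elif code in ("LYS", "ORN"):
        cg = mol.grow(cb, "C", "CG")
        cd = mol.grow(cg, "C", "CD")
        if code == "LYS":
            ce = mol.grow(cd, "C", "CE")
            mol.grow(ce, "N", "NZ", h=3)
        else:
            mol.grow(cd, "N", "NE", h=3)
    elif code == "ARG":
        cg = mol.grow(cb, "C", "CG")
        cd = mol.grow(cg, "C", "CD")
        ne = mol.grow(cd, "N", "NE", h=1, geometry="sp2")
        cz = mol.grow(ne, "C", "CZ", geometry="sp2")
        mol.grow(cz, "N", "NH1", order=2, h=1, geometry="sp2")
        mol.grow(cz, "N", "NH2", h=2, geometry="sp2")
    elif code in ("ASP", "ASN", "GLU", "GLN"):
        tip = cb
        letter = "D" if code in ("ASP", "ASN") else "E"
        if code in ("GLU", "GLN"):
            tip = mol.grow(cb, "C", "CG")
        carb = mol.grow(tip, "C", "CG" if letter == "D" else "CD",
                        geometry="sp2")
        mol.grow(carb, "O", f"O{letter}1", order=2)
        if code in ("ASP", "GLU"):
            mol.grow(carb, "O", f"O{letter}2", h=0)
        else:
            mol.grow(carb, "N", f"N{letter}2", h=2, geometry="sp2")
    elif code == "PHE":
        _ring6(mol, cb)
    elif code == "TYR":
        ring = _ring6(mol, cb, h_last=0)
        mol.grow(ring[3], "O", "OH")  # on CZ
    elif code == "HIS":
        spec = [("C", "CG", 0), ("N", "ND1", 0), ("C", "CE1", 1),
                ("N", "NE2", 1), ("C", "CD2", 1)]
        mol.ring(cb, spec)
    elif code == "TRP":
        spec = [("C", "CG", 0), ("C", "CD1", 1), ("N", "NE1", 1),
                ("C", "CE2", 0), ("C", "CD2", 0)]
        ring5 = mol.ring(cb, spec)
        ce2, cd2 = ring5[3], ring5[4]
        mol.fused_ring(cd2, ce2, [("C", "CZ2", 1), ("C", "CH2", 1),
                                  ("C", "CZ3", 1), ("C", "CE3", 1)])
    else:
        raise ValueError(f"unknown residue recipe {code!r}")


CANONICAL_RESIDUES = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

#: Deviations of the literal sole-occupant naming rule from common usage:
#: residue -> {conventional name: name this package emits}.  The delta
#: methyl of isoleucine is the single heavy occupant of its distance shell
#: on chain 1, so the chain number is dropped.
NAMING_DEVIATIONS: Dict[str, Dict[str, str]] = {
    "ILE": {"CD1": "CD"},
}


def residue(code: str, n_h: Optional[int] = None) -> MolecularGraph:
    """A standalone residue with amino and carboxyl termini and all H."""
    code = code.upper()
    mol = Mol()
    n = mol.root("N", "N", h=(1 if code == "PRO" else n_h))
    ca = mol.grow(n, "C", "CA")
    c = mol.grow(ca, "C", "C", geometry="sp2")
    mol.grow(c, "O", "O", order=2)
    mol.grow(c, "O", "OXT")
    _build_side_chain(mol, code, ca, n)
    mol.add_hydrogens()
    mol.g.validate()
    return mol.g


def reference_side_chain_names(code: str) -> List[str]:
    """Conventional heavy side-chain atom names for a residue recipe."""
    g = residue(code)
    bb = {"N", "CA", "C", "O", "OXT"}
    return [a.name for a in g.atoms
            if not a.is_hydrogen and a.name not in bb]


# ---------------------------------------------------------------------------
# capped peptide templates
# ---------------------------------------------------------------------------

def _add_residue(mol: Mol, prev_c: Optional[int], code: str,
                 n_methyl: bool = False) -> Tuple[int, int, int]:
    """Append one residue; returns (n, ca, c).  ``prev_c`` is the carbonyl
    carbon of the preceding residue (None for a free N terminus)."""
    if prev_c is None:
        n = mol.root("N", "N", h=(1 if code == "PRO" else 2))
    else:
        h = 0 if (n_methyl or code == "PRO") else 1
        n = mol.grow(prev_c, "N", "N", h=h, geometry="sp3")
    if n_methyl:
        mol.grow(n, "C", "CN")
    ca = mol.grow(n, "C", "CA")
    c = mol.grow(ca, "C", "C", geometry="sp2")
    mol.grow(c, "O", "O", order=2)
    _build_side_chain(mol, code, ca, n)
    return n, ca, c


def capped_template(x: str = "ORN", kind: str = "internal",
                    n_methyl_x: bool = False) -> MolecularGraph:
    """A capped submission template around the residue of interest ``x``.

    ``kind`` selects the construct: ``internal`` gives Ace-Ala-X-Ala-NMe,
    ``n_terminal`` gives X-Ala-NMe and ``c_terminal`` gives Ace-Ala-X.
    """
    mol = Mol()
    prev_c = None
    if kind in ("internal", "c_terminal"):
        cme = mol.root("C", "CH3")
        prev_c = mol.grow(cme, "C", "C", geometry="sp2")
        mol.grow(prev_c, "O", "O", order=2)
        _, _, prev_c = _add_residue(mol, prev_c, "ALA")
    _, _, prev_c = _add_residue(mol, prev_c, x, n_methyl=n_methyl_x)
    if kind in ("internal", "n_terminal"):
        _, _, prev_c = _add_residue(mol, prev_c, "ALA")
        nme_n = mol.grow(prev_c, "N", "N", h=1)
        mol.grow(nme_n, "C", "CH3")
    else:
        mol.grow(prev_c, "O", "OXT")
    if kind not in ("internal", "n_terminal", "c_terminal"):
        raise ValueError(f"unknown template kind {kind!r}")
    mol.add_hydrogens()
    mol.g.validate()
    return mol.g


# ---------------------------------------------------------------------------
# toys and random molecules
# ---------------------------------------------------------------------------

def toy(name: str) -> MolecularGraph:
    """Small purpose-built molecules for priority-rule corner cases."""
    mol = Mol()
    if name == "o_vs_c_branch":
        # CB branches into -CH2-OH and -CH2-CH3: oxygen branch ranks first
        n = mol.root("N", "N", h=2)
        ca = mol.grow(n, "C", "CA")
        c = mol.grow(ca, "C", "C", geometry="sp2")
        mol.grow(c, "O", "O", order=2)
        mol.grow(c, "O", "OXT")
        cb = mol.grow(ca, "C", "CB")
        c1 = mol.grow(cb, "C", "CG1")
        c2 = mol.grow(cb, "C", "CG2")
        mol.grow(c1, "O", "OD")
        mol.grow(c2, "C", "CD")
    elif name == "twin_rings":
        # a carbon bearing two identical phenyl rings: the symmetry re-pass
        # must hand each ring a consecutive block of chain numbers
        n = mol.root("N", "N", h=2)
        ca = mol.grow(n, "C", "CA")
        c = mol.grow(ca, "C", "C", geometry="sp2")
        mol.grow(c, "O", "O", order=2)
        mol.grow(c, "O", "OXT")
        cb = mol.grow(ca, "C", "CB", h=1)
        _ring6(mol, cb, prefix="a")
        _ring6(mol, cb, prefix="b")
    elif name == "ethanol":
        c1 = mol.root("C", "C1")
        c2 = mol.grow(c1, "C", "C2")
        mol.grow(c2, "O", "O1")
    elif name == "ethene":
        c1 = mol.root("C", "C1")
        mol.grow(c1, "C", "C2", order=2, geometry="sp2")
    elif name == "methane":
        mol.root("C", "C1")
    else:
        raise ValueError(f"unknown toy {name!r}")
    mol.add_hydrogens()
    return mol.g


def random_side_chain(seed: int, max_heavy: int = 25) -> MolecularGraph:
    """A random acyclic side chain grafted on a standard backbone.

    Same seed, same graph.  Elements are drawn from {C, N, O, S} with
    valences respected; all bonds single.  The heavy-atom count (backbone
    included) never exceeds ``max_heavy``.
    """
    rng = random.Random(seed)
    mol = Mol()
    n = mol.root("N", "N", h=2)
    ca = mol.grow(n, "C", "CA")
    c = mol.grow(ca, "C", "C", geometry="sp2")
    mol.grow(c, "O", "O", order=2)
    mol.grow(c, "O", "OXT")
    cb = mol.grow(ca, "C", "CB")
    heavy = 6
    budget = rng.randint(1, max_heavy - heavy)
    growable = [cb]
    free = {cb: 3}
    while budget > 0 and growable:
        parent = rng.choice(growable)
        el = rng.choice(["C", "C", "C", "C", "N", "O", "S"])
        child = mol.grow(parent, el, f"{el}x")
        budget -= 1
        free[parent] -= 1
        if free[parent] <= 0:
            growable.remove(parent)
        slots = {"C": 3, "N": 2, "O": 1, "S": 1}[el]
        if slots > 0 and rng.random() < 0.8:
            free[child] = slots
            growable.append(child)
    mol.add_hydrogens()
    mol.g.validate()
    return mol.g


# ---------------------------------------------------------------------------
# CYANA library fixtures
# ---------------------------------------------------------------------------

def _lib_atom(serial, name, type_code, xyz, bonded):
    x, y, z = xyz
    cols = "".join(f"{b:6d}" for b in bonded)
    return (f"{serial:6d} {name:<5s} {type_code:<6s} "
            f"{x:9.4f} {y:9.4f} {z:9.4f}{cols}")


def cysx_lib_text() -> str:
    """A CYSX-style extended-cysteine library entry.

    The residue carries the real side chain Cb-Sg plus the partner's
    Sg'-Cb' extension (atoms SGX/CBX with hydrogens and a QBX pseudoatom),
    ready for disulfide linking where the same entry serves as both inputs.
    """
    atoms = [
        (1,  "N",    "N_AMI",  (-1.329, 0.858, 0.000),  [2, 3]),
        (2,  "H",    "H_AMI",  (-2.288, 1.022, 0.000),  [1]),
        (3,  "CA",   "C_ALI",  (0.000, 0.000, 0.000),   [1, 4, 5, 15]),
        (4,  "HA",   "H_ALI",  (0.255, -0.510, 0.915),  [3]),
        (5,  "CB",   "C_ALI",  (1.207, 0.872, -0.340),  [3, 6, 7, 8, 9]),
        (6,  "HB2",  "H_ALI",  (1.056, 1.405, -1.268),  [5]),
        (7,  "HB3",  "H_ALI",  (1.376, 1.601, 0.441),   [5]),
        (8,  "QB",   "PSEUDO", (1.216, 1.503, -0.414),  [5]),
        (9,  "SG",   "S_RED",  (2.706, -0.119, -0.473), [5, 10]),
        (10, "SGX",  "S_RED",  (3.962, 1.135, -0.925),  [9, 11]),
        (11, "CBX",  "C_ALI",  (5.461, 0.144, -1.058),  [10, 12, 13, 14]),
        (12, "HBX2", "H_ALI",  (5.612, -0.585, -0.277), [11]),
        (13, "HBX3", "H_ALI",  (5.433, -0.363, -2.010), [11]),
        (14, "QBX",  "PSEUDO", (5.523, -0.474, -1.144), [11]),
        (15, "C",    "C_BYL",  (-0.233, -1.123, -1.006), [3, 16]),
        (16, "O",    "O_BYL",  (-1.339, -1.370, -1.463), [15]),
    ]
    lines = [f"RESIDUE   CYSX    2   {len(atoms)}    1   {len(atoms)}"]
    lines.append(f"{1:6d} CHI1     0    0   1.0000{1:6d}{3:6d}{5:6d}{9:6d}")
    lines.append(f"{2:6d} CHI2     0    0   1.0000{3:6d}{5:6d}{9:6d}{10:6d}")
    lines.extend(_lib_atom(*a) for a in atoms)
    return "\n".join(lines) + "\n"


def vancomycin_link3_lib_text() -> str:
    """Synthetic stand-ins for the two extended templates of the third
    vancomycin side-chain link (residues 5 and 7), built so that the
    published overlap mapping (CG1, CE1, CZ3, CZ4 in residue 5 paired with
    CE5, CE3, CD1, CB in residue 7) validates verbatim.  Heavy atoms only;
    coordinates schematic."""
    five = [
        (1, "N",   "N_AMI", (0.0, 0.0, 0.0),  [2]),
        (2, "CA",  "C_ALI", (1.5, 0.0, 0.0),  [1, 3, 5]),
        (3, "C",   "C_BYL", (2.2, 1.3, 0.0),  [2, 4]),
        (4, "O",   "O_BYL", (1.6, 2.4, 0.0),  [3]),
        (5, "CB",  "C_ALI", (2.2, -1.3, 0.0), [2, 6]),
        (6, "CG1", "C_ARO", (3.7, -1.3, 0.0), [5, 7, 8]),
        (7, "CE1", "C_ARO", (4.4, -2.6, 0.0), [6]),
        (8, "CD1", "C_ARO", (4.4, 0.0, 0.0),  [6, 9]),
        (9, "CZ3", "C_ARO", (5.9, 0.0, 0.0),  [8, 10]),
        (10, "CZ4", "C_ARO", (6.6, 1.3, 0.0), [9]),
    ]
    seven = [
        (1, "N",   "N_AMI", (0.0, 0.0, 0.0),  [2]),
        (2, "CA",  "C_ALI", (1.5, 0.0, 0.0),  [1, 3, 5]),
        (3, "C",   "C_BYL", (2.2, 1.3, 0.0),  [2, 4]),
        (4, "O",   "O_BYL", (1.6, 2.4, 0.0),  [3]),
        (5, "CB",  "C_ALI", (2.2, -1.3, 0.0), [2, 6]),
        (6, "CD1", "C_ARO", (3.7, -1.3, 0.0), [5, 7]),
        (7, "CG3", "C_ARO", (4.4, -2.6, 0.0), [6, 8]),
        (8, "CE5", "C_ARO", (5.9, -2.6, 0.0), [7, 9]),
        (9, "CE3", "C_ARO", (6.6, -3.9, 0.0), [8]),
    ]
    lines = [f"RESIDUE   VR5     0   {len(five)}    1   {len(five)}"]
    lines.extend(_lib_atom(*a) for a in five)
    lines.append(f"RESIDUE   VR7     0   {len(seven)}    1   {len(seven)}")
    lines.extend(_lib_atom(*a) for a in seven)
    return "\n".join(lines) + "\n"


def multi_model_pdb_text(n_models: int = 2) -> str:
    """A small calculated-ensemble stand-in: CYSX residues with three DUMMY
    extension atoms per model, for exercising post-calculation cleanup."""
    lines = []
    atoms = [
        ("N", "CYSX", 3), ("CA", "CYSX", 3), ("SG", "CYSX", 3),
        ("SGX", "CYSX", 3), ("CBX", "CYSX", 3), ("HBX2", "CYSX", 3),
        ("N", "ALA", 4), ("CA", "ALA", 4),
    ]
    for m in range(1, n_models + 1):
        lines.append(f"MODEL {m:8d}")
        serial = 0
        for name, res, seq in atoms:
            serial += 1
            pad = name if len(name) == 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {pad} {res:<4.4s}A{seq:4d}    "
                f"{serial * 1.0:8.3f}{m * 1.0:8.3f}{0.0:8.3f}  1.00  0.00")
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# graph transforms used by property tests
# ---------------------------------------------------------------------------

def mirror(g: MolecularGraph) -> MolecularGraph:
    """Mirror image: x coordinates negated, topology untouched."""
    out = g.copy()
    for a in out.atoms:
        x, y, z = a.coords
        a.coords = (-x, y, z)
    return out


def permute_serials(g: MolecularGraph, seed: int) -> Tuple[MolecularGraph, Dict[int, int]]:
    """Relabel atom serials by a seeded random permutation.

    Returns the permuted graph and the old->new serial mapping.
    """
    rng = random.Random(seed)
    old = [a.serial for a in g.atoms]
    new = old[:]
    rng.shuffle(new)
    mapping = dict(zip(old, new))
    atoms = [Atom(mapping[a.serial], a.name, a.element, a.coords,
                  a.is_pseudo, a.is_duplicate, a.charge) for a in g.atoms]
    bonds = [Bond(mapping[b.a], mapping[b.b], b.order) for b in g.bonds]
    return MolecularGraph(atoms, bonds, g.net_charge), mapping
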