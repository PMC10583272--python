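"""IUPAC-conformant automatic atom naming for amino-acid side chains.

Side-chain heavy atoms are named by their bond distance from the alpha
carbon (a transliterated Greek letter: beta for one bond, gamma for two,
...) plus a chain number distinguishing branches that lie at the same
distance.  Chain numbers follow Cahn-Ingold-Prelog priority: the branch
with the higher CIP rank gets the lower number.  Branches that are
graph-identical are ordered geometrically, by the handedness of the two
candidate atoms around their (tetrahedral) branch point; prochiral
hydrogens are numbered by the same geometric rule.

The pipeline is::

    rename(graph)
      -> heavy_atom_subgraph, drop backbone N/C'/O
      -> expand_unsaturation        (CIP phantom duplicates)
      -> assign_chains              (distances + chain numbers)
      -> name_atoms                 (heavy, hydrogen and pseudo atom names)
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .chemgraph import (
    Atom,
    Backbone,
    ChemGraphError,
    DegenerateGeometryError,
    MolecularGraph,
    bond_distances,
    chirality_sign,
    expand_unsaturation,
    find_backbone,
    heavy_atom_subgraph,
)

__all__ = [
    "GREEK_ROMAN",
    "position_label",
    "label_sequence",
    "distance_for_label",
    "cip_compare",
    "ChainAssignment",
    "assign_chains",
    "NamingResult",
    "name_atoms",
    "rename",
    "NamingError",
]


class NamingError(ChemGraphError):
    """Raised when the naming rules cannot produce a unique name set."""


# ---------------------------------------------------------------------------
# positional labels
# ---------------------------------------------------------------------------

#: Default Greek -> Roman transliteration, alpha through omega.
#: alpha A, beta B, gamma G, delta D, epsilon E, zeta Z, eta H, theta Q,
#: iota I, kappa K, lambda L, mu M, nu V, xi X, omicron O, pi P, rho R,
#: sigma S, tau T, upsilon U, phi F, chi C, psi Y, omega W.
GREEK_ROMAN = "ABGDEZHQIKLMVXOPRSTUFCYW"

#: Number of distinct positions the scheme supports (alpha plus 23 further
#: single letters plus 24*24 two-letter codes).
N_POSITIONS = 600


def position_label(distance: int, table: str = GREEK_ROMAN) -> str:
    """Positional label for a heavy atom ``distance`` bonds from C-alpha.

    Distances 1..23 map to single letters beta..omega.  From distance 24
    (position 25 counting the alpha position) the alphabet repeats as
    two-letter codes alpha-alpha, alpha-beta, ... omega-omega, giving 600
    positions in total.
    """
    if len(table) != 24:
        raise NamingError("transliteration table must have 24 letters")
    if not 1 <= distance <= N_POSITIONS - 1:
        raise NamingError(
            f"distance {distance} outside supported range 1..{N_POSITIONS - 1}")
    if distance < 24:
        return table[distance]
    two = distance - 24
    return table[two // 24] + table[two % 24]


def label_sequence(table: str = GREEK_ROMAN) -> List[str]:
    """The full ordered label sequence, alpha position first (600 labels)."""
    return [table[0]] + [position_label(d, table) for d in range(1, N_POSITIONS)]


def distance_for_label(label: str, table: str = GREEK_ROMAN) -> int:
    """Inverse of :func:`position_label` (0 for the alpha label itself)."""
    if len(label) == 1:
        idx = table.index(label)
        return idx
    if len(label) == 2:
        return 24 + table.index(label[0]) * 24 + table.index(label[1])
    raise NamingError(f"malformed positional label {label!r}")


# ---------------------------------------------------------------------------
# CIP priority comparison on the expanded heavy-atom graph
# ---------------------------------------------------------------------------

_PHANTOM_KEY = (0, ())


def _rank_key(g: MolecularGraph, node: int, parent: Optional[int],
              ancestors: frozenset) -> tuple:
    """Nested rank key of the hierarchical-digraph branch rooted at ``node``.

    Children are the node's neighbours except the atom it was entered from;
    a neighbour that is already an ancestor on the current path closes a
    ring and contributes only a childless duplicate of itself (standard CIP
    digraph semantics).  The key is ``(atomic number, sorted child keys)``
    with children sorted highest-priority first.
    """
    z = g.atom(node).atomic_number
    child_keys = []
    anc = ancestors | {node}
    for nbr in g.neighbors(node):
        if nbr == parent:
            continue
        if nbr in ancestors:
            child_keys.append((g.atom(nbr).atomic_number, ()))
        else:
            child_keys.append(_rank_key(g, nbr, node, anc))
    child_keys.sort(key=functools.cmp_to_key(_cmp_keys), reverse=True)
    return (z, tuple(child_keys))


def _cmp_keys(ka: tuple, kb: tuple) -> int:
    """-1 if ``ka`` ranks below ``kb``, +1 above, 0 if identical."""
    if ka[0] != kb[0]:
        return -1 if ka[0] < kb[0] else 1
    ca, cb = ka[1], kb[1]
    for i in range(max(len(ca), len(cb))):
        xa = ca[i] if i < len(ca) else _PHANTOM_KEY
        xb = cb[i] if i < len(cb) else _PHANTOM_KEY
        r = _cmp_keys(xa, xb)
        if r:
            return r
    return 0


def cip_compare(g: MolecularGraph, a: int, b: int, exclude: int) -> str:
    """Compare two sibling branches by CIP priority.

    ``g`` must be the duplicate-expanded heavy-atom graph; ``exclude`` is
    the shared predecessor (the branch point).  Returns ``"a_first"``,
    ``"b_first"`` or ``"tie"``; a tie means the branches are graph-identical
    and only geometry (or nothing) can distinguish them.
    """
    ka = _rank_key(g, a, exclude, frozenset({exclude}))
    kb = _rank_key(g, b, exclude, frozenset({exclude}))
    r = _cmp_keys(ka, kb)
    return "tie" if r == 0 else ("a_first" if r > 0 else "b_first")


# ---------------------------------------------------------------------------
# chain assignment
# ---------------------------------------------------------------------------

@dataclass
class ChainAssignment:
    """Distances and chain numbers for the side-chain heavy atoms."""

    distance: Dict[int, int] = field(default_factory=dict)
    chain: Dict[int, int] = field(default_factory=dict)
    resolved_by: Dict[int, str] = field(default_factory=dict)
    predecessor: Dict[int, int] = field(default_factory=dict)
    #: 2- or 3-way graph-identical branch groups, (branch atom, members in
    #: resolved priority order, how the tie was resolved)
    tie_groups: List[Tuple[int, Tuple[int, ...], str]] = field(default_factory=list)
    backbone: Optional[Backbone] = None
    audit: List[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return max(self.chain.values(), default=0)

    def shell(self, distance: int) -> List[int]:
        return sorted(s for s, d in self.distance.items() if d == distance)


def _side_chain_graph(g: MolecularGraph, backbone: Backbone) -> MolecularGraph:
    """Heavy-atom graph restricted to C-alpha plus the side chain.

    Backbone N and C' are removed (taking the carbonyl/carboxyl oxygens and
    any N-substituent with them) so that distances are measured through
    side-chain bonds only: a proline delta carbon is three bonds from
    C-alpha, not two bonds via the backbone nitrogen.
    """
    heavy = heavy_atom_subgraph(g)
    drop = {backbone.n, backbone.c}
    trimmed = heavy.subgraph(
        a.serial for a in heavy.atoms if a.serial not in drop)
    dist = bond_distances(trimmed, backbone.ca)
    return trimmed.subgraph(dist)


def _order_siblings(full: MolecularGraph, exp: MolecularGraph,
                    kids: List[int], branch: int, anchor: int,
                    asg: ChainAssignment) -> List[int]:
    """Order sibling branches highest-priority first.

    Graph ties between exactly two branches at a tetrahedral branch atom are
    broken geometrically (handedness around the branch atom relative to the
    ``anchor`` atom on the path back to C-alpha); a planar or three-way tie
    is left in input-serial order and flagged arbitrary.
    """
    keys = {k: _rank_key(exp, k, branch, frozenset({branch})) for k in kids}
    groups: List[List[int]] = []
    for k in sorted(kids):
        for grp in groups:
            if _cmp_keys(keys[grp[0]], keys[k]) == 0:
                grp.append(k)
                break
        else:
            groups.append([k])
    groups.sort(key=functools.cmp_to_key(
        lambda ga, gb: _cmp_keys(keys[ga[0]], keys[gb[0]])), reverse=True)

    ordered: List[int] = []
    for grp in groups:
        if len(grp) == 1:
            ordered.append(grp[0])
            if len(kids) > 1:
                asg.resolved_by.setdefault(grp[0], "sphere-comparison")
            continue
        how = "arbitrary"
        if len(grp) == 2:
            if full.degree(branch) == 4:
                try:
                    sign = chirality_sign(
                        full.coords(grp[0]), full.coords(grp[1]),
                        full.coords(branch), full.coords(anchor))
                    if sign < 0:
                        grp = [grp[1], grp[0]]
                    how = "geometric"
                except DegenerateGeometryError:
                    asg.audit.append(
                        f"degenerate geometry at branch {branch}: "
                        f"tie {grp} left arbitrary")
            else:
                asg.audit.append(
                    f"non-tetrahedral branch {branch}: tie {grp} arbitrary")
        else:
            asg.audit.append(
                f"{len(grp)}-way identical branches at {branch}: arbitrary")
        for k in grp:
            asg.resolved_by[k] = how
        asg.tie_groups.append((branch, tuple(grp), how))
        ordered.extend(grp)
    for k in kids:
        asg.resolved_by.setdefault(k, "atomic-number")
    return ordered


def assign_chains(g: MolecularGraph, backbone: Backbone) -> ChainAssignment:
    """Assign (distance, chain number) to every side-chain heavy atom.

    The assignment sweeps outward shell by shell from C-alpha.  Within each
    shell, parents are visited in order of their own chain number; each
    parent's highest-priority child continues the parent's chain and every
    further child opens a new chain with the next free number.  An atom
    reached twice at the same distance (a ring join) keeps the lower of the
    two chain numbers on offer.  A final re-pass renumbers the chains
    spawned inside graph-identical sibling branches so that, e.g., two
    identical rings carry consecutive chain numbers instead of interleaved
    ones.
    """
    asg = ChainAssignment(backbone=backbone)
    heavy_all = heavy_atom_subgraph(g)
    reachable = set(bond_distances(heavy_all, backbone.ca))
    stray = {a.serial for a in heavy_all.atoms} - reachable
    if stray:
        raise NamingError(
            f"side-chain atoms unreachable from C-alpha: {sorted(stray)}")
    side = _side_chain_graph(g, backbone)
    ca = backbone.ca
    dist = bond_distances(side, ca)
    side_serials = {a.serial for a in side.atoms} - {ca}
    for s in side_serials:
        asg.distance[s] = dist[s]
    if not side_serials:
        return asg

    exp = expand_unsaturation(side)
    max_d = max(asg.distance.values())
    created_at: Dict[int, int] = {}
    next_chain = 1

    # shell 1: branches off C-alpha; the geometric anchor is the backbone N
    kids = [s for s in side.neighbors(ca) if s in side_serials]
    ordered = _order_siblings(g, exp, kids, ca, backbone.n, asg)
    for k in ordered:
        asg.chain[k] = next_chain
        created_at[next_chain] = k
        asg.predecessor[k] = ca
        next_chain += 1

    for d in range(2, max_d + 1):
        parents = sorted(asg.shell(d - 1), key=lambda s: asg.chain[s])
        for parent in parents:
            kids = [s for s in side.neighbors(parent)
                    if asg.distance.get(s) == d]
            if not kids:
                continue
            anchor = asg.predecessor[parent]
            ordered = _order_siblings(g, exp, kids, parent, anchor, asg)
            for i, k in enumerate(ordered):
                proposed_new = i > 0
                if k in asg.chain:
                    # ring join: keep the lower number on offer
                    offer = asg.chain[parent] if not proposed_new else None
                    if offer is not None and offer < asg.chain[k]:
                        asg.audit.append(
                            f"ring join at {k}: chain {asg.chain[k]} -> {offer}")
                        asg.chain[k] = offer
                        asg.predecessor[k] = parent
                    asg.resolved_by[k] = "ring-join"
                    continue
                if not proposed_new:
                    asg.chain[k] = asg.chain[parent]
                else:
                    asg.chain[k] = next_chain
                    created_at[next_chain] = k
                    next_chain += 1
                asg.predecessor[k] = parent

    _compact_chains(asg, created_at)
    _symmetry_repass(asg, created_at)
    return asg


def _compact_chains(asg: ChainAssignment, created_at: Dict[int, int]) -> None:
    """Renumber chains to a gap-free 1..K keeping their relative order."""
    used = sorted(set(asg.chain.values()))
    remap = {old: i + 1 for i, old in enumerate(used)}
    if all(k == v for k, v in remap.items()):
        return
    for s in asg.chain:
        asg.chain[s] = remap[asg.chain[s]]
    for old in list(created_at):
        atom = created_at.pop(old)
        if old in remap:
            created_at[remap[old]] = atom


def _subtree(asg: ChainAssignment, root: int) -> set:
    """Atoms whose predecessor path runs through ``root`` (incl. root)."""
    members = {root}
    changed = True
    while changed:
        changed = False
        for s, p in asg.predecessor.items():
            if p in members and s not in members:
                members.add(s)
                changed = True
    return members


def _symmetry_repass(asg: ChainAssignment, created_at: Dict[int, int]) -> None:
    """Give identical sibling branches blocks of consecutive chain numbers.

    Chains first opened inside the subtrees of graph-identical branches are
    pooled and re-dealt branch by branch in the branches' resolved priority
    order, so a duplicated ring never ends up holding chain numbers
    interleaved with its twin's.
    """
    for branch, members, _how in sorted(
            asg.tie_groups, key=lambda t: asg.distance.get(t[1][0], 0)):
        per_member: List[List[int]] = []
        for m in members:
            sub = _subtree(asg, m)
            chains = sorted(c for c, at in created_at.items() if at in sub)
            per_member.append(chains)
        pool = sorted(c for chains in per_member for c in chains)
        if not pool:
            continue
        remap = {}
        i = 0
        for chains in per_member:
            for c in chains:
                remap[c] = pool[i]
                i += 1
        if all(k == v for k, v in remap.items()):
            continue
        asg.audit.append(f"symmetry re-pass at branch {branch}: {remap}")
        for s in asg.chain:
            if asg.chain[s] in remap:
                asg.chain[s] = remap[asg.chain[s]]
        moved = {remap[c]: created_at[c] for c in remap}
        for c, at in moved.items():
            created_at[c] = at


# ---------------------------------------------------------------------------
# name generation
# ---------------------------------------------------------------------------

@dataclass
class NamingResult:
    """Complete old->new name mapping for one residue."""

    names: Dict[int, str] = field(default_factory=dict)
    heavy_names: Dict[int, str] = field(default_factory=dict)
    hydrogen_names: Dict[int, str] = field(default_factory=dict)
    #: pseudoatom name -> serials of the hydrogens it stands for
    pseudoatoms: Dict[str, List[int]] = field(default_factory=dict)
    assignment: Optional[ChainAssignment] = None
    audit: List[str] = field(default_factory=list)

    def rename_table(self, g: MolecularGraph) -> List[Tuple[str, str]]:
        return [(g.atom(s).name, n) for s, n in sorted(self.names.items())]

    def apply(self, g: MolecularGraph) -> MolecularGraph:
        """Copy of ``g`` with the new names written onto the atoms."""
        out = g.copy()
        for s, name in self.names.items():
            if s in out:
                out.atom(s).name = name
        return out


def _positional_part(asg: ChainAssignment, serial: int, table: str,
                     sticky_suffix: bool) -> str:
    d = asg.distance[serial]
    letter = position_label(d, table)
    shell = asg.shell(d)
    numbered = not (asg.chain[serial] == 1 and len(shell) == 1)
    if sticky_suffix and not numbered:
        # retain the number when any atom on the path back to C-alpha
        # carries more than one side-chain branch
        s = serial
        while s in asg.predecessor:
            p = asg.predecessor[s]
            branches = [t for t, q in asg.predecessor.items() if q == p]
            if len(branches) > 1:
                numbered = True
                break
            s = p
    return letter + (str(asg.chain[serial]) if numbered else "")


def name_atoms(assignment: ChainAssignment, g: MolecularGraph,
               table: str = GREEK_ROMAN, sticky_suffix: bool = False,
               backbone_h_name: str = "H") -> NamingResult:
    """Generate heavy-atom, hydrogen and pseudoatom names for one residue.

    Heavy side-chain atoms are named element symbol + positional letter +
    chain number, the number being dropped for a chain-1 atom that is the
    sole heavy occupant of its distance shell.  Hydrogens take H plus the
    parent's positional part; the two hydrogens of a tetrahedral methylene
    are numbered 2/3 by the handedness of the pair around their carbon,
    methyl hydrogens 1/2/3 by input order, and planar NH2-type pairs 1/2 by
    input order.  Pseudoatoms (Q + positional part) cover methyl, methylene
    and symmetry-equivalent aromatic-pair hydrogens.
    """
    asg = assignment
    bb = asg.backbone
    if bb is None:
        raise NamingError("assignment carries no backbone record")
    res = NamingResult(assignment=asg, audit=list(asg.audit))
    res.pseudoatoms = {}

    pos_part: Dict[int, str] = {}
    for s in asg.distance:
        pos_part[s] = _positional_part(asg, s, table, sticky_suffix)
        res.heavy_names[s] = g.atom(s).element.strip().upper() + pos_part[s]

    # backbone heavy atoms keep their fixed names
    res.heavy_names[bb.n] = "N"
    res.heavy_names[bb.ca] = "CA"
    res.heavy_names[bb.c] = "C"
    res.heavy_names[bb.o] = "O"
    pos_part[bb.ca] = "A"

    # extra backbone oxygens (C-terminal carboxylate) and N-substituents are
    # left out of the side chain; give terminal oxygens conventional names
    for s in g.neighbors(bb.c):
        if s == bb.o or s in res.heavy_names:
            continue
        a = g.atom(s)
        if a.element.upper() == "O" and not a.is_hydrogen:
            res.heavy_names[s] = "OXT"

    def attached_h(parent: int) -> List[int]:
        return sorted(s for s in g.neighbors(parent)
                      if g.atom(s).is_hydrogen and not g.atom(s).is_pseudo)

    # hydrogens on side-chain heavy atoms and on CA
    h_parents = list(asg.distance) + [bb.ca]
    for parent in h_parents:
        hs = attached_h(parent)
        if not hs:
            continue
        pp = pos_part[parent]
        if len(hs) == 1:
            res.hydrogen_names[hs[0]] = "H" + pp
        elif len(hs) == 2:
            if g.degree(parent) == 4:
                anchor = asg.predecessor.get(parent, bb.n if parent == bb.ca
                                             else bb.ca)
                try:
                    sign = chirality_sign(
                        g.coords(hs[0]), g.coords(hs[1]),
                        g.coords(parent), g.coords(anchor))
                except DegenerateGeometryError:
                    sign = 1
                    res.audit.append(
                        f"degenerate methylene geometry at {parent}; "
                        "hydrogen numbers assigned by input order")
                first, second = (hs[0], hs[1]) if sign > 0 else (hs[1], hs[0])
                res.hydrogen_names[first] = "H" + pp + "2"
                res.hydrogen_names[second] = "H" + pp + "3"
            else:
                for i, h in enumerate(hs, start=1):
                    res.hydrogen_names[h] = "H" + pp + str(i)
            res.pseudoatoms.setdefault("Q" + pp, []).extend(hs)
        else:
            for i, h in enumerate(hs, start=1):
                res.hydrogen_names[h] = "H" + pp + str(i)
            res.pseudoatoms.setdefault("Q" + pp, []).extend(hs)

    # backbone amide hydrogens
    n_hs = attached_h(bb.n)
    if len(n_hs) == 1:
        res.hydrogen_names[n_hs[0]] = backbone_h_name
    else:
        for i, h in enumerate(n_hs, start=1):
            res.hydrogen_names[h] = backbone_h_name + str(i)

    # N-substituents (N-methylated backbones, e.g. sarcosine): the methyl
    # carbon takes the conventional CN name, its hydrogens HN1..HN3
    n_subs = [s for s in g.neighbors(bb.n)
              if s != bb.ca and not g.atom(s).is_hydrogen
              and s not in res.heavy_names]
    for j, s in enumerate(sorted(n_subs), start=1):
        suffix = "" if len(n_subs) == 1 else str(j)
        res.heavy_names[s] = g.atom(s).element.strip().upper() + "N" + suffix
        for i, h in enumerate(attached_h(s), start=1):
            res.hydrogen_names[h] = "HN" + suffix + str(i)
        deeper = [t for t in g.neighbors(s)
                  if t != bb.n and not g.atom(t).is_hydrogen]
        if deeper:
            raise NamingError(
                f"N-substituent at {s} extends beyond one heavy atom; "
                "only methyl-type backbone N-substitution is supported")
    for h in attached_h(bb.o):
        res.hydrogen_names[h] = "HO"
    for s in g.neighbors(bb.c):
        if res.heavy_names.get(s) == "OXT":
            for h in attached_h(s):
                res.hydrogen_names[h] = "HXT"

    # symmetry-equivalent aromatic pairs: one Q pseudoatom per matched pair
    for _branch, members, _how in asg.tie_groups:
        if len(members) != 2:
            continue
        sub_a = _subtree(asg, members[0])
        sub_b = _subtree(asg, members[1])
        by_shell_a: Dict[Tuple[int, str], List[int]] = {}
        by_shell_b: Dict[Tuple[int, str], List[int]] = {}
        for sub, acc in ((sub_a, by_shell_a), (sub_b, by_shell_b)):
            for s in sub:
                if s not in asg.distance:
                    continue
                hs = attached_h(s)
                if len(hs) == 1:
                    key = (asg.distance[s], g.atom(s).element.upper())
                    acc.setdefault(key, []).append(s)
        for key, alist in by_shell_a.items():
            blist = by_shell_b.get(key, [])
            if len(alist) == 1 and len(blist) == 1 and alist != blist:
                letter = position_label(key[0], table)
                qname = "Q" + letter
                hs = attached_h(alist[0]) + attached_h(blist[0])
                res.pseudoatoms.setdefault(qname, hs)

    res.names = dict(res.heavy_names)
    res.names.update(res.hydrogen_names)

    unnamed = [a.serial for a in g.atoms
               if not a.is_pseudo and a.serial not in res.names]
    if unnamed:
        raise NamingError(f"atoms left unnamed: {unnamed}; audit: {res.audit}")
    values = list(res.names.values())
    if len(values) != len(set(values)):
        dupes = sorted({v for v in values if values.count(v) > 1})
        raise NamingError(f"name collision: {dupes}; audit: {res.audit}")
    return res


def rename(g: MolecularGraph, table: str = GREEK_ROMAN,
           sticky_suffix: bool = False,
           backbone_h_name: str = "H") -> NamingResult:
    """Name every atom of a single (excised or standalone) residue.

    Composition of backbone location, side-chain chain assignment and name
    generation; deterministic for a fixed input graph.
    """
    backbone = find_backbone(g)
    assignment = assign_chains(g, backbone)
    return name_atoms(assignment, g, table=table, sticky_suffix=sticky_suffix,
                      backbone_h_name=backbone_h_name)
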