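"""Brute-force CIP chain-assignment oracle.

An independent re-implementation of the side-chain numbering used to
cross-check :func:`ncaatools.namer.assign_chains`.  Everything is
recomputed from the raw molecular graph with plain dictionaries and
explicit recursion: its own adjacency and breadth-first distances, its own
unsaturation duplicates, and full materialised hierarchical-digraph trees
compared without memoisation.  Only :func:`~ncaatools.chemgraph.chirality_sign`
is shared, since both implementations are required to consult the same
geometric construction for graph-identical branches.

Capped at 25 heavy atoms: tree materialisation is exponential in ring-rich
inputs and this module values transparency over speed.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from ..chemgraph import (
    Backbone,
    DegenerateGeometryError,
    MolecularGraph,
    chirality_sign,
)

__all__ = ["brute_force_cip", "OracleSizeError"]

MAX_HEAVY_ATOMS = 25


class OracleSizeError(ValueError):
    pass


def _side_adjacency(g: MolecularGraph, bb: Backbone):
    """Adjacency over heavy side-chain atoms (component of CA after
    deleting backbone N and C'), plus duplicate-atom lists per atom."""
    heavy = [a.serial for a in g.atoms
             if not a.is_hydrogen and not a.is_pseudo and not a.is_duplicate]
    drop = {bb.n, bb.c}
    keep = [s for s in heavy if s not in drop]
    adj: Dict[int, List[int]] = {s: [] for s in keep}
    dup: Dict[int, List[int]] = {s: [] for s in keep}
    aromatic: Dict[int, bool] = {s: False for s in keep}
    for b in g.bonds:
        if b.a not in adj or b.b not in adj:
            continue
        adj[b.a].append(b.b)
        adj[b.b].append(b.a)
        if b.order in (2, "2", 3, "3"):
            times = 1 if b.order in (2, "2") else 2
            for _ in range(times):
                dup[b.a].append(g.atom(b.b).atomic_number)
                dup[b.b].append(g.atom(b.a).atomic_number)
        elif b.order in ("ar", 1.5):
            aromatic[b.a] = True
            aromatic[b.b] = True
    for s in keep:
        if aromatic[s]:
            dup[s].append(g.atom(s).atomic_number)
    # restrict to the connected component containing CA
    seen = {bb.ca}
    queue = [bb.ca]
    while queue:
        cur = queue.pop()
        for nbr in adj.get(cur, ()):
            if nbr not in seen:
                seen.add(nbr)
                queue.append(nbr)
    adj = {s: [t for t in nbrs if t in seen]
           for s, nbrs in adj.items() if s in seen}
    dup = {s: d for s, d in dup.items() if s in seen}
    return adj, dup


def _distances(adj, source):
    dist = {source: 0}
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for s in frontier:
            for t in adj[s]:
                if t not in dist:
                    dist[t] = d
                    nxt.append(t)
        frontier = nxt
    return dist


def _tree(g, adj, dup, node, parent, path):
    """Materialised digraph branch: (atomic number, [child trees])."""
    children = [(z, []) for z in dup[node]]
    for nbr in adj[node]:
        if nbr == parent:
            continue
        if nbr in path:
            children.append((g.atom(nbr).atomic_number, []))
        else:
            children.append(_tree(g, adj, dup, nbr, node, path + [node]))
    # insertion sort, highest first, using the full recursive comparison
    ordered = []
    for ch in children:
        i = 0
        while i < len(ordered) and _cmp_tree(ordered[i], ch) >= 0:
            i += 1
        ordered.insert(i, ch)
    return (g.atom(node).atomic_number, ordered)


def _cmp_tree(t1, t2):
    if t1[0] != t2[0]:
        return 1 if t1[0] > t2[0] else -1
    c1, c2 = t1[1], t2[1]
    for i in range(max(len(c1), len(c2))):
        x1 = c1[i] if i < len(c1) else (0, [])
        x2 = c2[i] if i < len(c2) else (0, [])
        r = _cmp_tree(x1, x2)
        if r != 0:
            return r
    return 0


def brute_force_cip(g: MolecularGraph, bb: Backbone):
    """Chain assignment by exhaustive digraph comparison.

    Returns ``(distance, chain)``: two dicts over the heavy side-chain
    serials, matching the output contract of
    :func:`ncaatools.namer.assign_chains`.
    """
    n_heavy = sum(1 for a in g.atoms
                  if not a.is_hydrogen and not a.is_pseudo and not a.is_duplicate)
    if n_heavy > MAX_HEAVY_ATOMS:
        raise OracleSizeError(
            f"{n_heavy} heavy atoms exceeds the {MAX_HEAVY_ATOMS}-atom cap")

    adj, dup = _side_adjacency(g, bb)
    dist = _distances(adj, bb.ca)
    dist.pop(bb.ca)
    if not dist:
        return {}, {}

    full_degree = {a.serial: len(g.neighbors(a.serial)) for a in g.atoms}

    def ordered_children(branch_atom, kids, anchor):
        """Kids sorted highest CIP priority first; ties broken by geometry
        at tetrahedral branch atoms, otherwise left in serial order.
        Returns the ordered list plus the tie groups encountered."""
        trees = {k: _tree(g, adj, dup, k, branch_atom, [branch_atom])
                 for k in kids}
        remaining = sorted(kids)
        order = []
        ties = []
        while remaining:
            best = [remaining[0]]
            for k in remaining[1:]:
                r = _cmp_tree(trees[k], trees[best[0]])
                if r > 0:
                    best = [k]
                elif r == 0:
                    best.append(k)
            if len(best) == 2 and full_degree[branch_atom] == 4:
                try:
                    s = chirality_sign(g.coords(best[0]), g.coords(best[1]),
                                       g.coords(branch_atom), g.coords(anchor))
                    if s < 0:
                        best = [best[1], best[0]]
                except DegenerateGeometryError:
                    pass
            if len(best) > 1:
                ties.append((branch_atom, tuple(best)))
            order.extend(best)
            for k in best:
                remaining.remove(k)
        return order, ties

    chain: Dict[int, int] = {}
    pred: Dict[int, int] = {}
    created_at: Dict[int, int] = {}
    tie_groups: List[Tuple[int, Tuple[int, ...]]] = []
    counter = 1
    max_d = max(dist.values())

    first = [s for s in adj[bb.ca] if s in dist]
    order, ties = ordered_children(bb.ca, first, bb.n)
    tie_groups.extend(ties)
    for s in order:
        chain[s] = counter
        created_at[counter] = s
        pred[s] = bb.ca
        counter += 1

    for d in range(2, max_d + 1):
        parents = [s for s in chain if dist[s] == d - 1]
        parents.sort(key=lambda s: chain[s])
        for p in parents:
            kids = [t for t in adj[p] if dist.get(t) == d]
            if not kids:
                continue
            order, ties = ordered_children(p, kids, pred[p])
            tie_groups.extend(ties)
            for i, s in enumerate(order):
                if s in chain:
                    if i == 0 and chain[p] < chain[s]:
                        chain[s] = chain[p]
                        pred[s] = p
                    continue
                if i == 0:
                    chain[s] = chain[p]
                else:
                    chain[s] = counter
                    created_at[counter] = s
                    counter += 1
                pred[s] = p

    # drop gaps left by ring joins that abandoned a fresh chain number
    used = sorted(set(chain.values()))
    squeeze = {c: i + 1 for i, c in enumerate(used)}
    chain = {s: squeeze[c] for s, c in chain.items()}
    created_at = {squeeze[c]: s for c, s in created_at.items() if c in squeeze}

    # symmetry re-pass: chains opened inside graph-identical sibling
    # branches are pooled and re-dealt branch by branch
    def subtree(root):
        members = {root}
        grew = True
        while grew:
            grew = False
            for s, p in pred.items():
                if p in members and s not in members:
                    members.add(s)
                    grew = True
        return members

    tie_groups.sort(key=lambda t: dist.get(t[1][0], 0))
    for _branch, members in tie_groups:
        blocks = []
        for m in members:
            sub = subtree(m)
            blocks.append(sorted(c for c, at in created_at.items() if at in sub))
        pool = sorted(c for blk in blocks for c in blk)
        remap = {}
        i = 0
        for blk in blocks:
            for c in blk:
                remap[c] = pool[i]
                i += 1
        if remap and any(k != v for k, v in remap.items()):
            chain = {s: remap.get(c, c) for s, c in chain.items()}
            created_at = {remap.get(c, c): s for c, s in created_at.items()}

    return dict(dist), chain
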