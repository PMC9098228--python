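"""Unit-cost parsimony on rooted, possibly polytomous trees.

The engine is the generalized (Sankoff) dynamic programme with a unit step
matrix rather than Fitch set operations, so polytomies, polymorphic leaves and
missing data need no special-casing.  Ancestral-state uncertainty is reported
as MPR ("most parsimonious reconstruction") sets: a state belongs to a node's
set iff at least one globally minimal full labeling assigns it — a two-state
set is what a published reconstruction table prints as "uncertain".

All arithmetic is integer; infinity is a sentinel larger than any achievable
tree length.  Branch lengths are ignored throughout.

``brute_force_mpr`` exhaustively enumerates labelings on small trees and is
the testing oracle for the dynamic programme; ``fitch_length`` is an
independent cross-check valid on fully resolved trees without missing data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Tuple

import dendropy

from .characters import ABSENT, PRESENT, FULL_SET, CharacterColumn
from .treeio import RootedTree, TreeError

__all__ = [
    "INF",
    "MPRResult",
    "downpass",
    "mpr_sets",
    "tree_length",
    "brute_force_mpr",
    "fitch_length",
]

STATES = (ABSENT, PRESENT)
INF = 10 ** 9  # larger than any achievable length (n_leaves would suffice)


def _leaf_costs(tree: RootedTree, col: CharacterColumn
                ) -> Dict[dendropy.Node, Tuple[int, int]]:
    costs = {}
    for leaf in tree.leaves():
        name = leaf.taxon.label
        if name not in col:
            raise TreeError(f"leaf {name!r} has no character entry")
        ss = col[name]
        costs[leaf] = tuple(0 if s in ss else INF for s in STATES)
    return costs


def downpass(tree: RootedTree, col: CharacterColumn
             ) -> Dict[dendropy.Node, Tuple[int, int]]:
    """Per-node Sankoff cost vectors.

    ``cost[v][s]`` is the minimum number of state changes in the subtree of
    ``v`` given that ``v`` is in state ``s``.  Polytomies are scored natively
    (hard polytomies); a leaf with state set ``S`` costs 0 on members of ``S``
    and infinity elsewhere, so missing leaves cost 0 everywhere.
    """
    cost = _leaf_costs(tree, col)
    for node in tree.postorder():
        if node.is_leaf():
            continue
        total = [0, 0]
        for child in node.child_nodes():
            c = cost[child]
            for s in STATES:
                best = min(c[t] + (0 if s == t else 1) for t in STATES)
                total[s] = min(total[s] + best, INF)
        cost[node] = tuple(total)
    return cost


def tree_length(tree: RootedTree, col: CharacterColumn) -> int:
    """Minimum number of state changes on the tree (rerooting-invariant)."""
    root_costs = downpass(tree, col)[tree.root]
    return min(root_costs)


@dataclass(frozen=True)
class MPRResult:
    """Minimum tree length plus per-node MPR state sets.

    ``node_sets`` maps every node (internal and leaf) of the analysed tree to
    the non-empty set of states realized in at least one globally minimal
    labeling; leaves echo their input sets restricted to MPR-compatible
    states.
    """

    tree_length: int
    node_sets: Mapping[dendropy.Node, FrozenSet[int]]

    def states_at(self, node: dendropy.Node) -> FrozenSet[int]:
        return self.node_sets[node]

    def to_jsonable(self, tree: RootedTree) -> dict:
        nodes = []
        for node, ss in self.node_sets.items():
            nodes.append({
                "label": RootedTree.node_name(node),
                "leaves": sorted(tree.leafset(node)),
                "states": sorted("absent" if s == ABSENT else "present"
                                 for s in ss),
            })
        return {"tree_length": self.tree_length, "nodes": nodes}


def mpr_sets(tree: RootedTree, col: CharacterColumn) -> MPRResult:
    """MPR state sets for every node (down-pass + up-pass DP).

    For node ``v`` and state ``s``, the conditional length is the minimum tree
    length over labelings with ``v`` fixed to ``s``; the node's MPR set is the
    set of states whose conditional length equals the global minimum.
    """
    down = downpass(tree, col)
    up: Dict[dendropy.Node, Tuple[int, int]] = {tree.root: (0, 0)}
    for node in tree.nodes():  # preorder
        if node.is_leaf():
            continue
        children = node.child_nodes()
        # m[c][t] = best contribution of child c when this node is in state t
        m = {
            c: tuple(min(down[c][t2] + (0 if t == t2 else 1) for t2 in STATES)
                     for t in STATES)
            for c in children
        }
        for c in children:
            vec = []
            for s in STATES:
                best = INF
                for t in STATES:
                    sib = down[node][t] - m[c][t]
                    cand = up[node][t] + sib + (0 if t == s else 1)
                    if up[node][t] >= INF or down[node][t] >= INF:
                        cand = INF
                    best = min(best, cand)
                vec.append(min(best, INF))
            up[c] = tuple(vec)

    length = min(down[tree.root])
    sets = {}
    for node in tree.nodes():
        total = tuple(min(down[node][s] + up[node][s], INF) for s in STATES)
        ss = frozenset(s for s in STATES if total[s] == length)
        if not ss:
            raise AssertionError("empty MPR set: inconsistent DP state")
        sets[node] = ss
    return MPRResult(tree_length=length, node_sets=sets)


def brute_force_mpr(tree: RootedTree, col: CharacterColumn,
                    max_internal_nodes: int = 16) -> MPRResult:
    """Exact MPR by exhaustive enumeration of all labelings (testing oracle).

    Enumerates every assignment of states to internal nodes; a leaf's state
    ranges over its input set, and since a leaf touches only the edge to its
    parent its contribution is folded in analytically: cost 0 (choosing the
    parent's state) when the parent's state is allowed, else cost 1 (any
    allowed state).  Refuses trees with more than ``max_internal_nodes``
    internal nodes.
    """
    leaf_costs = _leaf_costs(tree, col)
    internal = [n for n in tree.nodes() if not n.is_leaf()]
    leaves = [n for n in tree.nodes() if n.is_leaf()]
    if len(internal) > max_internal_nodes:
        raise TreeError(
            f"brute force refused: {len(internal)} internal nodes "
            f"> {max_internal_nodes}")
    allowed = {leaf: frozenset(s for s in STATES if leaf_costs[leaf][s] == 0)
               for leaf in leaves}

    if not internal:  # single-leaf tree
        (leaf,) = leaves
        return MPRResult(tree_length=0, node_sets={leaf: allowed[leaf]})

    best = INF
    minimal: List[Dict[dendropy.Node, int]] = []
    for combo in itertools.product(STATES, repeat=len(internal)):
        assign = dict(zip(internal, combo))
        length = 0
        for node in internal:
            if node.parent_node is not None and assign[node] != assign[node.parent_node]:
                length += 1
        for leaf in leaves:
            if assign[leaf.parent_node] not in allowed[leaf]:
                length += 1
        if length < best:
            best = length
            minimal = [assign]
        elif length == best:
            minimal.append(assign)

    sets: Dict[dendropy.Node, FrozenSet[int]] = {}
    for node in internal:
        sets[node] = frozenset(a[node] for a in minimal)
    for leaf in leaves:
        realized = set()
        for a in minimal:
            p = a[leaf.parent_node]
            # states of this leaf achieving the minimum under assignment a
            realized |= {p} if p in allowed[leaf] else set(allowed[leaf])
        sets[leaf] = frozenset(realized)
    return MPRResult(tree_length=best, node_sets=sets)


def fitch_length(tree: RootedTree, col: CharacterColumn) -> int:
    """Fitch down-pass change count (cross-check only).

    Valid on fully resolved (binary) trees whose leaves all have single
    observed states; raises on anything else.
    """
    length = 0
    sets: Dict[dendropy.Node, FrozenSet[int]] = {}
    for node in tree.postorder():
        if node.is_leaf():
            ss = col[node.taxon.label]
            if len(ss) != 1:
                raise TreeError("fitch_length requires unambiguous leaves")
            sets[node] = frozenset(ss)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise TreeError("fitch_length requires a fully resolved tree")
        a, b = sets[children[0]], sets[children[1]]
        inter = a & b
        if inter:
            sets[node] = inter
        else:
            sets[node] = a | b
            length += 1
    return length
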