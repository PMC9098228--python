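"""Rooted-tree I/O and surgery.

Trees here are rooted, possibly polytomous, with uniquely named leaves and
optional internal-node labels.  Branch lengths are carried through round-trips
but are ignored by every parsimony computation in this package: the analyses
are purely topological.

The two surgery operations, :meth:`RootedTree.prune` and
:meth:`RootedTree.graft_sister`, are the primitives used to move
phylogenetically unstable ("rogue") taxa between alternative attachment
points.  Both are pure: they return new trees and leave their input untouched.

Parsing and serialisation are delegated to :mod:`dendropy` (Newick and NEXUS
``TREES`` blocks, including ``TRANSLATE`` tables).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import dendropy

__all__ = [
    "TreeError",
    "TreeParseError",
    "CladeRef",
    "RootedTree",
    "read_newick",
    "write_newick",
    "read_tree_file",
]


class TreeError(ValueError):
    """Structural error in a tree operation (bad prune/graft/lookup)."""


class TreeParseError(TreeError):
    """Malformed Newick/NEXUS input."""


@dataclass(frozen=True)
class CladeRef:
    """Address of a clade: an internal-node label, or a leaf-name set resolved
    to its MRCA.

    Resolution is deterministic.  A single leaf name resolves to that leaf.
    """

    label: Optional[str] = None
    leaves: Optional[frozenset] = None

    def __post_init__(self):
        if (self.label is None) == (self.leaves is None):
            raise ValueError("CladeRef needs exactly one of label= or leaves=")
        if self.leaves is not None and len(self.leaves) == 0:
            raise ValueError("CladeRef leaf set must be non-empty")

    @classmethod
    def of(cls, ref: Union["CladeRef", str, Iterable[str]]) -> "CladeRef":
        if isinstance(ref, CladeRef):
            return ref
        if isinstance(ref, str):
            return cls(label=ref)
        return cls(leaves=frozenset(ref))


def _read_dendropy(text: str, schema: str,
                   taxon_namespace=None) -> dendropy.Tree:
    kwargs = dict(schema=schema, preserve_underscores=True)
    if taxon_namespace is not None:
        kwargs["taxon_namespace"] = taxon_namespace
    try:
        dtree = dendropy.Tree.get(data=text, **kwargs)
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        raise TreeParseError(f"cannot parse tree input: {exc}") from exc
    return dtree


class RootedTree:
    """A rooted phylogenetic tree with named leaves.

    Thin wrapper around a :class:`dendropy.Tree` that enforces unique leaf
    names, preserves child order verbatim, and exposes the surgery used by the
    topology-space enumeration.  Node handles returned by :meth:`mrca` /
    :meth:`resolve` are dendropy ``Node`` objects belonging to this tree.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        self._check_leaf_names()

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        return cls(_read_dendropy(text, "newick"))

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RootedTree":
        """Read a tree from a Newick or NEXUS file (sniffed by content)."""
        text = Path(path).read_text()
        schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
        return cls(_read_dendropy(text, schema))

    def to_newick(self) -> str:
        """Deterministic Newick string; children in stored order."""
        return self._dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            preserve_spaces=True,
        ).strip() + "\n"

    def to_file(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_newick())

    # ------------------------------------------------------------- queries

    @property
    def root(self) -> dendropy.Node:
        return self._dtree.seed_node

    def nodes(self) -> Iterator[dendropy.Node]:
        return self._dtree.preorder_node_iter()

    def postorder(self) -> Iterator[dendropy.Node]:
        return self._dtree.postorder_node_iter()

    def leaves(self) -> Iterator[dendropy.Node]:
        return self._dtree.leaf_node_iter()

    @property
    def leaf_names(self) -> list:
        return [lf.taxon.label for lf in self.leaves()]

    def __len__(self) -> int:
        return sum(1 for _ in self.leaves())

    def has_branch_lengths(self) -> bool:
        return any(e.length is not None for e in self._dtree.preorder_edge_iter()
                   if e.head_node is not self.root)

    @staticmethod
    def node_name(node: dendropy.Node) -> Optional[str]:
        if node.is_leaf():
            return node.taxon.label if node.taxon else node.label
        return node.label

    def leaf_node(self, name: str) -> dendropy.Node:
        for lf in self.leaves():
            if lf.taxon.label == name:
                return lf
        raise TreeError(f"unknown leaf name: {name!r}")

    def leafset(self, node: dendropy.Node) -> frozenset:
        """Names of the leaves descending from (and including) ``node``."""
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def mrca(self, names: Iterable[str]) -> dendropy.Node:
        """Deepest node ancestral to every named leaf.

        Computed by pairwise depth-balanced ancestor walking; an independent
        ancestor-set-intersection oracle lives in the test suite.
        """
        names = list(names)
        if not names:
            raise TreeError("mrca of an empty leaf set")
        nodes = [self.leaf_node(n) for n in names]
        depth = {}

        def _depth(n):
            if n in depth:
                return depth[n]
            d = 0 if n.parent_node is None else _depth(n.parent_node) + 1
            depth[n] = d
            return d

        cur = nodes[0]
        for other in nodes[1:]:
            a, b = cur, other
            da, db = _depth(a), _depth(b)
            while da > db:
                a, da = a.parent_node, da - 1
            while db > da:
                b, db = b.parent_node, db - 1
            while a is not b:
                a, b = a.parent_node, b.parent_node
            cur = a
        return cur

    def find_label(self, label: str) -> Optional[dendropy.Node]:
        for node in self.nodes():
            if self.node_name(node) == label:
                return node
        return None

    def resolve(self, ref: Union[CladeRef, str, Iterable[str]]) -> dendropy.Node:
        """Resolve a clade reference to a node of this tree."""
        ref = CladeRef.of(ref)
        if ref.label is not None:
            node = self.find_label(ref.label)
            if node is None:
                raise TreeError(f"no node labelled {ref.label!r}")
            return node
        missing = ref.leaves - frozenset(self.leaf_names)
        if missing:
            raise TreeError(f"leaves not in tree: {sorted(missing)}")
        return self.mrca(ref.leaves)

    # ------------------------------------------------------------- copying

    def copy(self) -> "RootedTree":
        # re-parse: cheapest way to get a fully independent tree + namespace
        return RootedTree.from_newick(self.to_newick())

    def extract_subtree(self, ref) -> "RootedTree":
        """A copy of the subtree rooted at ``ref``, as an independent tree."""
        node = self.resolve(ref)
        if node.is_leaf():
            return RootedTree.from_newick(_quote(node.taxon.label) + ";")
        text = _subtree_newick(node) + ";"
        return RootedTree.from_newick(text)

    # ------------------------------------------------------------- surgery

    def prune(self, ref) -> "RootedTree":
        """Remove a clade; suppress any resulting degree-2 node.

        Pruning the root (or everything) is a structural error.
        """
        new = self.copy()
        node = new.resolve(_rebind(ref))
        if node is new.root:
            raise TreeError("cannot prune the root")
        parent = node.parent_node
        parent.remove_child(node)
        new._dtree.suppress_unifurcations()
        new._dtree.update_taxon_namespace()
        if sum(1 for _ in new.leaves()) == 0:
            raise TreeError("prune removed every leaf")
        return new

    def graft_sister(self, subtree: "RootedTree", ref) -> tuple:
        """Attach ``subtree`` as sister to the clade at ``ref``.

        A new internal node is created on the edge above the target, with the
        target clade and the grafted subtree as its children; if the target is
        the root the new node becomes the new root.  Returns
        ``(new_tree, stem_node)`` where ``stem_node`` is that new node (the
        grafted subtree's stem node), belonging to ``new_tree``.
        """
        overlap = set(subtree.leaf_names) & set(self.leaf_names)
        if overlap:
            raise TreeError(f"leaf name collision: {sorted(overlap)}")
        new = self.copy()
        target = new.resolve(_rebind(ref))
        sub = _read_dendropy(subtree.to_newick(), "newick",
                             taxon_namespace=new._dtree.taxon_namespace)
        joint = dendropy.Node()
        if target is new.root:
            joint.add_child(target)
            joint.add_child(sub.seed_node)
            new._dtree.seed_node = joint
        else:
            parent = target.parent_node
            idx = parent._child_nodes.index(target)
            parent.remove_child(target)
            joint.add_child(target)
            joint.add_child(sub.seed_node)
            parent.insert_child(idx, joint)
        new._dtree.update_taxon_namespace()
        new._check_leaf_names()
        return new, joint

    # ---------------------------------------------------------- comparison

    def canonical_signature(self):
        """Order-insensitive canonical form of the rooted topology.

        Leaves map to their names; internal nodes to the sorted tuple of child
        signatures.  Two rooted trees are isomorphic (ignoring internal labels
        and branch lengths) iff their signatures are equal.
        """

        def sig(node):
            if node.is_leaf():
                return node.taxon.label
            return tuple(sorted((sig(c) for c in node.child_nodes()), key=repr))

        return sig(self.root)

    def is_isomorphic(self, other: "RootedTree") -> bool:
        return self.canonical_signature() == other.canonical_signature()

    # ------------------------------------------------------------ internal

    def _check_leaf_names(self):
        seen = set()
        for lf in self.leaves():
            if lf.taxon is None:
                raise TreeParseError("leaf without a name")
            name = lf.taxon.label
            if name in seen:
                raise TreeParseError(f"duplicate leaf name: {name!r}")
            seen.add(name)

    def __repr__(self):
        n = len(self)
        return f"<RootedTree with {n} leaves>"


def _rebind(ref):
    """CladeRefs resolve on the copy, so plain refs pass through unchanged."""
    return CladeRef.of(ref)


def _quote(label: str) -> str:
    if any(ch in label for ch in " _()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def _subtree_newick(node) -> str:
    if node.is_leaf():
        return _quote(node.taxon.label)
    inner = ",".join(_subtree_newick(c) for c in node.child_nodes())
    label = node.label or ""
    return f"({inner}){_quote(label) if label else ''}"


# Functional conveniences mirroring the class methods ----------------------

def read_newick(text: str) -> RootedTree:
    return RootedTree.from_newick(text)


def write_newick(tree: RootedTree) -> str:
    return tree.to_newick()


def read_tree_file(path) -> RootedTree:
    return RootedTree.from_file(path)
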