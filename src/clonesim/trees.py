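"""Rooted clonal trees with (possibly internal) uniquely labeled nodes.

Clonal trees differ from classical phylogenies: sampled sequences may sit on
internal nodes, nodes may have any number of children, and edge lengths are
integer mutation counts (true trees) or real substitutions per site
(estimated trees).  This module provides

* a light rooted-tree container (:class:`ClonalTree`) with Newick round-trip
  (internal labels in the standard internal-name slot, lengths to 6
  significant digits),
* ground-truth tree extraction from a simulated genealogy (restriction to
  sampled cells and their ancestors, suppression of unlabeled pass-through
  nodes, merging of zero-mutation neighbours),
* label induction and short-branch contraction for estimated trees, and
* the Hamming-distance minimum-spanning-tree baseline reconstructor with the
  naive root forced to be the tree root.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeNode",
    "ClonalTree",
    "parse_newick",
    "write_newick",
    "true_tree",
    "induce",
    "contract",
    "hamming",
    "mst_tree",
]


class TreeNode:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length  # edge length to the parent; None at the root
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> None:
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class ClonalTree:
    """A rooted tree whose nodes carry optional unique labels."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal -----------------------------------------------------
    def preorder(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterable[TreeNode]:
        out = list(self.preorder())
        return reversed(out)

    def nodes(self) -> list[TreeNode]:
        return list(self.preorder())

    def labels(self) -> list[str]:
        return [nd.label for nd in self.preorder() if nd.label is not None]

    def labeled_nodes(self) -> dict[str, TreeNode]:
        out: dict[str, TreeNode] = {}
        for nd in self.preorder():
            if nd.label is not None:
                if nd.label in out:
                    raise ValueError(f"duplicate label {nd.label!r}")
                out[nd.label] = nd
        return out

    def copy(self) -> "ClonalTree":
        def rec(nd: TreeNode) -> TreeNode:
            new = TreeNode(nd.label, nd.length)
            for c in nd.children:
                new.add(rec(c))
            return new
        return ClonalTree(rec(self.root))

    def validate(self) -> None:
        self.labeled_nodes()
        for nd in self.preorder():
            if nd is not self.root and nd.length is not None and nd.length < 0:
                raise ValueError("edge lengths must be nonnegative")
            for c in nd.children:
                if c.parent is not nd:
                    raise ValueError("broken parent pointer")


# ---------------------------------------------------------------------------
# Newick dialect
# ---------------------------------------------------------------------------

_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|+-]+$")


def _fmt_len(x: float) -> str:
    return format(float(x), ".6g")


def write_newick(tree: ClonalTree) -> str:
    """Serialise with internal labels in the internal-name slot and branch
    lengths to 6 significant digits (bit-exact round-trip with parse)."""

    def name(nd: TreeNode) -> str:
        if nd.label is None:
            return ""
        if not _SAFE_LABEL.match(nd.label):
            return "'" + nd.label.replace("'", "''") + "'"
        return nd.label

    def rec(nd: TreeNode) -> str:
        inner = ""
        if nd.children:
            inner = "(" + ",".join(rec(c) for c in nd.children) + ")"
        out = inner + name(nd)
        if nd.length is not None and nd is not tree.root:
            out += ":" + _fmt_len(nd.length)
        return out

    return rec(tree.root) + ";"


def parse_newick(text: str) -> ClonalTree:
    """Parse the dialect; labeled internal nodes are supported, labels must be
    unique (error names the duplicate)."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as e:  # dendropy reports the offending position
        raise ValueError(f"malformed Newick: {e}") from None

    def conv(dnode) -> TreeNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label or None
        nd = TreeNode(label, dnode.edge.length)
        for c in dnode.child_nodes():
            nd.add(conv(c))
        return nd

    tree = ClonalTree(conv(dtree.seed_node))
    tree.root.length = None
    tree.labeled_nodes()  # duplicate check
    return tree


# ---------------------------------------------------------------------------
# Ground-truth extraction
# ---------------------------------------------------------------------------

def true_tree(parent: Sequence[int], n_mut: Sequence[int],
              labels: dict[str, int], root_id: int = 0) -> ClonalTree:
    """Clonal tree of the labeled entities of a genealogy.

    ``parent[e]`` is the parent entity of ``e`` (-1 for the root) and
    ``n_mut[e]`` the number of substitutions on the edge above ``e``.  The
    genealogy is restricted to the labeled entities, the root and their
    ancestors; unlabeled pass-through nodes are suppressed (edge mutation
    counts summed); zero-mutation edges are merged so that an unlabeled
    endpoint disappears into its neighbour, while two labeled nodes joined by
    a zero-mutation edge stay distinct.
    """
    by_entity: dict[int, str] = {}
    for lab, eid in labels.items():
        if not (0 <= eid < len(parent)):
            raise ValueError(f"label {lab!r} points to nonexistent entity {eid}")
        if eid in by_entity:
            raise ValueError(f"entity {eid} carries two labels")
        by_entity[eid] = lab

    keep: set[int] = {root_id}
    for eid in by_entity:
        e = eid
        while e != -1 and e not in keep:
            keep.add(e)
            e = parent[e]

    children: dict[int, list[int]] = {e: [] for e in keep}
    for e in keep:
        p = parent[e]
        if e != root_id and p != -1:
            children[p].append(e)

    nodes: dict[int, TreeNode] = {}

    def build(e: int) -> TreeNode:
        nd = TreeNode(by_entity.get(e), float(n_mut[e]) if e != root_id else None)
        nodes[e] = nd
        for c in sorted(children[e]):
            nd.add(build(c))
        return nd

    tree = ClonalTree(build(root_id))
    _suppress_and_merge(tree)
    return tree


def _suppress_and_merge(tree: ClonalTree) -> None:
    """Iterate unifurcation suppression and zero-length merging to fixpoint."""
    changed = True
    while changed:
        changed = False
        for nd in list(tree.postorder()):
            if nd.parent is None:
                continue
            par = nd.parent
            # suppress unlabeled pass-through node (sum edge lengths)
            if nd.label is None and len(nd.children) == 1:
                (child,) = nd.children
                child.length = (child.length or 0.0) + (nd.length or 0.0)
                nd.children = []
                i = par.children.index(nd)
                par.children[i] = child
                child.parent = par
                nd.parent = None
                changed = True
                continue
            if nd.length == 0.0:
                if nd.label is None:
                    # unlabeled endpoint merges into its neighbour
                    i = par.children.index(nd)
                    par.children[i:i + 1] = nd.children
                    for c in nd.children:
                        c.parent = par
                    nd.children = []
                    nd.parent = None
                    changed = True
                elif par.label is None:
                    # labeled node absorbs its unlabeled zero-distance parent
                    par.label = nd.label
                    nd.label = None
                    changed = True
                # two labeled nodes joined by a zero edge stay distinct
        # root-side cleanup: unlabeled root with one child stays (psi-hat position)


def induce(tree: ClonalTree) -> ClonalTree:
    """Minimal tree on the labeled nodes (plus the root); idempotent.

    Unlabeled nodes with fewer than two children bearing labeled descendants
    are removed, pass-through nodes are suppressed with edge lengths summed.
    """
    out = tree.copy()

    def rec(nd: TreeNode) -> Optional[TreeNode]:
        kept = [k for k in (rec(c) for c in nd.children) if k is not None]
        nd.children = []
        for k in kept:
            nd.add(k)
        if nd.label is not None or len(kept) >= 2:
            return nd
        if len(kept) == 1:
            (child,) = kept
            child.length = (child.length or 0.0) + (nd.length or 0.0)
            child.parent = None
            return child
        return None

    root = out.root
    kept = [k for k in (rec(c) for c in root.children) if k is not None]
    root.children = []
    for k in kept:
        root.add(k)
    return ClonalTree(root)


def contract(tree: ClonalTree, threshold: float = 1e-4) -> ClonalTree:
    """Collapse branches shorter than ``threshold`` in an estimated tree.

    Internal short edges are contracted (children reattach to the parent); a
    short terminal edge below an unlabeled parent relocates the leaf label to
    that parent (creating an internal sample).  Two labeled nodes are never
    merged.  No internal edge below the threshold remains.
    """
    out = tree.copy()
    changed = True
    while changed:
        changed = False
        for nd in list(out.postorder()):
            par = nd.parent
            if par is None or nd.length is None or nd.length >= threshold:
                continue
            if nd.children:  # internal edge
                if nd.label is None:
                    i = par.children.index(nd)
                    par.children[i:i + 1] = nd.children
                    for c in nd.children:
                        c.parent = par
                    nd.children = []
                    nd.parent = None
                    changed = True
                elif par.label is None:
                    par.label = nd.label
                    nd.label = None
                    changed = True
            else:  # terminal edge
                if nd.label is not None and par.label is None:
                    par.label = nd.label
                    nd.detach()
                    changed = True
                elif nd.label is None:
                    nd.detach()
                    changed = True
    return out


# ---------------------------------------------------------------------------
# Hamming MST baseline
# ---------------------------------------------------------------------------

def hamming(s1, s2) -> int:
    """Nucleotide Hamming distance between equal-length sequences."""
    a = np.frombuffer(s1.encode(), dtype=np.uint8) if isinstance(s1, str) else np.asarray(s1)
    b = np.frombuffer(s2.encode(), dtype=np.uint8) if isinstance(s2, str) else np.asarray(s2)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return int(np.count_nonzero(a != b))


def mst_tree(labels: Sequence[str], sequences: Sequence[str],
             root_index: int = 0) -> ClonalTree:
    """Minimum spanning tree over pairwise Hamming distances.

    The record at ``root_index`` (the naive sequence) is forced to be the
    root: edges are oriented away from it and edge lengths are Hamming
    distances.  Kruskal with edges sorted by (weight, smaller record index,
    larger record index) makes ties deterministic.  The root node itself is
    left unlabeled (it is the naive anchor, not a sample).
    """
    n = len(sequences)
    if n != len(labels):
        raise ValueError("need one label per sequence")
    if n < 2:
        raise ValueError("need at least the root and one sample")
    arrs = [np.frombuffer(s.encode(), dtype=np.uint8) if isinstance(s, str)
            else np.asarray(s) for s in sequences]
    L = len(arrs[0])
    for a in arrs:
        if len(a) != L:
            raise ValueError("sequences must share one length")
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            edges.append((int(np.count_nonzero(arrs[i] != arrs[j])), i, j))
    edges.sort()

    parent_uf = list(range(n))

    def find(x: int) -> int:
        while parent_uf[x] != x:
            parent_uf[x] = parent_uf[parent_uf[x]]
            x = parent_uf[x]
        return x

    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    taken = 0
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent_uf[ri] = rj
            adj[i].append((j, w))
            adj[j].append((i, w))
            taken += 1
            if taken == n - 1:
                break

    nodes = {i: TreeNode(None if i == root_index else labels[i]) for i in range(n)}
    seen = {root_index}
    stack = [root_index]
    while stack:
        i = stack.pop()
        for j, w in sorted(adj[i]):
            if j not in seen:
                seen.add(j)
                nodes[j].length = float(w)
                nodes[i].add(nodes[j])
                stack.append(j)
    return ClonalTree(nodes[root_index])
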