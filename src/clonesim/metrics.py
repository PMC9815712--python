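"""Clonal-tree properties and reference-vs-estimate comparison metrics.

All metrics operate on rooted trees whose labeled nodes may be internal (see
:mod:`clonesim.trees`), after both trees are induced down to their labeled
nodes.  The *cluster* of a node is the set of labels at or below it (a
labeled node's own label included); cluster collections are de-duplicated
sets of label sets.  Because singleton clusters are trivial only when all
labels sit at leaves, most metrics exist in singleton-inclusive and
singleton-exclusive (starred) variants.

Unnormalised distances (RF, TD, TED, MD, PD) can be divided by their mean
under a random relabeling of the reference tree (the permutation control);
FDR and FNR are already normalised.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .trees import ClonalTree, TreeNode, induce

__all__ = [
    "PropertyReport",
    "cluster_sets",
    "compare_clusters",
    "triplet_metrics",
    "triplet_metrics_bruteforce",
    "restrict_to_labels",
    "path_metrics",
    "tree_properties",
    "permute_labels",
    "control_normalize",
    "NormalizedMetric",
    "full_comparison",
    "random_labeled_tree",
]


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------

def cluster_sets(tree: ClonalTree, include_singletons: bool = True,
                 include_root_cluster: bool = True) -> set[frozenset]:
    """Set of label-sets below each node (duplicates collapsed).

    ``include_root_cluster=False`` additionally drops the all-labels cluster.
    """
    clusters: dict[TreeNode, set] = {}
    out: set[frozenset] = set()
    all_labels: set[str] = set()
    for nd in tree.postorder():
        acc: set = set()
        if nd.label is not None:
            acc.add(nd.label)
            all_labels.add(nd.label)
        for c in nd.children:
            acc |= clusters.pop(c)
        clusters[nd] = acc
        if acc:
            out.add(frozenset(acc))
    if not include_singletons:
        out = {c for c in out if len(c) > 1}
    if not include_root_cluster:
        out.discard(frozenset(all_labels))
    return out


def _check_labels(R: ClonalTree, E: ClonalTree) -> None:
    lr, le = set(R.labels()), set(E.labels())
    if lr != le:
        only_r = sorted(lr - le)
        only_e = sorted(le - lr)
        raise ValueError(
            f"label sets differ: only in reference {only_r}, only in estimate {only_e}")


def compare_clusters(R: ClonalTree, E: ClonalTree, include_singletons: bool = True,
                     include_root_cluster: bool = True) -> tuple[float, float, float]:
    """(FDR, FNR, RF): cluster precision/recall errors and symmetric difference.

    FDR = |C(E) \\ C(R)| / |C(E)|, FNR = |C(R) \\ C(E)| / |C(R)|,
    RF = |C(E) symmetric-difference C(R)|, so RF = FDR*|C(E)| + FNR*|C(R)|.
    """
    _check_labels(R, E)
    cr = cluster_sets(R, include_singletons, include_root_cluster)
    ce = cluster_sets(E, include_singletons, include_root_cluster)
    fdr = len(ce - cr) / len(ce) if ce else 0.0
    fnr = len(cr - ce) / len(cr) if cr else 0.0
    rf = float(len(ce ^ cr))
    return fdr, fnr, rf


# ---------------------------------------------------------------------------
# Triplet metrics
# ---------------------------------------------------------------------------

class _Index:
    """Per-tree label index: Euler intervals for ancestry, parents for MRCA."""

    def __init__(self, tree: ClonalTree):
        self.tin: dict[TreeNode, int] = {}
        self.tout: dict[TreeNode, int] = {}
        self.depth: dict[TreeNode, int] = {}
        self.parent: dict[TreeNode, Optional[TreeNode]] = {}
        timer = 0
        stack: list[tuple[TreeNode, bool]] = [(tree.root, False)]
        self.depth[tree.root] = 0
        self.parent[tree.root] = None
        while stack:
            nd, done = stack.pop()
            if done:
                self.tout[nd] = timer
                timer += 1
                continue
            self.tin[nd] = timer
            timer += 1
            stack.append((nd, True))
            for c in nd.children:
                self.depth[c] = self.depth[nd] + 1
                self.parent[c] = nd
                stack.append((c, False))
        self.by_label = tree.labeled_nodes()

    def is_anc(self, a: TreeNode, b: TreeNode) -> bool:
        """a is an ancestor of b or a == b."""
        return self.tin[a] <= self.tin[b] and self.tout[b] <= self.tout[a]

    def mrca(self, a: TreeNode, b: TreeNode) -> TreeNode:
        while not self.is_anc(a, b):
            a = self.parent[a]
        return a

    def triplet_clusters(self, x: str, y: str, z: str) -> frozenset:
        """Cluster-set encoding of the tree induced to labels {x, y, z}."""
        nx, ny, nz = self.by_label[x], self.by_label[y], self.by_label[z]
        nodes = {nx, ny, nz, self.mrca(nx, ny), self.mrca(nx, nz), self.mrca(ny, nz)}
        out = set()
        for nd in nodes:
            cl = frozenset(lab for lab, ln in ((x, nx), (y, ny), (z, nz))
                           if self.is_anc(nd, ln))
            if cl:
                out.add(cl)
        return frozenset(out)


def triplet_metrics(R: ClonalTree, E: ClonalTree) -> tuple[int, int]:
    """(TD, TED) over all 3-subsets of labels.

    TD counts triplets whose induced labeled rooted shapes differ; TED sums
    the RF cluster distance between the two induced 3-label trees.  Induced
    shapes are encoded by their cluster sets (which determine a labeled
    rooted tree uniquely), computed from precomputed pairwise MRCAs.
    """
    _check_labels(R, E)
    labels = sorted(R.labels())
    if len(labels) < 3:
        raise ValueError("triplet metrics need at least 3 labels")
    ir, ie = _Index(R), _Index(E)
    td = ted = 0
    for x, y, z in itertools.combinations(labels, 3):
        cr = ir.triplet_clusters(x, y, z)
        ce = ie.triplet_clusters(x, y, z)
        if cr != ce:
            td += 1
        ted += len(cr ^ ce)
    return td, ted


def restrict_to_labels(tree: ClonalTree, keep: set[str]) -> ClonalTree:
    """Copy of ``tree`` induced down to the labels in ``keep``."""
    out = tree.copy()
    for nd in out.preorder():
        if nd.label is not None and nd.label not in keep:
            nd.label = None
    return induce(out)


def triplet_metrics_bruteforce(R: ClonalTree, E: ClonalTree) -> tuple[int, int]:
    """Reference implementation: restrict both trees per triplet and compare."""
    _check_labels(R, E)
    labels = sorted(R.labels())
    td = ted = 0
    for combo in itertools.combinations(labels, 3):
        keep = set(combo)
        cr = cluster_sets(restrict_to_labels(R, keep))
        ce = cluster_sets(restrict_to_labels(E, keep))
        if cr != ce:
            td += 1
        ted += len(cr ^ ce)
    return td, ted


# ---------------------------------------------------------------------------
# Path metrics
# ---------------------------------------------------------------------------

def path_metrics(R: ClonalTree, E: ClonalTree) -> tuple[int, int]:
    """(MD, PD) in branch counts.

    MD sums, over ordered label pairs (u, v), the absolute difference between
    the branch count from u to mrca(u, v) in the two trees; PD sums, over
    unordered pairs, the absolute difference of the full u-v path lengths.
    """
    _check_labels(R, E)
    labels = sorted(R.labels())
    ir, ie = _Index(R), _Index(E)
    md = pd = 0
    for u, v in itertools.combinations(labels, 2):
        ru, rv = ir.by_label[u], ir.by_label[v]
        eu, ev = ie.by_label[u], ie.by_label[v]
        rm, em = ir.mrca(ru, rv), ie.mrca(eu, ev)
        bru = ir.depth[ru] - ir.depth[rm]
        brv = ir.depth[rv] - ir.depth[rm]
        beu = ie.depth[eu] - ie.depth[em]
        bev = ie.depth[ev] - ie.depth[em]
        md += abs(bru - beu) + abs(brv - bev)  # both ordered pairs
        pd += abs((bru + brv) - (beu + bev))
    return md, pd


# ---------------------------------------------------------------------------
# Tree properties
# ---------------------------------------------------------------------------

@dataclass
class PropertyReport:
    internal_sample_pct: float
    bifurcation_index: float
    sample_depth: float
    balance_cherry: float
    single_mutation_branch_pct: float
    accumulated_mutations_avg: float
    accumulated_mutations_sum: float
    mutations_per_branch: float


def tree_properties(tree: ClonalTree) -> PropertyReport:
    """Topology, branch-length and label-placement summary of an induced tree."""
    nodes = tree.nodes()
    labeled = [nd for nd in nodes if nd.label is not None]
    if len(labeled) < 2:
        raise ValueError("tree properties need at least 2 labeled nodes")
    internal = [nd for nd in nodes if nd.children]
    edges = [nd for nd in nodes if nd.parent is not None]

    depth: dict[TreeNode, int] = {tree.root: 0}
    plen: dict[TreeNode, float] = {tree.root: 0.0}
    for nd in tree.preorder():
        for c in nd.children:
            depth[c] = depth[nd] + 1
            plen[c] = plen[nd] + (c.length or 0.0)

    leaves = [nd for nd in nodes if nd.is_leaf]
    balance = 0.0
    for leaf in leaves:
        if leaf.parent is None:
            continue
        sibs = [s for s in leaf.parent.children if s is not leaf]
        if sibs:
            balance += sum(1 for s in sibs if s.is_leaf) / len(sibs)
    lengths = np.array([e.length or 0.0 for e in edges], dtype=np.float64)

    return PropertyReport(
        internal_sample_pct=100.0 * sum(1 for nd in labeled if nd.children) / len(labeled),
        bifurcation_index=len(internal) / (len(labeled) - 1),
        sample_depth=float(np.mean([depth[nd] for nd in labeled])),
        balance_cherry=0.5 * balance,
        single_mutation_branch_pct=100.0 * float(np.mean(lengths == 1.0)) if len(edges) else 0.0,
        accumulated_mutations_avg=float(np.mean([plen[nd] for nd in labeled])),
        accumulated_mutations_sum=float(lengths.sum()),
        mutations_per_branch=float(lengths.mean()) if len(edges) else 0.0,
    )


# ---------------------------------------------------------------------------
# Permutation control
# ---------------------------------------------------------------------------

def permute_labels(tree: ClonalTree, rng: np.random.Generator) -> ClonalTree:
    """Copy of the tree with labels uniformly permuted over labeled positions."""
    out = tree.copy()
    nodes = [nd for nd in out.preorder() if nd.label is not None]
    labels = [nd.label for nd in nodes]
    perm = rng.permutation(len(labels))
    for nd, i in zip(nodes, perm):
        nd.label = labels[i]
    return out


@dataclass
class NormalizedMetric:
    raw: float
    control_mean: Optional[float] = None
    normalized: Optional[float] = None
    n_perm: int = 0


def control_normalize(metric: Callable[[ClonalTree, ClonalTree], float],
                      R: ClonalTree, E: ClonalTree, n_perm: int = 100,
                      rng: Optional[np.random.Generator] = None,
                      seed: Optional[int] = None) -> NormalizedMetric:
    """Divide ``metric(R, E)`` by its mean over random relabelings of R.

    A degenerate control (mean 0) leaves the normalized value undefined
    (NaN), reported as such.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    raw = float(metric(R, E))
    controls = [float(metric(R, permute_labels(R, rng))) for _ in range(n_perm)]
    mean = float(np.mean(controls))
    norm = raw / mean if mean > 0 else math.nan
    return NormalizedMetric(raw, mean, norm, n_perm)


_METRIC_FUNS: dict[str, Callable[[ClonalTree, ClonalTree], float]] = {
    "RF": lambda R, E: compare_clusters(R, E)[2],
    "RF*": lambda R, E: compare_clusters(R, E, include_singletons=False)[2],
    "TD": lambda R, E: triplet_metrics(R, E)[0],
    "TED": lambda R, E: triplet_metrics(R, E)[1],
    "MD": lambda R, E: path_metrics(R, E)[0],
    "PD": lambda R, E: path_metrics(R, E)[1],
}


def full_comparison(R: ClonalTree, E: ClonalTree, n_perm: int = 100,
                    seed: Optional[int] = None) -> dict[str, NormalizedMetric]:
    """All comparison metrics, raw and control-normalized.

    FDR/FNR (and their starred variants) are already normalised and are
    reported raw only.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, NormalizedMetric] = {}
    fdr, fnr, _ = compare_clusters(R, E)
    fdrs, fnrs, _ = compare_clusters(R, E, include_singletons=False)
    out["FDR"] = NormalizedMetric(fdr)
    out["FNR"] = NormalizedMetric(fnr)
    out["FDR*"] = NormalizedMetric(fdrs)
    out["FNR*"] = NormalizedMetric(fnrs)
    for name, fn in _METRIC_FUNS.items():
        if name in ("TD", "TED") and len(R.labels()) < 3:
            continue
        out[name] = control_normalize(fn, R, E, n_perm=n_perm, rng=rng)
    return out


# ---------------------------------------------------------------------------
# Random fixture trees
# ---------------------------------------------------------------------------

def random_labeled_tree(n_labels: int, internal_label_fraction: float,
                        rng: Optional[np.random.Generator] = None,
                        seed: Optional[int] = None,
                        label_prefix: str = "s") -> ClonalTree:
    """Random induced clonal tree with a requested share of internal labels.

    A random bifurcating topology is grown over the leaf labels by sequential
    random joins; the remaining labels are then placed on distinct unlabeled
    internal nodes.  Edge lengths are uniform integers in 1..3.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_labels < 2:
        raise ValueError("need at least 2 labels")
    if not 0 <= internal_label_fraction < 1:
        raise ValueError("internal_label_fraction must lie in [0, 1)")
    n_internal = int(round(internal_label_fraction * n_labels))
    n_leaf = n_labels - n_internal
    if n_leaf < 2:
        raise ValueError("fraction leaves fewer than 2 leaf labels; infeasible")
    if n_internal > n_leaf - 1:
        raise ValueError(
            f"{n_internal} internal labels infeasible with {n_leaf} leaves")
    labels = [f"{label_prefix}{i + 1}" for i in range(n_labels)]
    order = rng.permutation(n_labels)
    leaf_labels = [labels[i] for i in order[:n_leaf]]
    internal_labels = [labels[i] for i in order[n_leaf:]]

    forest = [TreeNode(lab, float(rng.integers(1, 4))) for lab in leaf_labels]
    while len(forest) > 1:
        i, j = sorted(rng.choice(len(forest), size=2, replace=False).tolist())
        b = forest.pop(j)
        a = forest.pop(i)
        par = TreeNode(None, float(rng.integers(1, 4)))
        par.add(a)
        par.add(b)
        forest.append(par)
    root = forest[0]
    root.length = None
    tree = ClonalTree(root)

    if internal_labels:
        candidates = [nd for nd in tree.preorder() if nd.children and nd.label is None]
        picks = rng.choice(len(candidates), size=len(internal_labels), replace=False)
        for lab, i in zip(internal_labels, picks.tolist()):
            candidates[i].label = lab
    tree.validate()
    return tree
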