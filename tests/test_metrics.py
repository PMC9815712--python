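"""Tree properties and comparison metrics, including the permutation control."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonesim.metrics import (
    cluster_sets,
    compare_clusters,
    control_normalize,
    full_comparison,
    path_metrics,
    permute_labels,
    random_labeled_tree,
    restrict_to_labels,
    tree_properties,
    triplet_metrics,
    triplet_metrics_bruteforce,
)
from clonesim.trees import parse_newick, write_newick


def canon(tree):
    """Canonical form of a labeled rooted topology (isomorphism oracle)."""
    def rec(nd):
        return (nd.label or "", tuple(sorted(rec(c) for c in nd.children)))
    return rec(tree.root)


def fs(*labels):
    return frozenset(labels)


def random_pair(rng, n):
    R = random_labeled_tree(n, float(rng.choice([0.0, 0.2, 0.3])), rng=rng)
    E = permute_labels(R, rng) if rng.random() < 0.5 else \
        random_labeled_tree(n, float(rng.choice([0.0, 0.25])), rng=rng)
    return R, E


class TestClusterSets:
    def test_binary_tree(self, tree_abc):
        assert cluster_sets(tree_abc) == {fs("a"), fs("b"), fs("c"),
                                          fs("a", "b"), fs("a", "b", "c")}

    def test_labeled_internal_chain_convention(self):
        """A labeled ancestor's cluster includes its own label; the ancestor
        does not additionally contribute a singleton."""
        tree = parse_newick("(b:1)a;")
        assert cluster_sets(tree) == {fs("b"), fs("a", "b")}
        assert cluster_sets(tree, include_singletons=False) == {fs("a", "b")}

    def test_star(self, tree_star):
        assert cluster_sets(tree_star) == {fs("a"), fs("b"), fs("c"),
                                           fs("a", "b", "c")}

    def test_root_cluster_flag(self, tree_abc):
        out = cluster_sets(tree_abc, include_root_cluster=False)
        assert fs("a", "b", "c") not in out and fs("a", "b") in out

    @given(st.integers(0, 10 ** 6), st.integers(2, 12))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_cluster_laminar_family_covers_labels(self, seed, n):
        """Clusters of any tree form a laminar family whose union (and
        maximum) is the full label set."""
        rng = np.random.default_rng(seed)
        frac = 0.25 if n >= 6 else 0.0
        tree = random_labeled_tree(n, frac, rng=rng)
        clusters = cluster_sets(tree)
        labels = frozenset(tree.labels())
        assert labels in clusters
        assert frozenset().union(*clusters) == labels
        for x, y in itertools.combinations(clusters, 2):
            assert x <= y or y <= x or not (x & y)


class TestCompareClusters:
    def test_identical_trees_all_zero(self, tree_abc):
        assert compare_clusters(tree_abc, tree_abc.copy()) == (0.0, 0.0, 0.0)

    def test_swapped_cherry(self, tree_abc, tree_acb):
        fdr, fnr, rf = compare_clusters(tree_abc, tree_acb)
        assert rf == 2 and fdr == pytest.approx(1 / 5) and fnr == pytest.approx(1 / 5)

    def test_star_estimate_loses_one_cluster(self, tree_abc, tree_star):
        fdr, fnr, rf = compare_clusters(tree_abc, tree_star)
        assert fdr == 0.0 and fnr == pytest.approx(1 / 5) and rf == 1

    def test_label_mismatch_reported(self, tree_abc):
        other = parse_newick("((a:1,b:1):1,d:1);")
        with pytest.raises(ValueError, match="d"):
            compare_clusters(tree_abc, other)

    def test_rf_identity_on_random_pairs(self, rng):
        for _ in range(50):
            R, E = random_pair(rng, int(rng.integers(4, 10)))
            for inc in (True, False):
                fdr, fnr, rf = compare_clusters(R, E, include_singletons=inc)
                ce = cluster_sets(E, include_singletons=inc)
                cr = cluster_sets(R, include_singletons=inc)
                assert rf == pytest.approx(fdr * len(ce) + fnr * len(cr))


class TestTripletMetrics:
    def test_identical(self, tree_abc):
        assert triplet_metrics(tree_abc, tree_abc.copy()) == (0, 0)

    def test_swapped_cherry_single_triplet(self, tree_abc, tree_acb):
        assert triplet_metrics(tree_abc, tree_acb) == (1, 2)

    def test_star_versus_resolved(self, tree_abc, tree_star):
        assert triplet_metrics(tree_abc, tree_star) == (1, 1)

    def test_needs_three_labels(self):
        two = parse_newick("(a:1,b:1);")
        with pytest.raises(ValueError):
            triplet_metrics(two, two.copy())

    def test_ted_dominates_td(self, rng):
        for _ in range(30):
            R, E = random_pair(rng, int(rng.integers(4, 10)))
            td, ted = triplet_metrics(R, E)
            assert ted >= td

    def test_matches_bruteforce_restriction(self, rng):
        for _ in range(40):
            R, E = random_pair(rng, int(rng.integers(4, 12)))
            assert triplet_metrics(R, E) == triplet_metrics_bruteforce(R, E)

    def test_restriction_keeps_only_requested_labels(self, rng):
        t = random_labeled_tree(8, 0.25, rng=rng)
        keep = set(sorted(t.labels())[:3])
        sub = restrict_to_labels(t, keep)
        assert set(sub.labels()) == keep


class TestPathMetrics:
    def test_identical(self, tree_abc):
        assert path_metrics(tree_abc, tree_abc.copy()) == (0, 0)

    def test_ancestor_versus_sibling_placement(self):
        R = parse_newick("(b:1)a;")           # a is b's parent
        E = parse_newick("(a:1,b:1);")        # siblings under unlabeled root
        md, pd = path_metrics(R, E)
        assert md == 1 and pd == 1

    def test_pd_symmetry(self, rng):
        for _ in range(20):
            R, E = random_pair(rng, int(rng.integers(4, 9)))
            assert path_metrics(R, E)[1] == path_metrics(E, R)[1]


class TestZeroIffIsomorphic:
    def test_all_metrics_zero_iff_label_isomorphic(self, rng):
        n_checked_equal = 0
        for _ in range(200):
            n = int(rng.integers(3, 12))
            R, E = random_pair(rng, n)
            fdr, fnr, rf = compare_clusters(R, E)
            td, ted = triplet_metrics(R, E)
            md, pd = path_metrics(R, E)
            zero = (fdr == fnr == rf == td == ted == md == pd == 0)
            iso = canon(R) == canon(E)
            assert zero == iso
            n_checked_equal += iso
        assert 0 < n_checked_equal < 200  # both directions exercised


class TestTreeProperties:
    def test_bifurcating_leaf_labeled_tree(self):
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        p = tree_properties(tree)
        assert p.bifurcation_index == 1.0
        assert p.internal_sample_pct == 0.0

    def test_star_properties(self):
        n = 6
        tree = parse_newick("(" + ",".join(f"s{i}:1" for i in range(n)) + ");")
        p = tree_properties(tree)
        assert p.bifurcation_index == pytest.approx(1 / (n - 1))
        assert p.balance_cherry == pytest.approx(n / 2)

    def test_caterpillar_depths_and_unit_branches(self):
        tree = parse_newick("(((a:1,b:1):1,c:1):1,d:1);")
        p = tree_properties(tree)
        assert p.sample_depth == pytest.approx((3 + 3 + 2 + 1) / 4)
        assert p.single_mutation_branch_pct == 100.0
        assert p.accumulated_mutations_sum == 6.0
        assert p.mutations_per_branch == 1.0

    def test_internal_sample_percentage(self):
        tree = parse_newick("((b:1,c:1)a:1,d:1);")
        p = tree_properties(tree)
        assert p.internal_sample_pct == pytest.approx(25.0)

    def test_needs_two_labels(self):
        with pytest.raises(ValueError):
            tree_properties(parse_newick("(a:1);"))


class TestControlNormalization:
    def test_identical_estimate_normalizes_to_zero(self, rng):
        R = random_labeled_tree(8, 0.2, rng=rng)
        m = control_normalize(lambda r, e: compare_clusters(r, e)[2], R, R.copy(),
                              n_perm=20, rng=rng)
        assert m.raw == 0.0 and m.normalized == 0.0

    def test_permuted_estimate_near_one(self, rng):
        """A random relabeling should score ~1 after control normalization."""
        vals = []
        for _ in range(60):
            R = random_labeled_tree(10, 0.0, rng=rng)
            E = permute_labels(R, rng)
            m = control_normalize(lambda r, e: compare_clusters(r, e)[2], R, E,
                                  n_perm=20, rng=rng)
            vals.append(m.normalized)
        assert 0.8 <= float(np.mean(vals)) <= 1.2

    def test_full_comparison_reports_fdr_fnr_raw_only(self, tree_abc, tree_acb):
        rep = full_comparison(tree_abc, tree_acb, n_perm=10, seed=0)
        assert rep["FDR"].control_mean is None and rep["FNR"].control_mean is None
        assert rep["RF"].control_mean is not None
        assert rep["FDR"].raw == pytest.approx(1 / 5)

    def test_seeded_reproducibility(self, tree_abc, tree_acb):
        a = full_comparison(tree_abc, tree_acb, n_perm=25, seed=7)
        b = full_comparison(tree_abc, tree_acb, n_perm=25, seed=7)
        assert all(a[k].normalized == b[k].normalized for k in a)


class TestRandomLabeledTree:
    def test_fraction_zero_all_labels_at_leaves(self, rng):
        t = random_labeled_tree(10, 0.0, rng=rng)
        assert all(not nd.children for nd in t.nodes() if nd.label)

    def test_same_seed_identical(self):
        a = random_labeled_tree(9, 0.3, seed=5)
        b = random_labeled_tree(9, 0.3, seed=5)
        assert write_newick(a) == write_newick(b)

    def test_requested_internal_fraction(self, rng):
        t = random_labeled_tree(10, 0.4, rng=rng)
        internal = sum(1 for nd in t.nodes() if nd.label and nd.children)
        assert internal == 4

    def test_infeasible_fraction_rejected(self):
        with pytest.raises(ValueError):
            random_labeled_tree(3, 0.9, seed=0)

    def test_thousand_draws_satisfy_invariants(self):
        rng = np.random.default_rng(31)
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            frac = float(rng.uniform(0, 0.45))
            if round(frac * n) > n - round(frac * n) - 1:
                continue
            t = random_labeled_tree(n, frac, rng=rng)
            t.validate()
            assert len(t.labels()) == n
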