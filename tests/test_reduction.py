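"""Re-rooting, forced-1 sets, component partition and site solvability."""

import numpy as np
import pytest

import delpars as dp
from delpars.errors import DelparsError
from conftest import random_instance, solution_key_set


def test_reroot_at_root_is_identity(demo):
    tree, _ = demo
    assert dp.reroot(tree, tree.root) is tree


def test_reroot_unknown_target_rejected(demo):
    tree, _ = demo
    with pytest.raises(DelparsError):
        dp.reroot(tree, "nope")
    with pytest.raises(DelparsError):
        dp.reroot(tree, ("a", "r"))  # reversed orientation is not an edge


def test_reroot_preserves_leafset_and_undirected_topology(demo):
    tree, _ = demo
    for target in tree.nodes:
        rt = dp.reroot(tree, target)
        assert set(rt.nodes) == set(tree.nodes)
        undirected = {frozenset(e) for e in tree.edges}
        assert {frozenset(e) for e in rt.edges} == undirected


def test_reroot_preserves_extension_cost_exactly(demo_solved):
    tree, aln, state, sols = demo_solved
    ext = sols.extensions[0]
    for target in tree.nodes:
        assert dp.extension_cost(dp.reroot(tree, target), ext) == sols.cost
    # edge subdivision adds a node; give it an all-1 row (no new deletions
    # on either half unless the subdivided edge had events at its midpoint).
    rng = np.random.default_rng(61)
    for _ in range(30):
        t, a = random_instance(rng)
        s = dp.bottom_up_pass(t, a)
        e = dp.top_down_single(t, s, a.m)
        c = dp.extension_cost(t, e)
        for target in t.nodes:
            assert dp.extension_cost(dp.reroot(t, target), e) == c


def test_forced_one_sets(demo):
    tree, aln = demo
    fn, fe = dp.forced_one_nodes(tree, aln)
    # a site where every leaf is 1 forces every node
    assert fn[4] == set(tree.nodes)
    # site 9: leaves a, c, d carry 1 -> spanning subtree contains r, x, y
    assert {"r", "x", "y"} <= fn[9] and "b" not in fn[9]
    assert ("x", "b") not in fe[9]


def test_forced_one_single_leaf():
    tree = dp.parse_newick("((a,b)u,c)r;")
    mat = np.array(
        [[1, 1, 1], [1, 0, 1], [1, 0, 1]], dtype=np.uint8
    )
    aln = dp.BinaryAlignment(["a", "b", "c"], mat)
    fn, fe = dp.forced_one_nodes(tree, aln)
    assert fn[1] == {"a"}
    assert fe[1] == set()


def test_forced_nodes_hold_in_every_candidate():
    rng = np.random.default_rng(62)
    for _ in range(20):
        tree, aln = random_instance(rng, max_m=4)
        fn, _ = dp.forced_one_nodes(tree, aln)
        for ext in dp.brute_force_candidates(tree, aln):
            for site, nodes in fn.items():
                for v in nodes:
                    assert ext.row(v)[site] == 1


def test_singleton_component_and_row_run_linking():
    tree = dp.parse_newick("((a,b)u,c)r;")
    mat = np.array(
        [[1, 0, 1, 1, 1], [1, 1, 1, 1, 1], [1, 1, 1, 1, 1]], dtype=np.uint8
    )
    aln = dp.BinaryAlignment(["a", "b", "c"], mat)
    part = dp.partition_components(tree, aln)
    assert part.blocks == [frozenset({("a", 1)})]
    # a row run spanning sites 2-3 merges anything touching sites 2 and 3
    mat2 = np.array(
        [[1, 1, 0, 0, 1], [1, 0, 1, 1, 1], [1, 1, 1, 0, 1]], dtype=np.uint8
    )
    aln2 = dp.BinaryAlignment(["a", "b", "c"], mat2)
    part2 = dp.partition_components(tree, aln2)
    spanning = [b for b in part2.blocks if {("a", 2), ("a", 3)} <= b]
    assert len(spanning) == 1
    assert ("c", 3) in spanning[0]


def test_all_one_separator_column_splits_components():
    """Two gapped blocks separated by an all-1 column stay in different
    components: every node is forced to 1 at the separator."""
    tree = dp.parse_newick("((a,b)u,(c,d)v)r;")
    rows = {
        "a": [1, 0, 0, 1, 1, 1, 1],
        "b": [1, 0, 1, 1, 0, 1, 1],
        "c": [1, 1, 0, 1, 0, 0, 1],
        "d": [1, 1, 1, 1, 1, 0, 1],
    }
    aln = dp.BinaryAlignment(list(rows), np.array(list(rows.values()), dtype=np.uint8))
    part = dp.partition_components(tree, aln)
    left = {ch for b in part.blocks for ch in b if ch[1] <= 2}
    right = {ch for b in part.blocks for ch in b if ch[1] >= 4}
    for b in part.blocks:
        assert not (b & left and b & right)


def test_demo_sites_all_entirely_solvable(demo):
    tree, aln = demo
    classes = dp.classify_sites(tree, aln)
    gapped = {
        s
        for t in aln.taxa
        for s in range(1, aln.m + 1)
        if aln.row(t)[s] == 0
    }
    assert set(classes) == gapped
    assert set(classes.values()) == {"entirely_solvable"}


def test_cherry_opposite_gaps_not_solvable():
    tree = dp.parse_newick("(x,y)r;")
    aln = dp.BinaryAlignment(
        ["x", "y"], np.array([[1, 1, 0, 1], [1, 0, 1, 1]], dtype=np.uint8)
    )
    classes = dp.classify_sites(tree, aln)
    assert classes == {1: "not_solvable", 2: "not_solvable"}


def test_gapless_alignment_has_empty_classification():
    tree = dp.parse_newick("(a,b)r;")
    aln = dp.BinaryAlignment(["a", "b"], np.ones((2, 5), dtype=np.uint8))
    assert dp.classify_sites(tree, aln) == {}


def test_class_counts_partition_gapped_sites():
    rng = np.random.default_rng(63)
    for _ in range(30):
        tree, aln = random_instance(rng)
        classes = dp.classify_sites(tree, aln)
        gapped = {
            s
            for t in aln.taxa
            for s in range(1, aln.m + 1)
            if aln.row(t)[s] == 0
        }
        assert set(classes) == gapped


def test_solvable_component_solves_as_deletion_only():
    """Re-rooting at a declared witness and solving the restriction of the
    alignment to the component's sites yields deletion-only optima."""
    rng = np.random.default_rng(64)
    checked = 0
    for _ in range(40):
        tree, aln = random_instance(rng)
        part = dp.partition_components(tree, aln)
        dp.classify_sites(tree, aln, part)
        for sites, ok, wit in zip(part.sites, part.solvable, part.witnesses):
            if not ok:
                continue
            cols = [0] + sorted(sites) + [aln.m + 1]
            sub = dp.BinaryAlignment(
                list(aln.taxa),
                aln.matrix[:, cols],
            )
            rt = dp.reroot(tree, wit)
            state = dp.bottom_up_pass(rt, sub)
            sols = dp.top_down_enumerate(rt, state, sub.m)
            for ext in sols.extensions:
                valid, _ = dp.is_deletion_only_candidate(rt, ext)
                assert valid
            checked += 1
    assert checked > 10
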