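"""Indel sweep against an exhaustive interval oracle, plus validators."""

import itertools

import numpy as np
import pytest

import delpars as dp
from delpars.errors import DelparsError
from conftest import random_instance


def oracle_indels(u, v):
    """Independent oracle: test every interval for the three endpoint/
    exclusion conditions and keep the maximal ones."""

    def events(a, b, kind):
        n = len(a)
        ok = []
        for i in range(n):
            for j in range(i, n):
                if (a[i], b[i]) != (1, 0) or (a[j], b[j]) != (1, 0):
                    continue
                if any((a[k], b[k]) == (1, 1) for k in range(i, j + 1)):
                    continue
                ok.append((i, j))
        maximal = [
            (i, j)
            for (i, j) in ok
            if not any((p <= i and j <= q and (p, q) != (i, j)) for p, q in ok)
        ]
        return [(kind, i, j) for i, j in maximal]

    evs = events(u, v, "deletion") + events(v, u, "insertion")
    return sorted(evs, key=lambda e: (e[1], e[0] != "deletion"))


def test_printed_example_rows():
    u = np.array([1, 1, 0, 0, 1, 1, 1, 1], dtype=np.uint8)
    v = np.array([1, 0, 0, 1, 0, 1, 0, 1], dtype=np.uint8)
    got = [(e.kind, e.start, e.end) for e in dp.indels_between(u, v)]
    assert got == [("deletion", 1, 4), ("insertion", 3, 3), ("deletion", 6, 6)]
    assert dp.unit_cost_distance(u, v) == 3


def test_sweep_matches_exhaustive_oracle_on_all_short_rows():
    """Every pair of flanked rows of total length 8 agrees with the oracle,
    and the distance is symmetric and zero exactly on equal rows."""
    interiors = list(itertools.product([0, 1], repeat=6))
    rows = [np.array((1,) + t + (1,), dtype=np.uint8) for t in interiors]
    for u in rows:
        for v in rows:
            got = [(e.kind, e.start, e.end) for e in dp.indels_between(u, v)]
            assert got == oracle_indels(u.tolist(), v.tolist())
            d = len(got)
            assert d == dp.unit_cost_distance(v, u)
            assert (d == 0) == bool(np.array_equal(u, v))


def test_deletions_from_full_row_are_the_zero_runs():
    rng = np.random.default_rng(11)
    for _ in range(50):
        m = int(rng.integers(1, 10))
        v = np.ones(m + 2, dtype=np.uint8)
        v[1:-1] = rng.integers(0, 2, size=m)
        u = np.ones_like(v)
        evs = dp.indels_between(u, v)
        assert all(e.kind == "deletion" for e in evs)
        assert [(e.start, e.end) for e in evs] == list(
            dp.to_gap_form(dp.BinaryAlignment(["v"], v[None, :])).gaps["v"]
        )


def test_row_length_mismatch_rejected():
    with pytest.raises(DelparsError, match="mismatch"):
        dp.unit_cost_distance(np.ones(4, dtype=np.uint8), np.ones(5, dtype=np.uint8))


def test_extension_cost_sums_edges(demo_solved):
    tree, aln, state, sols = demo_solved
    ext = sols.extensions[0]
    assert dp.extension_cost(tree, ext) == 8
    # independent per-edge summation
    total = sum(
        len(oracle_indels(ext.row(p).tolist(), ext.row(w).tolist()))
        for p, w in tree.edges
    )
    assert total == 8


def test_extension_cost_all_one_internals(demo):
    tree, aln = demo
    taxa = list(tree.preorder())
    mat = np.ones((len(taxa), aln.m + 2), dtype=np.uint8)
    for i, t in enumerate(taxa):
        if tree.is_leaf(t):
            mat[i] = aln.row(t)
    ext = dp.BinaryAlignment(taxa, mat)
    expected = sum(
        len(oracle_indels(ext.row(p).tolist(), ext.row(w).tolist()))
        for p, w in tree.edges
    )
    assert dp.extension_cost(tree, ext) == expected


def test_missing_node_row_rejected(demo):
    tree, aln = demo
    with pytest.raises(DelparsError, match="lacks rows"):
        dp.extension_cost(tree, aln)


def test_phylogenetic_correctness_detects_separated_ones():
    tree = dp.parse_newick("(a,(b,(c,d)y)x)r;")
    taxa = list(tree.preorder())
    mat = np.ones((len(taxa), 3), dtype=np.uint8)
    mat[taxa.index("x"), 1] = 0  # r=1, x=0, y=1 separates root from y
    ext = dp.BinaryAlignment(taxa, mat)
    ok, witness = dp.is_phylogenetically_correct(tree, ext)
    assert not ok and witness[0] == 1
    ok2, _ = dp.is_phylogenetically_correct(
        tree, dp.BinaryAlignment(taxa, np.ones((len(taxa), 3), dtype=np.uint8))
    )
    assert ok2


def test_deletion_only_validator(demo_solved):
    tree, aln, state, sols = demo_solved
    for ext in sols.extensions:
        ok, _ = dp.is_deletion_only_candidate(tree, ext, aln)
        assert ok
        assert dp.is_phylogenetically_correct(tree, ext)[0]
    # a 0 -> 1 transition down an edge is flagged
    bad = sols.extensions[0].matrix.copy()
    taxa = list(sols.extensions[0].taxa)
    site = 2
    bad[taxa.index("x"), site] = 0
    bad[taxa.index("y"), site] = 1
    ok, witness = dp.is_deletion_only_candidate(
        tree, dp.BinaryAlignment(taxa, bad)
    )
    assert not ok
    # a root row with a 0 is flagged
    bad2 = sols.extensions[0].matrix.copy()
    bad2[taxa.index("r"), 3] = 0
    bad2[taxa.index("x"), 3] = 0
    bad2[taxa.index("y"), 3] = 0
    ok2, w2 = dp.is_deletion_only_candidate(tree, dp.BinaryAlignment(taxa, bad2))
    assert not ok2 and w2[1] == ("r", "r")


def test_deletion_intervals_never_contain_both_present_columns():
    rng = np.random.default_rng(5)
    for _ in range(100):
        tree, aln = random_instance(rng)
        state = dp.bottom_up_pass(tree, aln)
        ext = dp.top_down_single(tree, state, aln.m)
        for p, w in tree.edges:
            ru, rv = ext.row(p), ext.row(w)
            for e in dp.indels_between(ru, rv):
                seg = slice(e.start, e.end + 1)
                assert not np.any((ru[seg] == 1) & (rv[seg] == 1))
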