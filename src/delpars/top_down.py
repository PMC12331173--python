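"""Top-down phase: resolve choices and materialize optimal extensions.

Nodes are visited in pre-order, so a node's parent is fully resolved (only
0-gaps) when the node is processed.  For each stored gap of node ``w`` with
parent ``p``:

* a C-gap whose exact interval is a 0-gap at ``p`` is reset to a 0-gap (both
  of its outcomes coincide there);
* any other C-gap branches the current partial solution: one branch resets
  it to a 0-gap, the other replaces it by the 0-gaps of ``p`` that lie
  inside the interval (i.e. copies the parent's pattern);
* a P-gap always copies the parent's 0-gaps inside its interval.

Because no labeled gap ever partially overlaps one of its parent's, copying
the parent's 0-gaps inside the interval reproduces the parent's pattern
exactly.  Exhausting all branch combinations enumerates every optimal
solution; always taking the "reset" branch yields a single optimum in
polynomial time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import BinaryAlignment, Interval
from .bottom_up import GapLabel, LabeledState
from .errors import DelparsError, EnumerationOverflowError, InternalConsistencyError
from .tree import Tree

__all__ = ["SolutionSet", "top_down_enumerate", "top_down_single", "project_node"]

DEFAULT_SOLUTION_CAP = 10**6


@dataclass
class SolutionSet:
    """All optimal extensions of one instance.

    Attributes
    ----------
    extensions:
        Distinct optimal extensions, one row per tree node, in the
        deterministic enumeration order (pre-order nodes, gaps left to
        right, "reset" branch before "copy parent").
    cost:
        The common total deletion count.
    s:
        Number of distinct solutions (``len(extensions)``).
    c_gaps:
        Number of C-gaps produced by the bottom-up phase; ``s <= 2**c_gaps``.
        ``None`` for solution sets not produced via the labeled-gap state
        (e.g. brute force).
    """

    extensions: list[BinaryAlignment]
    cost: int
    s: int
    c_gaps: int | None = None


# A resolved assignment maps each node to a sorted tuple of 0-intervals.
_Resolved = dict[str, tuple[Interval, ...]]


def _resolve_node(
    gaps, parent_zero: tuple[Interval, ...], branch_all: bool
) -> list[tuple[Interval, ...]]:
    """All resolved 0-interval tuples for one node given its parent's.

    Returns one tuple per branch combination (a single tuple when
    ``branch_all`` is false or no C-gap branches).
    """
    parent_set = set(parent_zero)
    alternatives: list[list[tuple[Interval, ...]]] = []
    for g in gaps:
        iv = (g.start, g.end)
        inside = tuple(
            z for z in parent_zero if g.start <= z[0] and z[1] <= g.end
        )
        if g.label is GapLabel.ZERO:
            alternatives.append([(iv,)])
        elif g.label is GapLabel.P:
            alternatives.append([inside])
        elif iv in parent_set:  # C-gap, rule with coinciding outcomes
            alternatives.append([(iv,)])
        elif branch_all:
            alternatives.append([(iv,), inside])
        else:
            alternatives.append([(iv,)])
    results: list[tuple[Interval, ...]] = [()]
    for alts in alternatives:
        results = [acc + choice for acc in results for choice in alts]
    return [tuple(sorted(r)) for r in results]


def _materialize(tree: Tree, m: int, resolved: _Resolved) -> BinaryAlignment:
    taxa = list(tree.preorder())
    mat = np.ones((len(taxa), m + 2), dtype=np.uint8)
    for r, w in enumerate(taxa):
        for i, j in resolved[w]:
            mat[r, i : j + 1] = 0
    return BinaryAlignment(taxa, mat)


def _run_top_down(
    tree: Tree, state: LabeledState, m: int, branch_all: bool, cap: int
) -> list[_Resolved]:
    if state.get(tree.root):
        raise InternalConsistencyError("top-down requires an empty root state")
    partials: list[_Resolved] = [{tree.root: ()}]
    for w in tree.preorder():
        if w == tree.root:
            continue
        p = tree.parent[w]
        grown: list[_Resolved] = []
        for sol in partials:
            for choice in _resolve_node(state.get(w, ()), sol[p], branch_all):
                nxt = dict(sol)
                nxt[w] = choice
                grown.append(nxt)
                if len(grown) > cap:
                    raise EnumerationOverflowError(
                        f"more than {cap} intermediate solutions; use the "
                        "site-graph representation instead"
                    )
        partials = grown
    return partials


def _count_c_gaps(state: LabeledState) -> int:
    return sum(
        1 for gaps in state.values() for g in gaps if g.label is GapLabel.C
    )


def top_down_enumerate(
    tree: Tree,
    state: LabeledState,
    m: int,
    cap: int = DEFAULT_SOLUTION_CAP,
) -> SolutionSet:
    """Enumerate every optimal solution of the deletion-only problem.

    ``state`` must come from :func:`delpars.bottom_up.bottom_up_pass` on the
    same instance; ``m`` is the interior column count.  Raises
    :class:`EnumerationOverflowError` beyond ``cap`` solutions.
    """
    from .indels import extension_cost

    resolved = _run_top_down(tree, state, m, branch_all=True, cap=cap)
    seen: set[bytes] = set()
    extensions: list[BinaryAlignment] = []
    for sol in resolved:
        ext = _materialize(tree, m, sol)
        key = ext.matrix.tobytes()
        if key not in seen:
            seen.add(key)
            extensions.append(ext)
    cost = extension_cost(tree, extensions[0])
    return SolutionSet(
        extensions=extensions,
        cost=cost,
        s=len(extensions),
        c_gaps=_count_c_gaps(state),
    )


def top_down_single(tree: Tree, state: LabeledState, m: int) -> BinaryAlignment:
    """Produce one optimal extension (the all-"reset" branch) in O(nb)."""
    resolved = _run_top_down(tree, state, m, branch_all=False, cap=2)
    assert len(resolved) == 1
    return _materialize(tree, m, resolved[0])


def project_node(solutions: SolutionSet, w: str) -> set[bytes]:
    """Distinct rows observed at node ``w`` across all optimal solutions.

    Rows are returned as bytes of the full sentinel-flanked uint8 row, which
    makes set comparisons against site-graph paths cheap and unambiguous.
    """
    if not solutions.extensions:
        raise DelparsError("empty solution set")
    if w not in solutions.extensions[0]:
        raise DelparsError(f"unknown node {w!r}")
    return {ext.row(w).tobytes() for ext in solutions.extensions}
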