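"""Bottom-up phase: labeled gaps for every node of the tree.

Walking the tree in post-order, each node accumulates a set of *labeled
gaps*: site intervals tagged

* ``0`` — necessarily a gap of this node's row in every optimal solution,
* ``P`` — the node necessarily copies its parent's pattern on the interval,
* ``C`` — a genuine binary choice between those two outcomes.

A leaf's labeled gaps are its maximal 0-runs, all tagged ``0``.  An internal
node combines every overlapping pair of labeled gaps of its two children:
the stored interval is the intersection and the tag follows the rule table

==============  =========  ======  ====
overlap          both 0/C  one P   both P
==============  =========  ======  ====
equal            0         C       P
strict nesting   C if the nested gap is not P, else P
partial          P         P       P
==============  =========  ======  ====

The intersections of two families of disjoint intervals are disjoint, so
each node's state is again a sorted disjoint interval list; a linear merge
finds all overlapping pairs.

Degree-2 pass-through nodes (which re-rooting can create) take their single
child's gaps with ``0`` relabeled ``C``: a gap certain at the child is, at
the pass-through node, exactly a choice between deleting below or above it.
The root's state is always empty when no input column is all-0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .alignment import BinaryAlignment, zero_runs
from .errors import InternalConsistencyError
from .tree import Tree

__all__ = [
    "GapLabel",
    "LabeledGap",
    "LabeledState",
    "leaf_labeled_gaps",
    "combine_pair",
    "bottom_up_pass",
    "state_to_tsv",
]


class GapLabel(enum.Enum):
    ZERO = "0"
    C = "C"
    P = "P"


@dataclass(frozen=True, order=True)
class LabeledGap:
    start: int
    end: int
    label: GapLabel = GapLabel.ZERO

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InternalConsistencyError(f"bad interval [{self.start},{self.end}]")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


#: Mapping node name -> sorted tuple of disjoint labeled gaps.
LabeledState = dict[str, tuple[LabeledGap, ...]]


def leaf_labeled_gaps(row: np.ndarray) -> tuple[LabeledGap, ...]:
    """Maximal 0-runs of a leaf row, each labeled ``0``."""
    return tuple(LabeledGap(i, j, GapLabel.ZERO) for i, j in zero_runs(row))


def combine_pair(gu: LabeledGap, gv: LabeledGap) -> LabeledGap | None:
    """Combine one labeled gap from each child; ``None`` if they are disjoint."""
    lo = max(gu.start, gv.start)
    hi = min(gu.end, gv.end)
    if lo > hi:
        return None
    iu, iv = gu.interval, gv.interval
    pu, pv = gu.label is GapLabel.P, gv.label is GapLabel.P
    if iu == iv:
        if not pu and not pv:
            label = GapLabel.ZERO
        elif pu and pv:
            label = GapLabel.P
        else:
            label = GapLabel.C
    elif lo == gu.start and hi == gu.end:  # gu strictly inside gv
        label = GapLabel.P if pu else GapLabel.C
    elif lo == gv.start and hi == gv.end:  # gv strictly inside gu
        label = GapLabel.P if pv else GapLabel.C
    else:  # partial overlap
        label = GapLabel.P
    return LabeledGap(lo, hi, label)


def _combine_children(
    left: tuple[LabeledGap, ...], right: tuple[LabeledGap, ...]
) -> tuple[LabeledGap, ...]:
    out: list[LabeledGap] = []
    i = j = 0
    while i < len(left) and j < len(right):
        g = combine_pair(left[i], right[j])
        if g is not None:
            out.append(g)
        if left[i].end < right[j].end:
            i += 1
        else:
            j += 1
    return tuple(out)


def bottom_up_pass(tree: Tree, aln: BinaryAlignment) -> LabeledState:
    """Compute the labeled-gap state of every node, leaves included."""
    leaf_set = set(tree.leaves)
    aln_rows = set(aln.taxa)
    extra = aln_rows - leaf_set
    # A tree rerooted at a former leaf keeps that taxon's row: the root is
    # forced all-1 in every candidate, so the row is only sanity-checked.
    if extra == {tree.root} and not tree.is_leaf(tree.root):
        if not bool(np.all(aln.row(tree.root) == 1)):
            from .errors import LeafMismatchError

            raise LeafMismatchError(
                f"row for root {tree.root!r} must be all-1 in the "
                "deletion-only model"
            )
        extra = set()
        aln_rows = aln_rows - {tree.root}
    if leaf_set != aln_rows or extra:
        from .errors import LeafMismatchError

        raise LeafMismatchError(
            f"tree leaves and alignment rows differ: "
            f"only-in-tree={sorted(leaf_set - aln_rows)} "
            f"only-in-alignment={sorted(extra | (aln_rows - leaf_set))}"
        )
    state: LabeledState = {}
    for w in tree.postorder():
        if tree.is_leaf(w):
            state[w] = leaf_labeled_gaps(aln.row(w))
            continue
        kids = tree.children[w]
        if len(kids) == 1:
            # Pass-through node: certain gaps of the child become choices.
            state[w] = tuple(
                LabeledGap(
                    g.start,
                    g.end,
                    GapLabel.C if g.label is GapLabel.ZERO else g.label,
                )
                for g in state[kids[0]]
            )
        else:
            state[w] = _combine_children(state[kids[0]], state[kids[1]])
    if state[tree.root]:
        if len(tree.children[tree.root]) == 1:
            # A degree-2 root is all-1 at every site in every candidate
            # (every column has a 1-leaf below it), so it has no gaps.
            state[tree.root] = ()
        else:
            raise InternalConsistencyError(
                "root has labeled gaps; the input alignment must contain an "
                "all-0 column that escaped validation"
            )
    return state


def state_to_tsv(state: LabeledState, tree: Tree) -> str:
    """Debug dump: node, start, end, label — nodes in pre-order."""
    lines = ["node\tstart\tend\tlabel"]
    for w in tree.preorder():
        for g in state.get(w, ()):
            lines.append(f"{w}\t{g.start}\t{g.end}\t{g.label.value}")
    return "\n".join(lines) + "\n"
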