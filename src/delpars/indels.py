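"""Indel events between aligned rows, costs and candidate validation.

Between two sentinel-flanked binary rows ``u`` (parent side) and ``v`` (child
side), a *deletion* is a maximal interval ``[i, j]`` whose endpoints show the
column pattern (1, 0), that contains no (1, 1) column; an *insertion* is the
symmetric notion with (0, 1).  A single event may bridge sites where both
rows are 0, which is what lets one deletion remove characters that are
consecutive in the ancestral sequence even when the alignment interleaves
them with older gaps.  The number of such events is the unit-cost distance
``d(u, v)``; each event costs 1 regardless of its length.

The sweep below segments the site axis at (1, 1) columns (the sentinels are
always (1, 1)), then emits at most one deletion and one insertion per
segment, which realizes maximality directly in O(m) per row pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DelparsError
from .tree import Tree
from .alignment import BinaryAlignment

__all__ = [
    "Indel",
    "indels_between",
    "unit_cost_distance",
    "extension_cost",
    "is_phylogenetically_correct",
    "is_deletion_only_candidate",
    "indels_to_tsv",
]


@dataclass(frozen=True)
class Indel:
    """A typed indel event at a closed site interval, optionally on an edge."""

    kind: Literal["deletion", "insertion"]
    start: int
    end: int
    edge: tuple[str, str] | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _check_rows(row_u: np.ndarray, row_v: np.ndarray) -> None:
    if row_u.shape != row_v.shape:
        raise DelparsError(
            f"row length mismatch: {row_u.shape[0]} vs {row_v.shape[0]}"
        )
    for row in (row_u, row_v):
        if row[0] != 1 or row[-1] != 1:
            raise DelparsError("rows must carry all-1 sentinel sites at both ends")


def indels_between(row_u: np.ndarray, row_v: np.ndarray) -> list[Indel]:
    """All indels from ``row_u`` to ``row_v``, sorted by start site.

    Within each maximal run of columns free of the (1, 1) pattern, the
    deletion (if any) spans the first to the last (1, 0) column, and the
    insertion spans the first to the last (0, 1) column.  At equal start
    sites the deletion is listed first.
    """
    row_u = np.asarray(row_u, dtype=np.uint8)
    row_v = np.asarray(row_v, dtype=np.uint8)
    _check_rows(row_u, row_v)
    both_one = (row_u == 1) & (row_v == 1)
    events: list[Indel] = []
    k = 0
    n = row_u.shape[0]
    while k < n:
        if both_one[k]:
            k += 1
            continue
        seg_start = k
        while k < n and not both_one[k]:
            k += 1
        seg = slice(seg_start, k)
        del_pos = np.flatnonzero((row_u[seg] == 1) & (row_v[seg] == 0)) + seg_start
        ins_pos = np.flatnonzero((row_u[seg] == 0) & (row_v[seg] == 1)) + seg_start
        seg_events = []
        if del_pos.size:
            seg_events.append(Indel("deletion", int(del_pos[0]), int(del_pos[-1])))
        if ins_pos.size:
            seg_events.append(Indel("insertion", int(ins_pos[0]), int(ins_pos[-1])))
        seg_events.sort(key=lambda e: (e.start, e.kind != "deletion"))
        events.extend(seg_events)
    return events


def unit_cost_distance(row_u: np.ndarray, row_v: np.ndarray) -> int:
    """Number of indels between two rows (symmetric, zero iff equal)."""
    return len(indels_between(row_u, row_v))


def edge_indels(tree: Tree, ext: BinaryAlignment) -> list[Indel]:
    """Indels of every tree edge of a full extension, with edges attached."""
    events: list[Indel] = []
    for p, w in tree.edges:
        for e in indels_between(ext.row(p), ext.row(w)):
            events.append(Indel(e.kind, e.start, e.end, edge=(p, w)))
    return events


def extension_cost(tree: Tree, ext: BinaryAlignment) -> int:
    """Total indel count of an extension: sum of d over all tree edges."""
    missing = [v for v in tree.nodes if v not in ext]
    if missing:
        raise DelparsError(f"extension lacks rows for nodes: {missing}")
    return sum(
        unit_cost_distance(ext.row(p), ext.row(w)) for p, w in tree.edges
    )


def is_phylogenetically_correct(
    tree: Tree, ext: BinaryAlignment
) -> tuple[bool, tuple[int, tuple[str, str]] | None]:
    """Check that, per site, the nodes carrying 1 form a connected subtree.

    Returns ``(True, None)`` or ``(False, (site, (u, v)))`` where ``u`` and
    ``v`` carry 1 at ``site`` but are separated by a 0 node.
    """
    order = list(tree.preorder())
    for site in range(1, ext.m + 1):
        ones = {v for v in order if ext.row(v)[site] == 1}
        if not ones:
            continue
        # Tops of connected components among the 1-nodes.
        tops = [
            v
            for v in ones
            if v == tree.root or tree.parent[v] not in ones
        ]
        if len(tops) > 1:
            return False, (site, (tops[0], tops[1]))
    return True, None


def is_deletion_only_candidate(
    tree: Tree, ext: BinaryAlignment, leaf_aln: BinaryAlignment | None = None
) -> tuple[bool, tuple[int, tuple[str, str]] | None]:
    """Check the deletion-only constraint on a full extension.

    A valid candidate has an all-1 root row and per-site values that never
    increase along any root-to-leaf edge (equivalently: every per-edge indel
    is a deletion).  If ``leaf_aln`` is given, the extension must agree with
    it on every leaf row (a mismatch is an error, not a ``False``).

    Returns ``(True, None)`` or ``(False, (site, (parent, child)))``; a root
    violation is reported with the pseudo-edge ``(root, root)``.
    """
    if leaf_aln is not None:
        for leaf in tree.leaves:
            if not np.array_equal(ext.row(leaf), leaf_aln.row(leaf)):
                raise DelparsError(f"extension does not agree with leaf row {leaf!r}")
    root_row = ext.row(tree.root)
    zeros = np.flatnonzero(root_row[1:-1] == 0)
    if zeros.size:
        return False, (int(zeros[0]) + 1, (tree.root, tree.root))
    for p, w in tree.edges:
        gained = np.flatnonzero((ext.row(p) == 0) & (ext.row(w) == 1))
        if gained.size:
            return False, (int(gained[0]), (p, w))
    return True, None


def indels_to_tsv(events: list[Indel]) -> str:
    """TSV export: parent, child, kind, start, end (1-based, closed)."""
    lines = ["parent\tchild\tkind\tstart\tend"]
    for e in events:
        p, w = e.edge if e.edge else ("", "")
        lines.append(f"{p}\t{w}\t{e.kind}\t{e.start}\t{e.end}")
    return "\n".join(lines) + "\n"
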