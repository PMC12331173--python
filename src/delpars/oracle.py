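"""Brute-force enumeration of candidate and optimal solutions.

This module is deliberately independent of the bottom-up/top-down solver:
it enumerates, site by site, every monotone 0/1 assignment of the internal
nodes (a value may only drop along a root-to-leaf path, and the root is 1),
takes the Cartesian product over sites, and scores every resulting full
extension with the per-edge indel sweep.  Costs couple sites — one deletion
can span several — so scoring happens on full extensions, never per site.

It is exponential and guarded, usable only on small instances; its role is
to certify the polynomial machinery on them.
"""

from __future__ import annotations

import itertools
from typing import Iterator

import numpy as np

from .alignment import BinaryAlignment
from .errors import DelparsError
from .indels import extension_cost
from .top_down import SolutionSet
from .tree import Tree

__all__ = ["brute_force_candidates", "brute_force_optima", "DEFAULT_GUARD"]

DEFAULT_GUARD = 10**6


def _site_assignments(tree: Tree, leaf_values: dict[str, int]) -> list[dict[str, int]]:
    """All monotone assignments of one site: root=1, child <= parent."""

    def expand(v: str, parent_val: int) -> list[dict[str, int]]:
        if tree.is_leaf(v):
            val = leaf_values[v]
            if val > parent_val:
                return []
            return [{v: val}]
        choices = [1] if v == tree.root else ([0] if parent_val == 0 else [0, 1])
        out: list[dict[str, int]] = []
        for val in choices:
            sub_lists: list[list[dict[str, int]]] = []
            for c in tree.children[v]:
                subs = expand(c, val)
                if not subs:
                    break
                sub_lists.append(subs)
            else:
                for combo in itertools.product(*sub_lists):
                    merged = {v: val}
                    for d in combo:
                        merged.update(d)
                    out.append(merged)
        return out

    return expand(tree.root, 1)


def brute_force_candidates(
    tree: Tree, aln: BinaryAlignment, guard: int = DEFAULT_GUARD
) -> Iterator[BinaryAlignment]:
    """Stream every deletion-only candidate extension of the instance.

    Raises :class:`DelparsError` when the product of per-site assignment
    counts exceeds ``guard``.
    """
    aln.validate_columns()
    taxa = list(tree.preorder())
    m = aln.m
    per_site: list[list[dict[str, int]]] = []
    total = 1
    for site in range(1, m + 1):
        leaf_values = {leaf: int(aln.row(leaf)[site]) for leaf in tree.leaves}
        assigns = _site_assignments(tree, leaf_values)
        if not assigns:
            raise DelparsError(f"site {site} admits no monotone assignment")
        total *= len(assigns)
        if total > guard:
            raise DelparsError(
                f"candidate count exceeds guard ({total} > {guard})"
            )
        per_site.append(assigns)

    for combo in itertools.product(*per_site):
        mat = np.ones((len(taxa), m + 2), dtype=np.uint8)
        for site_idx, assign in enumerate(combo, start=1):
            for r, t in enumerate(taxa):
                mat[r, site_idx] = assign[t]
        yield BinaryAlignment(list(taxa), mat)


def brute_force_optima(
    tree: Tree, aln: BinaryAlignment, guard: int = DEFAULT_GUARD
) -> SolutionSet:
    """Minimum-cost candidates, found by exhaustive scoring."""
    best_cost: int | None = None
    best: list[BinaryAlignment] = []
    seen: set[bytes] = set()
    for ext in brute_force_candidates(tree, aln, guard):
        cost = extension_cost(tree, ext)
        if best_cost is None or cost < best_cost:
            best_cost = cost
            best = [ext]
            seen = {ext.matrix.tobytes()}
        elif cost == best_cost:
            key = ext.matrix.tobytes()
            if key not in seen:
                seen.add(key)
                best.append(ext)
    if best_cost is None:
        raise DelparsError("instance admits no candidate solution")
    return SolutionSet(extensions=best, cost=best_cost, s=len(best))
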