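"""Per-node site graphs: a compact view of all optimal reconstructions.

For every internal node ``w`` the construction builds a directed acyclic
graph on the sites ``0..m+1`` whose 0→(m+1) paths are exactly the rows that
``w`` can take in an optimal solution: a path visiting vertex set ``V``
corresponds to the row with 1 at the sites of ``V`` and 0 elsewhere.  This
avoids enumerating the (possibly exponentially many) solutions while still
representing each of them individually — the same idea as the partial order
graphs used to summarize ancestral protein reconstructions.

Construction is a pre-order pass.  The root graph is the chain of arcs
(k, k+1).  For any other node, sites untouched by labeled gaps keep their
chain arcs; a 0-gap [i, j] contributes the single bypass arc (i-1, j+1); a
P-gap copies all parent arcs lying inside [i-1, j+1]; a C-gap does both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bottom_up import GapLabel, LabeledState
from .errors import EnumerationOverflowError, InternalConsistencyError
from .tree import Tree

__all__ = ["SiteGraph", "build_site_graphs", "count_paths", "enumerate_paths"]


@dataclass
class SiteGraph:
    """DAG on vertex set ``[0, m+1]`` with strictly increasing arcs."""

    owner: str
    m: int
    arcs: frozenset[tuple[int, int]]
    _succ: dict[int, tuple[int, ...]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for h, k in self.arcs:
            if not (0 <= h < k <= self.m + 1):
                raise InternalConsistencyError(f"bad arc ({h},{k})")
        succ: dict[int, list[int]] = {}
        for h, k in sorted(self.arcs):
            succ.setdefault(h, []).append(k)
        self._succ = {h: tuple(ks) for h, ks in succ.items()}

    def successors(self, v: int) -> tuple[int, ...]:
        return self._succ.get(v, ())

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.m + 2))
        g.add_edges_from(self.arcs)
        return g

    def is_planar(self) -> bool:
        import networkx as nx

        ok, _ = nx.check_planarity(self.to_networkx().to_undirected())
        return bool(ok)

    def to_dot(self) -> str:
        lines = [
            f'digraph "{self.owner}" {{',
            "  rankdir=LR;",
            "  node [shape=circle];",
        ]
        for v in range(self.m + 2):
            lines.append(f"  {v};")
        for h, k in sorted(self.arcs):
            lines.append(f"  {h} -> {k};")
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_tsv(self) -> str:
        lines = ["node\tfrom\tto"]
        for h, k in sorted(self.arcs):
            lines.append(f"{self.owner}\t{h}\t{k}")
        return "\n".join(lines) + "\n"


def build_site_graphs(tree: Tree, state: LabeledState, m: int) -> dict[str, SiteGraph]:
    """Site graph of every internal node (pre-order construction).

    ``state`` must come from the bottom-up phase on the same instance and
    ``m`` is the interior column count.  The graphs replace the top-down
    phase and are computable in polynomial time regardless of the number of
    optimal solutions.
    """
    graphs: dict[str, SiteGraph] = {}
    for w in tree.preorder():
        if tree.is_leaf(w):
            continue
        if w == tree.root:
            graphs[w] = SiteGraph(w, m, frozenset((k, k + 1) for k in range(m + 1)))
            continue
        parent_graph = graphs[tree.parent[w]]
        gaps = state.get(w, ())
        covered = {s for g in gaps for s in range(g.start, g.end + 1)}
        arcs = {
            (k, k + 1)
            for k in range(m + 1)
            if k not in covered and k + 1 not in covered
        }
        for g in gaps:
            lo, hi = g.start - 1, g.end + 1
            if g.label in (GapLabel.ZERO, GapLabel.C):
                arcs.add((lo, hi))
            if g.label in (GapLabel.P, GapLabel.C):
                arcs.update(
                    (h, k) for h, k in parent_graph.arcs if lo <= h and k <= hi
                )
        graphs[w] = SiteGraph(w, m, frozenset(arcs))
    return graphs


def count_paths(g: SiteGraph) -> int:
    """Exact number of directed 0→(m+1) paths (arbitrary-precision)."""
    target = g.m + 1
    ways = [0] * (target + 1)
    ways[0] = 1
    for v in range(target):
        if ways[v]:
            for nxt in g.successors(v):
                ways[nxt] += ways[v]
    return ways[target]


def enumerate_paths(g: SiteGraph, limit: int = 10**5) -> list[frozenset[int]]:
    """Vertex sets of all 0→(m+1) paths, in lexicographic order.

    Each vertex set is a reconstruction: 1 exactly at its sites.  Raises
    :class:`EnumerationOverflowError` when more than ``limit`` paths exist.
    """
    total = count_paths(g)
    if total > limit:
        raise EnumerationOverflowError(
            f"{total} paths exceed limit {limit}; use count_paths instead"
        )
    target = g.m + 1
    out: list[frozenset[int]] = []
    stack: list[int] = [0]

    def dfs(v: int) -> None:
        if v == target:
            out.append(frozenset(stack))
            return
        for nxt in g.successors(v):
            stack.append(nxt)
            dfs(nxt)
            stack.pop()

    dfs(0)
    return out
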