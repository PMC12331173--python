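"""Reduction machinery from the general indel problem to the deletion-only one.

The general problem (insertions allowed) is time-reversible: re-rooting the
tree leaves the cost of every fixed extension unchanged, because the edge
set is unchanged and the unit-cost distance is symmetric.  Whenever some
point of the tree — a node, or a point subdividing an edge — is forced to
carry 1 at a set of sites in every phylogenetically correct extension,
re-rooting there makes every event at those sites a deletion, and the
deletion-only solver applies.

Forcing comes from phylogenetic correctness alone: at each site, every node
(and fully contained edge) of the minimal subtree spanning the leaves that
carry 1 must itself carry 1.

Gap characters — the (row, site) cells equal to 0 — are partitioned into
*components* that can be resolved independently.  The partition used here is
deliberately conservative (it may merge more than strictly necessary, never
less): two gap characters are linked when they share a site, or when they
sit at consecutive sites k, k+1 such that some tree node is not forced to 1
at both — i.e. some phylogenetically correct extension could carry a gap
spanning the boundary, so a single event could touch both sites.  A leaf
row whose 0-run crosses the boundary is such a node, so in particular
consecutive characters of one row's gap are always linked.  Columns where
every node is forced to 1 (e.g. all-1 input columns) cleanly separate
components.  Over-merging can only under-report solvability, never claim an
independence the model does not support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .alignment import BinaryAlignment
from .errors import DelparsError
from .tree import Tree

__all__ = [
    "reroot",
    "forced_one_nodes",
    "ComponentPartition",
    "partition_components",
    "classify_sites",
    "classification_to_tsv",
]

SiteClass = Literal["entirely_solvable", "partially_solvable", "not_solvable"]


# --------------------------------------------------------------------- reroot
def reroot(tree: Tree, target: str | tuple[str, str], new_root_name: str = "R0") -> Tree:
    """Re-root ``tree`` at a node, or on an edge via a new subdividing root.

    Every original node is kept: the old root becomes a degree-2
    pass-through node, so the undirected edge set (up to the one subdivided
    edge) and hence the cost of any fixed extension are preserved.  When
    ``target`` is an edge ``(parent, child)``, a new degree-2 root named
    ``new_root_name`` is created between the two.
    """
    if isinstance(target, tuple):
        p, w = target
        if w not in tree.parent or tree.parent[w] != p:
            raise DelparsError(f"({p!r}, {w!r}) is not an edge of the tree")
        if new_root_name in set(tree.nodes):
            raise DelparsError(f"node name {new_root_name!r} already in tree")
        children = {k: list(v) for k, v in tree.children.items()}
        children[p][children[p].index(w)] = new_root_name
        children[new_root_name] = [w]
        base = Tree(
            root=tree.root,
            children={k: tuple(v) for k, v in children.items()},
        )
        return reroot(base, new_root_name)

    if target not in set(tree.nodes):
        raise DelparsError(f"unknown node {target!r}")
    if target == tree.root:
        return tree
    # Reverse the path from target up to the old root.
    path = [target]
    while path[-1] != tree.root:
        path.append(tree.parent[path[-1]])
    children = {k: list(v) for k, v in tree.children.items()}
    for child, parent in zip(path, path[1:]):
        children[parent].remove(child)
        children.setdefault(child, []).insert(0, parent)
    new_children = {k: tuple(v) for k, v in children.items() if v}
    return Tree(root=target, children=new_children)


# ----------------------------------------------------------------- forced 1s
def forced_one_nodes(
    tree: Tree, aln: BinaryAlignment
) -> tuple[dict[int, set[str]], dict[int, set[tuple[str, str]]]]:
    """Per site, the nodes and edges forced to 1 by phylogenetic correctness.

    Site ``k``'s forced set is the minimal subtree spanning the leaves with
    value 1 at ``k``: its nodes must be 1 in every phylogenetically correct
    extension, and any point subdividing one of its edges likewise.
    """
    postorder = list(tree.postorder())
    forced_nodes: dict[int, set[str]] = {}
    forced_edges: dict[int, set[tuple[str, str]]] = {}
    for site in range(1, aln.m + 1):
        ones = {leaf for leaf in tree.leaves if aln.row(leaf)[site] == 1}
        t = len(ones)
        count: dict[str, int] = {}
        for v in postorder:
            if tree.is_leaf(v):
                count[v] = 1 if v in ones else 0
            else:
                count[v] = sum(count[c] for c in tree.children[v])
        nodes: set[str] = set()
        edges: set[tuple[str, str]] = set()
        for v in postorder:
            c = count[v]
            if c == 0:
                continue
            if c < t:
                nodes.add(v)
                edges.add((tree.parent[v], v))
            elif not any(
                count[k] == t for k in tree.children.get(v, ())
            ):  # v is the LCA of the 1-leaves (or the single 1-leaf)
                nodes.add(v)
        forced_nodes[site] = nodes
        forced_edges[site] = edges
    return forced_nodes, forced_edges


# --------------------------------------------------------------- components
@dataclass
class ComponentPartition:
    """Partition of gap characters into independently resolvable blocks."""

    #: Each block is a frozenset of (row, site) gap characters.
    blocks: list[frozenset[tuple[str, int]]]
    #: Sites touched by each block.
    sites: list[frozenset[int]]
    #: Solvability flag and witness per block (node name or edge), once
    #: :func:`classify_sites` has run; ``None`` before that.
    solvable: list[bool] | None = None
    witnesses: list[str | tuple[str, str] | None] | None = None


def partition_components(tree: Tree, aln: BinaryAlignment) -> ComponentPartition:
    """Connected-component closure of the conservative linking rule."""
    forced_nodes, _ = forced_one_nodes(tree, aln)
    chars = [
        (t, site)
        for t in aln.taxa
        for site in range(1, aln.m + 1)
        if aln.row(t)[site] == 0
    ]
    index = {ch: i for i, ch in enumerate(chars)}
    parent = list(range(len(chars)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_site: dict[int, list[int]] = {}
    for ch, i in index.items():
        by_site.setdefault(ch[1], []).append(i)
    # (a) column links: all gap characters of one site.
    for ids in by_site.values():
        for other in ids[1:]:
            union(ids[0], other)
    # (b) boundary links: some node could carry 0 at both k and k+1.
    all_nodes = set(tree.nodes)
    for k in range(1, aln.m):
        if k not in by_site or k + 1 not in by_site:
            continue
        spanning = all_nodes - (forced_nodes[k] | forced_nodes[k + 1])
        if spanning:
            union(by_site[k][0], by_site[k + 1][0])

    groups: dict[int, list[tuple[str, int]]] = {}
    for ch, i in index.items():
        groups.setdefault(find(i), []).append(ch)
    blocks = [frozenset(g) for _, g in sorted(groups.items())]
    blocks.sort(key=lambda b: min((s, t) for t, s in b))
    sites = [frozenset(s for _, s in b) for b in blocks]
    return ComponentPartition(blocks=blocks, sites=sites)


def classify_sites(
    tree: Tree, aln: BinaryAlignment, partition: ComponentPartition | None = None
) -> dict[int, SiteClass]:
    """Classify every gapped site by reducibility to the deletion-only model.

    A component is *solvable* when some node, or some point subdividing an
    edge, is forced to 1 at every site the component touches; re-rooting
    there turns the component's resolution into a deletion-only instance.  A
    gapped site is then entirely / partially / not solvable according to
    whether all / some / none of its gap characters lie in solvable
    components.
    """
    if partition is None:
        partition = partition_components(tree, aln)
    forced_nodes, forced_edges = forced_one_nodes(tree, aln)
    solvable: list[bool] = []
    witnesses: list[str | tuple[str, str] | None] = []
    for sites in partition.sites:
        node_wit = set.intersection(*(forced_nodes[s] for s in sites))
        edge_wit = set.intersection(*(forced_edges[s] for s in sites))
        if node_wit:
            solvable.append(True)
            witnesses.append(sorted(node_wit)[0])
        elif edge_wit:
            solvable.append(True)
            witnesses.append(sorted(edge_wit)[0])
        else:
            solvable.append(False)
            witnesses.append(None)
    partition.solvable = solvable
    partition.witnesses = witnesses

    char_solvable: dict[tuple[str, int], bool] = {}
    for block, ok in zip(partition.blocks, solvable):
        for ch in block:
            char_solvable[ch] = ok
    classes: dict[int, SiteClass] = {}
    for site in range(1, aln.m + 1):
        flags = [
            char_solvable[(t, site)]
            for t in aln.taxa
            if aln.row(t)[site] == 0
        ]
        if not flags:
            continue
        if all(flags):
            classes[site] = "entirely_solvable"
        elif any(flags):
            classes[site] = "partially_solvable"
        else:
            classes[site] = "not_solvable"
    return classes


def classification_to_tsv(
    classes: dict[int, SiteClass], partition: ComponentPartition
) -> str:
    """Report: site, class, component id, witness; plus summary percentages."""
    comp_of_site: dict[int, list[int]] = {}
    for ci, sites in enumerate(partition.sites):
        for s in sites:
            comp_of_site.setdefault(s, []).append(ci)
    lines = ["site\tclass\tcomponents\twitnesses"]
    for site in sorted(classes):
        comps = comp_of_site.get(site, [])
        wit = ";".join(
            str(partition.witnesses[c]) if partition.witnesses else ""
            for c in comps
            if partition.witnesses and partition.witnesses[c] is not None
        )
        lines.append(
            f"{site}\t{classes[site]}\t{','.join(map(str, comps))}\t{wit}"
        )
    total = len(classes) or 1
    counts = {
        c: sum(1 for v in classes.values() if v == c)
        for c in ("entirely_solvable", "partially_solvable", "not_solvable")
    }
    lines.append(
        "# summary\tentirely s. {:.2%}\tpartially s. {:.2%}\tnot solvable {:.2%}".format(
            counts["entirely_solvable"] / total,
            counts["partially_solvable"] / total,
            counts["not_solvable"] / total,
        )
    )
    return "\n".join(lines) + "\n"
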