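"""Rooted phylogenetic trees.

The solver works on rooted trees whose internal nodes have exactly two
children.  Degree-2 ("unary") internal nodes are tolerated because re-rooting
(:mod:`delpars.reduction`) turns the old root into a pass-through node and may
introduce a fresh degree-2 root when rooting on an edge; :func:`Tree.validate`
lets callers choose whether to accept them.

Newick text is parsed with dendropy and converted into a minimal immutable
structure: ordered child tuples plus a parent map, keyed by node name.
Unlabeled internal nodes receive deterministic names ``N1..Nk`` in pre-order,
so repeated runs on the same input produce identical node naming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import dendropy

from .errors import NewickError, TreeStructureError

__all__ = ["Tree", "parse_newick", "write_newick"]


@dataclass(frozen=True)
class Tree:
    """A rooted tree with named nodes and ordered children.

    Parameters
    ----------
    root:
        Name of the root node.
    children:
        Mapping from each internal node to its ordered tuple of children.
        Leaves do not appear as keys.
    """

    root: str
    children: dict[str, tuple[str, ...]]
    parent: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        parent: dict[str, str] = {}
        for p, kids in self.children.items():
            for k in kids:
                if k in parent:
                    raise TreeStructureError(f"node {k!r} has two parents")
                parent[k] = p
        object.__setattr__(self, "parent", parent)
        # Reachability / uniqueness checks.
        seen: set[str] = set()
        for v in self.preorder():
            if v in seen:
                raise TreeStructureError(f"duplicate node name {v!r}")
            seen.add(v)
        orphans = (set(self.children) | set(parent)) - seen
        if orphans:
            raise TreeStructureError(f"nodes unreachable from root: {sorted(orphans)}")

    # ------------------------------------------------------------------ views
    def is_leaf(self, v: str) -> bool:
        return v not in self.children

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(v for v in self.preorder() if self.is_leaf(v))

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.preorder())

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        """Directed edges (parent, child) in pre-order of the child."""
        return tuple((self.parent[v], v) for v in self.preorder() if v != self.root)

    def preorder(self) -> Iterator[str]:
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self.children.get(v, ())))

    def postorder(self) -> Iterator[str]:
        out = list(self.preorder())
        # children always come after their parent in preorder; reversing a
        # preorder in which siblings were pushed in order gives a postorder.
        visited: list[str] = []
        stack: list[tuple[str, bool]] = [(self.root, False)]
        while stack:
            v, expanded = stack.pop()
            if expanded or self.is_leaf(v):
                visited.append(v)
                continue
            stack.append((v, True))
            for c in reversed(self.children[v]):
                stack.append((c, False))
        assert len(visited) == len(out)
        return iter(visited)

    # ------------------------------------------------------------- validation
    def validate(self, allow_unary: bool = False) -> None:
        """Check structural invariants.

        Raises :class:`TreeStructureError` if an internal node does not have
        exactly two children (or, with ``allow_unary``, one or two).
        """
        for v, kids in self.children.items():
            if len(kids) == 2:
                continue
            if allow_unary and len(kids) == 1:
                continue
            raise TreeStructureError(
                f"internal node {v!r} has {len(kids)} children; expected 2"
            )

    def path(self, u: str, v: str) -> list[str]:
        """Nodes on the path between ``u`` and ``v``, inclusive."""
        anc_u = [u]
        while anc_u[-1] != self.root:
            anc_u.append(self.parent[anc_u[-1]])
        index = {x: i for i, x in enumerate(anc_u)}
        walk = [v]
        while walk[-1] not in index:
            walk.append(self.parent[walk[-1]])
        return anc_u[: index[walk[-1]]] + walk[::-1]


def parse_newick(text: str, require_binary: bool = True) -> Tree:
    """Parse a single rooted Newick tree.

    Unlabeled internal nodes are assigned names ``N1..Nk`` in pre-order.
    With ``require_binary`` (the default) a non-binary internal node raises
    :class:`TreeStructureError` naming the offending node.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=False,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise NewickError(f"could not parse Newick input: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        raise NewickError("Newick input contains no tree")

    counter = 0
    names: dict[int, str] = {}
    used: set[str] = set()
    for node in dtree.preorder_node_iter():
        label = None
        if node.taxon is not None and node.taxon.label:
            label = str(node.taxon.label)
        elif node.label:
            label = str(node.label)
        if label is None:
            counter += 1
            while f"N{counter}" in used:
                counter += 1
            label = f"N{counter}"
        if not label:
            raise NewickError("empty node label")
        names[id(node)] = label
        used.add(label)

    children: dict[str, tuple[str, ...]] = {}
    for node in dtree.preorder_node_iter():
        kids = node.child_nodes()
        if kids:
            children[names[id(node)]] = tuple(names[id(c)] for c in kids)
    tree = Tree(root=names[id(dtree.seed_node)], children=children)
    if require_binary:
        tree.validate(allow_unary=False)
    return tree


def _newick_of(tree: Tree, v: str) -> str:
    if tree.is_leaf(v):
        return v
    inner = ",".join(_newick_of(tree, c) for c in tree.children[v])
    return f"({inner}){v}"


def write_newick(tree: Tree) -> str:
    """Serialize ``tree`` to Newick, preserving all internal labels."""
    return _newick_of(tree, tree.root) + ";"
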