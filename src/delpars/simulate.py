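"""Seeded deletion-history simulator.

Generates solvable instances with a known ground-truth extension and event
list.  Starting from an all-1 root row, each edge independently applies a
Poisson-distributed number of deletion events.  A deletion acts on the
*present* sites of the child sequence: it removes a geometric-length run of
consecutive present characters, which in alignment coordinates may bridge
columns already lost higher up — mirroring how a biological deletion removes
characters that are adjacent in the actual sequence, not in the alignment.

Columns in which every leaf loses its character are dropped (with an
old→new site map), so the emitted leaf alignment is always a valid
deletion-only instance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .alignment import BinaryAlignment
from .errors import DelparsError
from .indels import Indel
from .tree import Tree

__all__ = ["SimulatedHistory", "simulate_deletion_history"]


@dataclass
class SimulatedHistory:
    """Ground truth of one simulated deletion history.

    ``extension`` and ``events`` are in the original (pre-drop) coordinate
    system; ``leaf_alignment`` and ``extension_trimmed`` have all-0 columns
    removed and ``site_map`` maps retained old sites to new ones.
    """

    tree: Tree
    extension: BinaryAlignment
    leaf_alignment: BinaryAlignment
    extension_trimmed: BinaryAlignment
    events: list[Indel]
    site_map: dict[int, int]
    seed: int
    m: int
    edge_deletion_rate: float
    mean_deletion_length: float

    def manifest_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "m": self.m,
                "edge_deletion_rate": self.edge_deletion_rate,
                "mean_deletion_length": self.mean_deletion_length,
                "n_events": len(self.events),
                "site_map": {str(k): v for k, v in sorted(self.site_map.items())},
            },
            indent=2,
        )


def simulate_deletion_history(
    tree: Tree,
    m: int,
    edge_deletion_rate: float = 0.5,
    mean_deletion_length: float = 3.0,
    seed: int = 0,
) -> SimulatedHistory:
    """Simulate deletions down ``tree`` over ``m`` ancestral sites.

    Parameters
    ----------
    edge_deletion_rate:
        Expected number of deletion events per edge (Poisson), in [0, 1].
    mean_deletion_length:
        Mean of the geometric length distribution; lengths are truncated to
        the run of present sites they start in.
    """
    if not 0.0 <= edge_deletion_rate <= 1.0:
        raise DelparsError(f"edge_deletion_rate must be in [0,1], got {edge_deletion_rate}")
    if m < 1:
        raise DelparsError(f"m must be >= 1, got {m}")
    if mean_deletion_length < 1:
        raise DelparsError("mean_deletion_length must be >= 1")
    rng = np.random.default_rng(seed)

    rows: dict[str, np.ndarray] = {}
    events: list[Indel] = []
    order = list(tree.preorder())
    rows[tree.root] = np.ones(m + 2, dtype=np.uint8)
    for w in order:
        if w == tree.root:
            continue
        p = tree.parent[w]
        row = rows[p].copy()
        n_events = int(rng.poisson(edge_deletion_rate))
        for _ in range(n_events):
            present = np.flatnonzero(row[1:-1]) + 1  # interior present sites
            if present.size == 0:
                break
            start_idx = int(rng.integers(present.size))
            length = int(rng.geometric(1.0 / mean_deletion_length))
            removed = present[start_idx : start_idx + length]
            row[removed] = 0
            events.append(
                Indel("deletion", int(removed[0]), int(removed[-1]), edge=(p, w))
            )
        rows[w] = row

    extension = BinaryAlignment(order, np.vstack([rows[v] for v in order]))
    leaves = list(tree.leaves)
    leaf_full = BinaryAlignment(
        leaves, np.vstack([rows[v] for v in leaves])
    )
    leaf_alignment, site_map = leaf_full.drop_all_zero_columns()
    keep_cols = [0] + sorted(site_map) + [m + 1]
    trimmed = BinaryAlignment(order, extension.matrix[:, keep_cols])
    return SimulatedHistory(
        tree=tree,
        extension=extension,
        leaf_alignment=leaf_alignment,
        extension_trimmed=trimmed,
        events=events,
        site_map=site_map,
        seed=seed,
        m=m,
        edge_deletion_rate=edge_deletion_rate,
        mean_deletion_length=mean_deletion_length,
    )
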