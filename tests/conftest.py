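import numpy as np
import pytest

import delpars as dp

TOPOLOGIES_3 = ["((a,b)u,c)r;", "(a,(b,c)u)r;"]
TOPOLOGIES_4 = ["((a,b)u,(c,d)v)r;", "(a,(b,(c,d)v)u)r;", "(((a,b)v,c)u,d)r;"]


def random_instance(rng: np.random.Generator, max_m: int = 6):
    """A random small instance: <=3 internal nodes, m <= max_m, no all-0 column."""
    if rng.integers(2):
        newick = TOPOLOGIES_3[rng.integers(len(TOPOLOGIES_3))]
    else:
        newick = TOPOLOGIES_4[rng.integers(len(TOPOLOGIES_4))]
    tree = dp.parse_newick(newick)
    nl = len(tree.leaves)
    m = int(rng.integers(2, max_m + 1))
    while True:
        mat = np.ones((nl, m + 2), dtype=np.uint8)
        mat[:, 1 : m + 1] = rng.integers(0, 2, size=(nl, m))
        if mat[:, 1 : m + 1].any(axis=0).all():
            break
    return tree, dp.BinaryAlignment(list(tree.leaves), mat)


@pytest.fixture(scope="session")
def demo():
    """The bundled worked example: 4 taxa, m=11, 16 optima of cost 8."""
    return dp.load_demo()


@pytest.fixture(scope="session")
def demo_solved(demo):
    tree, aln = demo
    state = dp.bottom_up_pass(tree, aln)
    sols = dp.top_down_enumerate(tree, state, aln.m)
    return tree, aln, state, sols


def as_row_map(tree, ext):
    """Order-independent representation of an extension for set comparison."""
    return frozenset((v, ext.row(v).tobytes()) for v in tree.nodes)


def solution_key_set(tree, solset):
    return {as_row_map(tree, e) for e in solset.extensions}
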