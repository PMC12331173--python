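"""Small bundled example instances.

``load_demo`` returns the worked four-taxon example used throughout the
documentation and tests: tree ``(a,(b,(c,d)y)x)r`` with an 11-column
alignment whose gap form is  a: –, b: [2,2],[6,6],[9,10],
c: [2,3],[5,7],[10,11], d: [1,3],[5,8],[10,11].  It has 16 optimal
deletion-only solutions of cost 8.

``load_demo_pair`` returns the two-row alignment used to illustrate the
indel distance (d = 3: a deletion [1,4], an insertion [3,3], a deletion
[6,6], sentinel-flanked coordinates).
"""

from __future__ import annotations

from importlib import resources

from .alignment import BinaryAlignment, read_alignment
from .tree import Tree, parse_newick

__all__ = ["load_demo", "load_demo_pair", "demo_paths"]


def _read(name: str) -> str:
    return (resources.files("delpars") / "data" / name).read_text()


def demo_paths() -> dict[str, str]:
    """Absolute paths of the bundled demo files (tree, alignment, row pair)."""
    base = resources.files("delpars") / "data"
    return {
        "tree": str(base / "demo.nwk"),
        "alignment": str(base / "demo.fasta"),
        "pair": str(base / "demo_pair.fasta"),
    }


def load_demo() -> tuple[Tree, BinaryAlignment]:
    tree = parse_newick(_read("demo.nwk"))
    aln = read_alignment(_read("demo.fasta"))
    return tree, aln


def load_demo_pair() -> BinaryAlignment:
    # A bare row pair; columns gapped in both rows are legitimate here.
    return read_alignment(_read("demo_pair.fasta"), validate=False)
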