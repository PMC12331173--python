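# delpars — exact deletion-only indel parsimony

`delpars` reconstructs ancestral gap patterns on a rooted binary phylogeny
under a **deletion-only** model: characters present at the root can be lost
along the tree but never (re-)gained, the usual reading of Dollo's law for
sequence characters. Unlike site-independent methods, a single deletion
event may span many alignment columns, so the optimization couples sites.

Given a tree `T` and an alignment `A` of its leaves (reduced to a 0/1
presence/absence matrix with all-1 sentinel columns `A[0]`, `A[m+1]`), the
goal is an extension `A⁺` — one row per internal node, agreeing with the
leaves — minimizing

```
c(A⁺) = Σ_{(u,v) ∈ E(T)} d(A⁺_u, A⁺_v)
```

where `d(·,·)` is the unit-cost indel distance: the number of maximal
intervals `[i,j]` whose endpoint columns are (1,0) — or (0,1) for
insertions — and that contain no (1,1) column. Under the deletion-only
constraint every per-edge event must be a deletion (values never increase
from root to leaf, and the root row is all-1).

What the package computes, exactly:

* **one** optimal reconstruction in polynomial time (`top_down_single`);
* **all** optimal reconstructions (`top_down_enumerate`), via a bottom-up
  labeling of candidate gap intervals as `0` (certainly a gap), `P`
  (certainly copies the parent) or `C` (a binary choice), followed by a
  branching top-down resolution;
* a per-node **site graph** (`build_site_graphs`): a DAG on sites
  `0..m+1` whose 0→(m+1) paths are *exactly* the rows that node can take in
  an optimal solution — a partial-order-graph summary of all optima that
  stays polynomial even when their number is exponential;
* a **reduction** toolkit for the general insertion+deletion problem:
  cost-preserving re-rooting, forced-presence (Steiner-subtree) analysis,
  a conservative partition of gap characters into independent components,
  and per-site solvability classification;
* a brute-force **oracle** and a seeded deletion-history **simulator** for
  verification at small scale.

Intended users: developers of ancestral sequence reconstruction and
alignment tools, and anyone needing provably exhaustive indel
reconstructions (e.g. to quantify reconstruction uncertainty) rather than
one arbitrary optimum.

## Worked example

The bundled demo instance has tree `(a,(b,(c,d)y)x)r` and an 11-column
alignment whose rows, in gap form, are `a: –`, `b: [2,2],[6,6],[9,10]`,
`c: [2,3],[5,7],[10,11]`, `d: [1,3],[5,8],[10,11]`.

```python
>>> import delpars as dp
>>> tree, aln = dp.load_demo()
>>> state = dp.bottom_up_pass(tree, aln)
>>> [(g.start, g.end, g.label.value) for g in state["x"]]
[(2, 2, 'C'), (6, 6, 'C'), (10, 10, 'P')]
>>> sols = dp.top_down_enumerate(tree, state, aln.m)
>>> sols.s, sols.cost, sols.c_gaps
(16, 8, 4)
>>> graphs = dp.build_site_graphs(tree, state, aln.m)
>>> {w: dp.count_paths(g) for w, g in graphs.items()}
{'r': 1, 'x': 4, 'y': 9}
```

Reading: the bottom-up phase leaves four binary choices (`C`-gaps), so the
top-down phase enumerates `2⁴ = 16` distinct optimal extensions, each
containing 8 deletions in total. Node `x` can take 4 different rows across
those optima and node `y` can take 9; the site graphs encode those rows as
their source-to-sink paths without enumerating the 16 solutions.

The same results from the shell:

```console
$ delpars enumerate src/delpars/data/demo.nwk src/delpars/data/demo.fasta
cost=8 solutions=16 c_gaps=4
$ delpars graphs src/delpars/data/demo.nwk src/delpars/data/demo.fasta
r	1
x	4
y	9
$ delpars distance src/delpars/data/demo_pair.fasta u v
d=3
deletion	1	4
insertion	3	3
deletion	6	6
```

The last command shows the unit-cost distance on a classic row pair
(`u = 11001111`, `v = 10010101`): one deletion spanning sites 1–4, one
insertion at site 3 *inside* that deletion's interval, one deletion at
site 6 — three events, not five, because an event may bridge columns that
are absent on both rows.

Other subcommands: `solve` (single optimum), `simulate` (seeded fixture
bundles), `classify` (per-site solvability of general indel instances by
reduction to the deletion-only model), `run` (any mode from a JSON config).

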