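# Methods

## Model

The input is a rooted binary phylogeny `T` and a multiple sequence
alignment of its leaves, reduced to a binary matrix `A` (1 = character
present, 0 = gap). Two all-1 sentinel columns, site `0` and site `m+1`,
flank the `m` data columns so that every maximal 0-run is bordered by 1s.
Interior columns consisting only of 0s are rejected by default: under a
deletion-only model such a column would require a character that no extant
sequence retains, which the model cannot produce (a CLI flag instead drops
them and logs the old→new site map).

An *extension* `A⁺` adds one row per internal node, agreeing with the
leaves. Between the rows of an edge, an *indel* is a maximal interval whose
endpoint columns show (1,0) (deletion) or (0,1) (insertion) and which
contains no (1,1) column. Crucially an event may bridge (0,0) columns:
biologically, one deletion removes characters that are consecutive in the
ancestral *sequence*, even if the alignment interleaves them with older
gaps. The unit-cost distance `d` counts events irrespective of length; the
objective is the sum of `d` over edges, minimized under the constraint that
every event on every edge is a deletion — equivalently, per site, values
never increase from the (all-1) root toward the leaves.

## Algorithm

**Per-edge sweep.** `indels_between` segments the site axis at (1,1)
columns (the sentinels always are) and emits at most one deletion and one
insertion per segment, spanning the first to last (1,0) — resp. (0,1) —
column. This realizes the maximality condition directly in O(m) per edge;
the test suite checks it exhaustively against an O(m³) all-intervals oracle
for every pair of flanked rows of length 8.

**Bottom-up labeling.** Post-order over `T`. A leaf's labeled gaps are its
maximal 0-runs, tagged `0`. An internal node combines every overlapping
pair of its children's labeled gaps; the stored interval is the
intersection and the tag is: equal intervals — `0` unless one side is `P`
(then `C`) or both are (then `P`); strict nesting — the nested gap's side
decides (`C` unless it is `P`); partial overlap — always `P`. Tag
semantics, proved by the correctness results and re-checked here against
brute force: `0` = a gap of that node's row in *every* optimum, `P` = the
node copies its parent's pattern on the interval in every optimum, `C` = in
every optimum exactly one of those two holds. Since the intersections of
two disjoint families are disjoint, each state is a sorted disjoint list
and a linear merge suffices; state sizes are O(b), with `b` the number of
differing adjacent column pairs.

**Top-down resolution.** Pre-order. A `C`-gap whose exact interval is a
parent 0-gap is reset to `0` (both outcomes coincide); any other `C`-gap
branches the partial solution (reset to a gap / copy the parent's 0-gaps
inside the interval); a `P`-gap always copies. Copying reproduces the
parent's pattern exactly because no labeled gap partially overlaps a
parent's labeled gap. Exhausting branch combinations and deduplicating the
materialized matrices yields all optima; always taking the reset branch
yields one optimum in O(nb). Deduplication is kept even though the worked
example realizes all `2^c` branch vectors distinctly: no proof is attempted
that this holds in general, and set semantics are safe either way. An
enumeration cap (default 10⁶) turns pathological inputs into a clear error
pointing at the graph representation.

**Site graphs.** Pre-order again, replacing the top-down phase. The root
graph is the chain `(k, k+1)`. At any other node, chain arcs survive where
neither endpoint lies in a labeled gap; a 0-gap `[i,j]` adds the bypass arc
`(i-1, j+1)`; a `P`-gap copies the parent's arcs with both endpoints in
`[i-1, j+1]`; a `C`-gap does both. Path counting is an exact-integer DP
over vertices in increasing order (counts can be exponential in `m`);
enumeration is a lexicographic DFS guarded by the count. The graphs are
planar — arcs nest — which also bounds their arc count linearly in `m`;
planarity is asserted in tests, not enforced during construction. The
O(b)-vertex compressed variant of the graphs is deliberately not
implemented; vertex sets are always `0..m+1`.

**Degree-2 (pass-through) nodes.** Re-rooting keeps every original node,
so the old root becomes a degree-2 node, and rooting on an edge creates a
degree-2 root. The bottom-up rule for a pass-through node copies its single
child's labeled gaps with `0` relabeled `C`: a gap certain at the child is,
one level up, exactly the choice between deleting below or above the node.
A degree-2 root's state is forced empty (every column has a 1-leaf below
it, so the root is all-1 in every candidate). This extension beyond binary
trees is validated against brute force on rerooted random instances rather
than proved.

## Reduction of general indel instances

The general problem (insertions allowed) is time-reversible: the edge set
is unchanged by re-rooting and `d` is symmetric, so any fixed extension
keeps its cost — `reroot` preserves all nodes precisely to make this exact.
Per site, the minimal subtree spanning the 1-leaves is forced to 1 in every
phylogenetically correct extension (computed with subtree 1-leaf counts; a
node is in the Steiner tree iff its count is strictly between 0 and the
total, or it is the LCA of the 1-leaves; an edge iff its lower count is).
If some node or edge-subdivision point is forced to 1 at every site a
component of gap characters touches, re-rooting there makes that
component's resolution deletion-only.

**Component partition.** Gap characters are linked when (a) they share a
site, or (b) they sit at consecutive sites `k, k+1` such that some tree
node is *not* forced to 1 at both — i.e. some phylogenetically correct
extension could carry a gap spanning the boundary, so a single event could
involve both sites. Rule (b) subsumes linking consecutive characters of one
row's 0-run (the row's own leaf is such a node) and keeps blocks separated
by all-1 columns independent (every node is forced there). The partition is
deliberately conservative: it may merge components that a finer analysis
would separate, never the opposite, so solvability is under-reported at
worst and independence is never claimed where the model cannot support it.
Users with an externally justified finer partition can classify against it
by calling `classify_sites` with their own `ComponentPartition`. Site
classes follow from the component flags: *entirely* / *partially* / *not*
solvable according to whether all / some / none of the site's gap
characters lie in solvable components. Solving non-reducible components
(the general problem itself) is out of scope.

## Simulator

`simulate_deletion_history` emulates the generative story behind the model:
an all-1 root row; on each edge an independent Poisson(`rate`) number of
deletion events (default rate 0.5, valid range [0,1], i.e. expected events
per edge); each event removes a Geometric(1/mean)-length run (default mean
3, truncated at the end of the present run it starts in) of *currently
present* sites of the child — so in alignment coordinates an event may
bridge previously deleted columns, as in the real process. Columns lost in
every leaf are dropped with a site map. The simulator is deterministic
given a seed; the true history is itself a candidate solution, so the
optimal cost can never exceed the simulated event count — an invariant the
tests rely on. What it does not emulate: insertions, substitutions, rate
heterogeneity across lineages or sites, or alignment error; tests on
simulated data therefore certify algorithmic correctness under the model,
not robustness to model violations on real alignments.

## Verification strategy and problem sizes

The exhaustive oracle enumerates, per site, every monotone assignment of
internal-node values (root 1, never increasing downward, consistent with
leaves), takes the product over sites, and scores full extensions with the
per-edge sweep; it shares no code path with the solver. Randomized checks
use trees with at most 3 internal nodes and `m ≤ 6` (a scale where the
oracle is instant and 200+ instances complete in seconds), seeded
generators throughout, and assert *set equality* of solution sets, per-node
equality of graph path sets and projected optimal rows, the three tag
semantics, re-rooting cost invariance and the simulator cost bound. The
worked four-taxon example is additionally pinned bit-exactly (labels, 16
solutions, cost 8, arc lists, path counts 1/4/9).

## Numerical and representational choices

Rows are numpy `uint8`; extensions are compared as raw row bytes, making
dedup and set comparisons exact. Coordinates are 1-based closed intervals
user-facing; sentinels never appear as event endpoints. Event order per
edge is by start site, deletion before insertion at ties (the relative
order on an edge is not meaningful). Unlabeled internal nodes are named
`N1..Nk` in pre-order, so identical inputs always produce byte-identical
outputs. Path counting uses Python integers — no overflow at any `m`.

## Known limitations

Unit costs only: no affine or length-dependent penalties, no
edge-dependent costs, no asymmetric insertion/deletion weights. Input trees
must be binary (degree-2 nodes arise only through re-rooting). The
component partition is an over-approximation, so "not solvable" verdicts
are conservative. Full enumeration is inherently exponential in the number
of `C`-gaps; use the single-solution mode or the site graphs beyond the cap.
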