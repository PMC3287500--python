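# Methods

## The computing model

The simulator implements a plain electrical reconfigurable mesh: a 2-D
grid of processing units, four ports each (N, S, E, W), with port
partitions chosen per unit from the 15 set partitions of the four labels
(the five containing a group of three or more ports are flagged as illegal
for Linear-r-mesh variants but are permitted here). Buses are the
connected components of the graph whose vertices are (unit, port) pairs
and whose edges are intra-unit fusions plus the fixed abutments
E(r,c)–W(r,c+1) and S(r,c)–N(r+1,c). A *broadcasting step* is atomic:
configure partitions, drive bits onto border ports (or any port via
`drives`), and read every bus as the OR of its drivers. OR resolution is
a design choice — the model itself does not fix a concurrent-write rule —
and is what the max switches rely on (a 1 anywhere on the bus dominates).
Cyclic configurations are permitted and well defined under OR semantics.
Buses are 1-bit; n-bit values travel as n parallel bit-planes.

Bus resolution uses an array-based union-find; an independent breadth
first flood fill (and networkx connected components) serve as oracles in
the tests.

## Numbers

Values are unsigned unary (1UN): x is stored in w bits as x + 1 leading
ones (3 at width 8 is `11110000`); the all-zero pattern is a reserved
underflow marker, produced by any subtraction that would go negative and
treated as smaller than every encodable value. Operations that would
exceed w − 1 raise a capacity error rather than saturate; DP assemblies
pick the smallest width that holds the maximum attainable score.
The affine selector bit is *not* part of the number — it travels as a
separate tagged field so the prefix invariant stays testable.

## Components

* **Max switches.** One unit fused {NSEW} for two bits; the printed
  four-unit configuration {NSW,E}, {NSE,W}, {NE,S,W}, {NSW,E} on a 2 × 2
  grid wires all four input ports onto one bus (verified by exhaustive
  truth table). A w-bit switch is one 4-input switch per bit plane (4w
  units); three-input uses feed a zero into the spare port.
* **Adder/subtractor.** k × w units for a pre-loaded operand of magnitude
  k; the operand's encoding is left-shifted once (dropping the bit that
  represents zero) so only its one-bits need rows. Every kept row fuses
  {NE,SW} and shifts the travelling prefix by one position: North-in /
  South-out adds, South-in / North-out (East border fed 0) subtracts, and
  a prefix that runs off the low end leaves the underflow pattern. An
  underflow input short-circuits to an underflow output so a dead branch
  can never be resurrected downstream.
* **On/off switch.** w × (w + 1) units; column i fuses with row w−1−i
  into an L-path from the North border to the last column, which either
  passes each row's bit to the East border or blocks it. The construction
  described for the last column — fuse {NSEW} as a signal travels through
  — cannot be taken literally under atomic OR-bus semantics (fused
  last-column cells would merge into one bus and every output bit would
  read the OR of all inputs), so the simulator models the electrically
  cascaded fuse as configure-time switching on the selector bit:
  {EW},{N},{S} to pass, {NS,E,W} to block. Geometry, PU count and
  behaviour are unchanged.

Component geometries (and their resolved bus structures) are cached per
shape; evaluation rewrites border drives and re-broadcasts.

## Dynamic programming

All three recurrences share one cell: three adder/subtractor units
(diagonal: + s(x_i, y_j); vertical/horizontal: + g, which for negative g
is a subtraction with underflow) feeding a max switch, with the floor
value wired into the spare fourth input for the local (Smith–Waterman)
variant. The LCS cell instead routes diagonal + 1 on a match and
max(up, left) on a mismatch ({N,E,SW} vs {NS,E,W} in the routing unit).

Conventions, fixed package-wide and mirrored by the sequential oracles:

* **Boundary.** `c[0,j] = c[i,0] = 0` for every mode — leading gaps in
  either sequence are free. (The textbook global-alignment boundary
  `c[0,j] = j·g` would place negative values in boundary cells, which the
  unsigned mesh cannot hold; the zero boundary is the form the mesh
  computes and the one all cross-checks use. With non-negative
  substitution scores it also guarantees every interior cell is
  non-negative, since the diagonal candidate is.)
* **Mesh precondition.** Substitution scores must be non-negative; the
  gap score may be negative (its magnitude is subtracted, branches clamp
  to underflow, and underflow never wins a max). Matrices with negative
  entries are scaled up first.
* **Scale-up.** `scale_up` adds β = max(0, −min(scores ∪ {g})) to every
  score including the gap; in log-odds terms this multiplies every
  substitution probability by a^β. It shifts each path step uniformly,
  so alignments with different step counts can re-rank; the traceback
  path can always be re-scored against the original scheme
  (`rescore_original`, a running prefix sum over the path), and the tests
  record empirically how often the scaled optimum re-scores to the
  unscaled optimum rather than assuming it.
* **Smith–Waterman floor.** 0 unscaled, β scaled; traceback stops at the
  first cell holding the floor value.
* **Ties.** Traceback prefers diagonal over vertical over horizontal,
  with an optional seeded-random mode; the max-location rounds and
  neighbor joining break ties toward the smallest index / earliest
  created pair. Determinism everywhere is deliberate: both engines and
  the independent reference must produce byte-identical output.

Large assemblies are simulated hierarchically: cells are evaluated in
row-major (topological) order, each through real component meshes, with
border values passed between components. Because values only flow down
and right this is functionally equivalent to the single-broadcast flat
grid; a literal flat O(n⁴)-unit layout is not constructed (PU accounting
still reports flat totals). Argmax location runs the staged 3-D rounds
(fan-out, per-slice flag-matrix max, index return, final max) over arrays
rather than a literal 3-D port graph.

### Affine gaps

Every travelling value carries a selector bit (1 = already gap
penalized). The modified gap unit charges the extension g, then either
adds the extra opening charge ε = |o| − |g| (gap − gap_open on signed
scores) on a side path (selector 0, the
on/off switch blocks the extension-only branch) or lets the
extension-only branch through to a 2-input max (selector 1). Diagonal
results reset the tag to 0; boundary cells carry tag 0. The single tag
merges the two gap directions that Gotoh's three matrices keep separate,
so exact equivalence with Gotoh is not claimed; the tests treat the
selector-bit rules as the contract and record the observed agreement with
a Gotoh oracle (total agreement on the seeded instances tested, with the
tag rules as ground truth where they would differ).

## Sum-of-pairs and group alignment

Column-vs-column scores use the counting form over the merged residue
pool of both columns (gap included as a symbol type; s(a,−) is the gap
score, s(−,−) defaults to 0 and is configurable). The merged pool counts
within-column pairs as well as cross-column pairs — this follows the
15-pair worked enumeration rather than a cross-column-only reading, and
the brute-force oracle enumerates the same pool. One consequence worth
knowing: a group that already contains gap columns can score better by
splitting a half-gap column than by matching it against itself, so
self-alignment idempotence holds for gap-free groups only.

Group DP runs the same zero-boundary recurrence over columns, with
per-cell pre-computed SP operands (diagonal: sp(A_i, B_j); gap steps:
sp(column, all-gap column)); a gap step inserts an all-gap column into
the other group and the traceback merges both row sets. Two singleton
groups reduce exactly to pairwise DP. When the input scheme has any
negative score the whole pipeline (pairwise scores, distances, merges)
runs on the scaled-up scheme, which keeps every SP operand non-negative —
the mesh precondition — and makes the two engines interchangeable; merge
scores are therefore reported in scaled units.

## Guide trees

Distances are `D_ij = max(S) − S_ij` from the pairwise score matrix
(the transform is a package choice; the source procedure passes scores to
clustering without fixing one). Neighbor joining performs exactly m − 1
joins (at two active nodes the pair joins directly with D/2 per branch,
net divergence being undefined there), yielding a rooted binary tree with
2m − 1 nodes whose join order drives the merges. The distance update is
the standard Saitou–Nei `(D_iv + D_jv − D_ij)/2`; the unhalved variant is
available as `paper_literal=True` for comparison. Branch lengths are
computed even though the merge order alone would suffice, so trees can be
written as Newick. The mesh realisation of clustering is an accounting
story (O(m³) units, O(m) rounds); the algorithm itself is sequential.

## Synthetic families

`synth_family` emulates what progressive alignment assumes: one random
ancestor, each descendant mutated independently by per-position
substitutions (default rate 0.1) and single-symbol indels (default rate
0.05, deletion/insertion equiprobable). Defaults describe moderately
diverged DNA families; tests run m ≤ 8 sequences of length ≤ 12 so the
mesh engine stays tractable. The generator does not model rate
heterogeneity, indel length distributions, back mutations along a
phylogeny, or composition bias — so passing tests demonstrate
correctness of the algorithms under the stated model, not alignment
accuracy on real genomic data.

## Problem sizes and numerics

Mesh-vs-oracle checks use sequence lengths ≤ 10–12 and hundreds of seeded
random instances per claim; exhaustive checks (adder operands ≤ 12,
on/off values, LCS vs subsequence enumeration at length ≤ 8) cover the
small domains completely. Unary widths are chosen per run as maximum
attainable score + 2; all arithmetic is integer, and the only floating
point lives in guide-tree distances, where every quantity is a dyadic
rational (integer scores halved a bounded number of times), so engine
comparisons are exact.

## Known limitations

* The flat single-broadcast grid is never materialised; fidelity rests on
  the per-component port-level simulation plus the value-flow argument.
* The selector-bit affine scheme is taken as specified; its relation to
  Gotoh is characterised empirically, not resolved.
* Scale-up can change the optimal alignment when candidate alignments
  differ in step count; consumers needing original-scheme optima should
  compare `rescore_original` output against a signed-oracle run.
* The aligner is a simulator: asymptotic speed claims are represented by
  PU accounting, and actual run time grows with mesh size rather than
  shrinking.
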