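# meshalign

Progressive multiple sequence alignment (MSA) on a simulated
**reconfigurable mesh** (r-mesh), with every parallel building block
cross-validated against independent sequential implementations.

An r-mesh is a grid of processing units (PUs), each with four ports
(N, S, E, W) that can be *fused* into groups. Fused ports plus the fixed
wiring between neighbouring units form *buses*; in one broadcasting step a
bus carries the logical OR of every bit driven onto it. With numbers in the
unary **1UN** encoding — the value *x* is a prefix of *x* + 1 one-bits, the
all-zero pattern marks underflow — surprisingly much of sequence alignment
becomes pure signal routing:

* **max** of unary numbers = bitwise OR on shared buses (a 1 dominates);
* **add / subtract** a constant *k* = a *k* × *w* grid whose rows each
  shift the prefix boundary by one bit;
* a dynamic-programming cell `c[i,j] = max(c[i-1,j-1] + s(x_i, y_j),
  c[i-1,j] + g, c[i,j-1] + g)` = three adder/subtractor units feeding a max
  switch, so a whole Needleman–Wunsch / Smith–Waterman / LCS matrix fills
  in a single broadcast;
* affine gap costs `o + g(l-1)` ride on one extra selector bit per value,
  gated by an on/off switch — no Gotoh matrices needed when every cell is
  a processor with local state.

On top of the pairwise meshes sit the classic progressive-MSA stages:
all-pairs DP scores, a neighbor-joining guide tree
(`M_ij = D_ij - r_i - r_j`, `r_i = Σ_j D_ij / (m-2)`), and guide-tree-ordered
group alignment where two columns *f*, *g* are matched by the
**counting form of sum-of-pairs**

```
sp(f,g) = Σ_i  n_i(n_i-1)/2 · s(i,i)  +  Σ_{i<j}  n_i n_j · s(i,j)
```

over the per-symbol counts `n_i` of the merged column pool — cost O(T²) in
the alphabet size T, independent of how many sequences the columns hold.

Who is this for: anyone studying bit-level parallel models of
computation applied to sequence analysis — the package is a *simulator*
and test bed, not a production aligner. Every mesh result is checked
against plain sequential oracles (and, for trees, against scikit-bio and
dendropy), so the repository doubles as an executable argument that the
constructions are correct.

## Worked example

```python
from meshalign import ScoringScheme, align, mesh_dp
from meshalign.oracles import oracle_dp

x, y = "ACGTTAC", "AGTTC"
scheme = ScoringScheme.constant("ACGT", match=2, mismatch=0, gap=-1)

matrix = mesh_dp(x, y, scheme, "nw")        # simulated r-mesh
oracle, _ = oracle_dp(x, y, scheme, "nw")   # sequential reference
assert (matrix.c == oracle).all()

result, _ = align(x, y, scheme, "nw", engine="mesh")
print(result.score)      # 8
print(result.aligned_x)  # ACGTTAC
print(result.aligned_y)  # A-GTT-C
```

The score 8 is four matches (4 × 2) at free leading positions minus
nothing: the first row and column of the DP matrix are initialised to
zero, so leading gaps in either sequence are free; the two interior gaps
cost −1 each and the five matches contribute 10 (10 − 2 = 8).

The same machinery from the shell:

```bash
meshalign simulate-component adder 3 3 --width 8   # 11111110 (= 6), 24 PUs
meshalign msa family.fa --engine mesh --out aln.fa --out-tree tree.nwk
```

and `examples/` contains one narrative script per capability
(components, pairwise DP, sum-of-pairs, guide trees, end-to-end MSA).

## Resource accounting

Constant-time claims are tracked as processing-unit counts, not wall
clock: each component reports its simulated PU total (1 for the 2-input
bit switch, 4 for the 4-input, 4*w* for the *w*-bit max switch, *k*×*w*
for the adder, *w*(*w*+1) for the on/off switch), and
`meshalign.resources` provides the closed forms for the composites — 10*n*
per DP cell under constant schemes, O(*n*³) per DP mesh, O(*m*³) for
neighbor joining, O(*m·n*³) (constant schemes) or O(*m·n*⁴) (general) for
the full pipeline, reached in O(*m*) broadcast rounds.

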