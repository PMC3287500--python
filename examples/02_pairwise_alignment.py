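"""Pairwise alignment on the simulated DP mesh, checked against the oracle.

Aligns two short DNA sequences with a match-rewarding scheme on both
backends, prints the DP matrix, the decoded alignment, and the PU
accounting for a mesh of this size.
"""

from meshalign import resources
from meshalign.dpmesh import align, mesh_dp
from meshalign.oracles import oracle_dp
from meshalign.scoring import ScoringScheme

x, y = "ACGTTAC", "AGTTC"
scheme = ScoringScheme.constant("ACGT", match=2, mismatch=0, gap=-1)

mesh_matrix = mesh_dp(x, y, scheme, "nw")
oracle_matrix, _ = oracle_dp(x, y, scheme, "nw")
assert (mesh_matrix.c == oracle_matrix).all()
print("mesh DP matrix (== sequential oracle cell-for-cell):")
print(mesh_matrix.c)

result, _ = align(x, y, scheme, "nw", engine="mesh")
print(f"\nglobal alignment, score {result.score}:")
print(" ", result.aligned_x)
print(" ", result.aligned_y)

result_sw, _ = align(x, y, scheme, "sw", engine="mesh")
print(f"\nlocal (floored) alignment, score {result_sw.score}, "
      f"end cell {result_sw.end}:")
print(" ", result_sw.aligned_x)
print(" ", result_sw.aligned_y)

n = max(len(x), len(y))
print(f"\nPU accounting for an n={n} DP mesh, constant scheme: "
      f"{resources.dp_mesh_constant(n)} units (10n per cell)")
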