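"""Neighbor-joining guide tree from all-pairs alignment scores.

Scores every sequence pair with the DP aligner, converts similarities to
distances, and prints the dendrogram that fixes the progressive merge
order.
"""

from meshalign.guidetree import distances_from_scores, nj_build
from meshalign.progressive import pairwise_all
from meshalign.scoring import ScoringScheme

ids = ["human", "chimp", "mouse", "fly"]
seqs = ["ACGTTACG", "ACGTTACG", "ACGATACG", "TTGATTGG"]
scheme = ScoringScheme.constant("ACGT", match=2, mismatch=0, gap=-1)

S = pairwise_all(seqs, scheme)
print("pairwise NW scores:")
print(S)

dm = distances_from_scores(S, ids)
print("\ndistances (max score minus score):")
print(dm.D)

tree = nj_build(dm)
print(f"\nguide tree ({len(tree.merge_order)} merges = m - 1):")
print(" ", tree.newick())
print("Identical sequences sit at distance 0 and join first; the merge "
      "order drives the progressive stage.")
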