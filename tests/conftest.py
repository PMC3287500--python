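import numpy as np
import pytest

from meshalign.scoring import ScoringScheme


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def dna_scheme():
    """Match-rewarding DNA scheme with a negative gap (mesh-safe unscaled)."""
    return ScoringScheme.constant("ACGT", match=2, mismatch=0, gap=-1)


def random_dna(rng, lo, hi, alphabet="ACGT"):
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def make_seq():
    return random_dna


def random_additive_matrix(rng, n_taxa):
    """Distances induced by a random binary tree with integer branch lengths.

    Returns ``(D, labels, newick of the generating tree)``; the matrix is
    exactly additive, so neighbor joining must recover the topology.
    """
    labels = [chr(ord("A") + i) for i in range(n_taxa)]
    dist = {}
    paths = {lab: {lab: 0.0} for lab in labels}
    newick = {lab: lab for lab in labels}
    live = list(labels)
    while len(live) > 2:
        i, j = sorted(rng.choice(len(live), size=2, replace=False))
        a, b = live[int(i)], live[int(j)]
        la = float(rng.integers(1, 6))
        lb = float(rng.integers(1, 6))
        new_label = a + b
        newick[new_label] = f"({newick[a]}:{la},{newick[b]}:{lb})"
        for leaf in paths[a]:
            paths[a][leaf] += la
        for leaf in paths[b]:
            paths[b][leaf] += lb
        for x, dx in paths[a].items():
            for y, dy in paths[b].items():
                dist[tuple(sorted((x, y)))] = dx + dy
        paths[new_label] = {**paths[a], **paths[b]}
        live = [v for v in live if v not in (a, b)] + [new_label]
    a, b = live
    edge = float(rng.integers(1, 6))
    for x, dx in paths[a].items():
        for y, dy in paths[b].items():
            dist[tuple(sorted((x, y)))] = dx + dy + edge
    D = np.zeros((n_taxa, n_taxa))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i != j:
                D[i, j] = dist[tuple(sorted((x, y)))]
    tree_newick = f"({newick[a]}:{edge},{newick[b]}:0);"
    return D, labels, tree_newick
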