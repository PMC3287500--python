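"""Independent sequential reference implementations.

These are direct transcriptions of the textbook recurrences using plain
signed integers — no unary encodings, no mesh constructs — and serve as the
ground truth the mesh modules are tested against, as well as the fast
``engine="reference"`` backend.  A mesh-vs-oracle mismatch is a
build-failing event.

All DP variants use the zero-initialised first row and column
(``c[0, j] = c[i, 0] = 0``), i.e. leading gaps in either sequence are free;
this is the convention the mesh implements.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np

from .scoring import GAP, ProfileColumn, ScoringScheme

__all__ = [
    "oracle_dp",
    "oracle_affine",
    "oracle_gotoh",
    "oracle_sp",
    "oracle_argmax",
    "oracle_lcs_bruteforce",
    "oracle_alignment_bruteforce",
    "flood_fill_buses",
    "oracle_nj",
]


# ---------------------------------------------------------------------------
# pairwise dynamic programming
# ---------------------------------------------------------------------------

def oracle_dp(x: str, y: str, scheme: ScoringScheme, mode: str):
    """Row-major evaluation of the NW / SW / LCS recurrence.

    Returns ``(matrix, score)`` where the score is ``c[n, m]`` for NW and
    LCS and the matrix maximum for SW.  SW floors every cell at 0, or at
    ``beta`` for a scaled scheme.
    """
    n, m = len(x), len(y)
    c = np.zeros((n + 1, m + 1), dtype=np.int64)
    floor = scheme.beta if scheme.scaled else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if mode == "lcs":
                if x[i - 1] == y[j - 1]:
                    c[i, j] = c[i - 1, j - 1] + 1
                else:
                    c[i, j] = max(c[i - 1, j], c[i, j - 1])
            elif mode == "nw":
                c[i, j] = max(
                    c[i - 1, j - 1] + scheme.s(x[i - 1], y[j - 1]),
                    c[i - 1, j] + scheme.gap,
                    c[i, j - 1] + scheme.gap,
                )
            elif mode == "sw":
                c[i, j] = max(
                    floor,
                    c[i - 1, j - 1] + scheme.s(x[i - 1], y[j - 1]),
                    c[i - 1, j] + scheme.gap,
                    c[i, j - 1] + scheme.gap,
                )
            else:
                raise ValueError(f"unknown mode {mode!r}")
    score = int(c.max()) if mode == "sw" else int(c[n, m])
    return c, score


def oracle_affine(x: str, y: str, scheme: ScoringScheme):
    """The selector-bit affine recurrence, transcribed sequentially.

    Each cell keeps ``(value, tag)``: tag 1 means the value was produced by
    a gap step.  A gap step charges ``gap_open`` if the source tag is 0 and
    ``gap`` (extension only) if it is 1; diagonal results always carry tag
    0.  Ties prefer diagonal over vertical over horizontal, matching the
    traceback policy.  Returns ``(value matrix, tag matrix, score)``.
    """
    n, m = len(x), len(y)
    c = np.zeros((n + 1, m + 1), dtype=np.int64)
    tag = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = c[i - 1, j - 1] + scheme.s(x[i - 1], y[j - 1])
            up = c[i - 1, j] + (scheme.gap if tag[i - 1, j] else scheme.gap_open)
            left = c[i, j - 1] + (scheme.gap if tag[i, j - 1] else scheme.gap_open)
            best = max(diag, up, left)
            c[i, j] = best
            tag[i, j] = 0 if diag == best else 1
    return c, tag, int(c[n, m])


def oracle_gotoh(x: str, y: str, scheme: ScoringScheme) -> int:
    """Three-matrix Gotoh affine DP under the same free-end-gap convention.

    Used only as an empirical comparison point for the selector-bit scheme;
    the two need not agree in all cases.
    """
    n, m = len(x), len(y)
    neg = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), neg, dtype=np.int64)  # gap in x (left moves)
    F = np.full((n + 1, m + 1), neg, dtype=np.int64)  # gap in y (up moves)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] + scheme.gap, H[i, j - 1] + scheme.gap_open)
            F[i, j] = max(F[i - 1, j] + scheme.gap, H[i - 1, j] + scheme.gap_open)
            H[i, j] = max(
                H[i - 1, j - 1] + scheme.s(x[i - 1], y[j - 1]), E[i, j], F[i, j]
            )
    return int(H[n, m])


# ---------------------------------------------------------------------------
# exponential brute force (the oracle of the oracle, tiny sizes only)
# ---------------------------------------------------------------------------

def oracle_lcs_bruteforce(x: str, y: str) -> int:
    """Longest common subsequence by subsequence enumeration of ``x``."""
    best = 0
    for r in range(len(x), 0, -1):
        for idx in combinations(range(len(x)), r):
            sub = "".join(x[i] for i in idx)
            it = iter(y)
            if all(ch in it for ch in sub):
                return r
    return best


def oracle_alignment_bruteforce(x: str, y: str, scheme: ScoringScheme) -> int:
    """Max alignment score by enumerating all alignments (free leading gaps).

    A column is (x_i, y_j), (x_i, -) or (-, y_j).  Leading gap columns that
    all fall in the same sequence are free, mirroring the zero-initialised
    DP boundary.
    """

    def score(cols) -> int:
        k = 0
        if cols:
            which = None
            for a, b in cols:
                if a == GAP:
                    side = "x"
                elif b == GAP:
                    side = "y"
                else:
                    break
                if which is None:
                    which = side
                if side != which:
                    break
                k += 1
        total = 0
        for a, b in cols[k:]:
            total += scheme.gap if GAP in (a, b) else scheme.s(a, b)
        return total

    best = None
    stack = [(0, 0, [])]
    while stack:
        i, j, cols = stack.pop()
        if i == len(x) and j == len(y):
            v = score(cols)
            best = v if best is None else max(best, v)
            continue
        if i < len(x) and j < len(y):
            stack.append((i + 1, j + 1, cols + [(x[i], y[j])]))
        if i < len(x):
            stack.append((i + 1, j, cols + [(x[i], GAP)]))
        if j < len(y):
            stack.append((i, j + 1, cols + [(GAP, y[j])]))
    return best


# ---------------------------------------------------------------------------
# sum-of-pairs, argmax, buses
# ---------------------------------------------------------------------------

def oracle_sp(f, g, scheme: ScoringScheme) -> int:
    """Brute-force SP: explicit double loop over the merged residue pool."""
    pool = list(f) + list(g)
    total = 0
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            total += scheme.s(pool[i], pool[j])
    return total


def oracle_argmax(matrix) -> tuple[int, int]:
    """Linear-scan argmax with lexicographically-smallest tie breaking."""
    arr = np.asarray(matrix)
    best = None
    loc = None
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            if best is None or arr[i, j] > best:
                best = arr[i, j]
                loc = (i, j)
    return loc


def flood_fill_buses(mesh):
    """Bus structure by breadth-first flood fill over the port graph.

    Independent of the union-find resolver in :mod:`meshalign.mesh`.
    Returns a set of frozensets of ``(position, port)`` vertices.
    """
    from .mesh import PORTS, _ADJACENT  # graph definition only

    nodes = [(pos, p) for pos in mesh.units for p in PORTS]
    neighbours = {node: [] for node in nodes}
    for pos, pu in mesh.units.items():
        for group in pu.partition.groups:
            members = [(pos, p) for p in group]
            for a in members:
                for b in members:
                    if a != b:
                        neighbours[a].append(b)
    for (r, c) in mesh.units:
        for dr, dc, mine, theirs in _ADJACENT:
            nb = (r + dr, c + dc)
            if nb in mesh.units:
                neighbours[((r, c), mine)].append((nb, theirs))
                neighbours[(nb, theirs)].append(((r, c), mine))
    seen = set()
    buses = set()
    for start in nodes:
        if start in seen:
            continue
        comp = set()
        queue = deque([start])
        seen.add(start)
        while queue:
            v = queue.popleft()
            comp.add(v)
            for w in neighbours[v]:
                if w not in seen:
                    seen.add(w)
                    queue.append(w)
        buses.add(frozenset(comp))
    return buses


# ---------------------------------------------------------------------------
# end-to-end progressive reference
# ---------------------------------------------------------------------------

def oracle_progressive_msa(seqs, scheme: ScoringScheme, ids=None):
    """Self-contained sequential progressive MSA, coded independently.

    Mirrors the pipeline's study conditions — scale-up of negative schemes,
    zero-boundary NW, score-derived distances, neighbor joining with
    creation-order tie breaking, SP column scores by brute-force pair
    enumeration, diagonal > up > left traceback — but shares no DP, SP, NJ
    or mesh code with the package modules it checks.

    Returns ``(ids, aligned rows in input order)``.
    """
    if ids is None:
        ids = [f"seq{i}" for i in range(len(seqs))]
    lo = min(scheme.matrix.min_score(), scheme.gap, scheme.gap_gap)
    if scheme.gap_open is not None:
        lo = min(lo, scheme.gap_open)
    beta = max(0, -lo)

    def sc(a, b):
        if a == GAP and b == GAP:
            return scheme.gap_gap + beta
        if a == GAP or b == GAP:
            return scheme.gap + beta
        return scheme.matrix.score(a, b) + beta

    def sp(col_f, col_g):
        pool = list(col_f) + list(col_g)
        return sum(
            sc(pool[i], pool[j])
            for i in range(len(pool))
            for j in range(i + 1, len(pool))
        )

    def grid_align(rows_a, rows_b):
        """NW over columns; returns merged rows (a's rows first)."""
        la = len(rows_a[0]) if rows_a[0] else 0
        lb = len(rows_b[0]) if rows_b[0] else 0
        cols_a = ["".join(r[i] for r in rows_a) for i in range(la)]
        cols_b = ["".join(r[j] for r in rows_b) for j in range(lb)]
        gap_a = GAP * len(rows_a)
        gap_b = GAP * len(rows_b)
        c = [[0] * (lb + 1) for _ in range(la + 1)]
        for i in range(1, la + 1):
            for j in range(1, lb + 1):
                c[i][j] = max(
                    c[i - 1][j - 1] + sp(cols_a[i - 1], cols_b[j - 1]),
                    c[i - 1][j] + sp(cols_a[i - 1], gap_b),
                    c[i][j - 1] + sp(gap_a, cols_b[j - 1]),
                )
        i, j = la, lb
        steps = []
        while i > 0 or j > 0:
            if i == 0:
                steps.append("left")
                j -= 1
            elif j == 0:
                steps.append("up")
                i -= 1
            elif c[i][j] == c[i - 1][j - 1] + sp(cols_a[i - 1], cols_b[j - 1]):
                steps.append("diag")
                i, j = i - 1, j - 1
            elif c[i][j] == c[i - 1][j] + sp(cols_a[i - 1], gap_b):
                steps.append("up")
                i -= 1
            else:
                steps.append("left")
                j -= 1
        steps.reverse()
        out_a = [""] * len(rows_a)
        out_b = [""] * len(rows_b)
        i = j = 0
        for step in steps:
            if step in ("diag", "up"):
                for k, r in enumerate(rows_a):
                    out_a[k] += r[i]
                i += 1
            else:
                for k in range(len(rows_a)):
                    out_a[k] += GAP
            if step in ("diag", "left"):
                for k, r in enumerate(rows_b):
                    out_b[k] += r[j]
                j += 1
            else:
                for k in range(len(rows_b)):
                    out_b[k] += GAP
        return out_a + out_b

    # step (i): all-pairs NW scores (singleton "groups")
    m = len(seqs)
    S = [[0] * m for _ in range(m)]
    for i in range(m):
        for j in range(i, m):
            x, y = seqs[i], seqs[j]
            c = [[0] * (len(y) + 1) for _ in range(len(x) + 1)]
            for a in range(1, len(x) + 1):
                for b in range(1, len(y) + 1):
                    c[a][b] = max(
                        c[a - 1][b - 1] + sc(x[a - 1], y[b - 1]),
                        c[a - 1][b] + sc(x[a - 1], GAP),
                        c[a][b - 1] + sc(GAP, y[b - 1]),
                    )
            S[i][j] = S[j][i] = c[len(x)][len(y)]

    # step (ii): distances and neighbor joining
    top = max(max(row) for row in S)
    D = {(i, j): float(top - S[i][j]) if i != j else 0.0
         for i in range(m) for j in range(m)}
    active = list(range(m))
    groups = {i: ([ids[i]], [seqs[i]]) for i in range(m)}
    nxt = m
    while len(active) > 1:
        if len(active) == 2:
            i, j = sorted(active)
        else:
            mm = len(active)
            r = {a: sum(D[(a, b)] for b in active if b != a) / (mm - 2)
                 for a in active}
            best = None
            for a, b in combinations(sorted(active), 2):
                M = D[(a, b)] - r[a] - r[b]
                if best is None or M < best[0] - 1e-12:
                    best = (M, a, b)
            _, i, j = best
        ga, gb = groups.pop(i), groups.pop(j)
        merged_rows = grid_align(ga[1], gb[1])
        groups[nxt] = (ga[0] + gb[0], merged_rows)
        for v in active:
            if v not in (i, j):
                d = (D[(i, v)] + D[(j, v)] - D[(i, j)]) / 2
                D[(nxt, v)] = D[(v, nxt)] = max(d, 0.0)
        D[(nxt, nxt)] = 0.0
        active = [v for v in active if v not in (i, j)] + [nxt]
        nxt += 1

    out_ids, out_rows = groups[active[0]]
    row_of = dict(zip(out_ids, out_rows))
    return list(ids), [row_of[s] for s in ids]


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def oracle_nj(D, labels):
    """Independently coded neighbor joining, returning nested-tuple topology.

    Standard Saitou–Nei: join the pair minimising
    ``M_ij = D_ij - r_i - r_j`` with ``r_i = sum_j D_ij / (m - 2)``; update
    ``D_vu = (D_iv + D_jv - D_ij) / 2``.  Ties pick the earliest-created
    node pair (leaves in input order, then join order) — the same policy
    the guide-tree builder states.  Returns the final nested label tuple.
    """
    arr = np.asarray(D, dtype=float)
    m = len(labels)
    Dd = {(i, j): arr[i, j] for i in range(m) for j in range(m)}
    trees = {i: labels[i] for i in range(m)}
    active = list(range(m))
    nxt = m
    while len(active) > 1:
        if len(active) == 2:
            i, j = sorted(active)
        else:
            mm = len(active)
            r = {a: sum(Dd[(a, b)] for b in active if b != a) / (mm - 2)
                 for a in active}
            best = None
            for a, b in combinations(sorted(active), 2):
                M = Dd[(a, b)] - r[a] - r[b]
                if best is None or M < best[0]:
                    best = (M, a, b)
            _, i, j = best
        trees[nxt] = (trees[i], trees[j])
        for v in active:
            if v not in (i, j):
                Dd[(nxt, v)] = Dd[(v, nxt)] = (
                    Dd[(i, v)] + Dd[(j, v)] - Dd[(i, j)]
                ) / 2
        Dd[(nxt, nxt)] = 0.0
        active = [v for v in active if v not in (i, j)] + [nxt]
        nxt += 1
    return trees[active[0]]
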