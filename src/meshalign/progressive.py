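"""End-to-end progressive multiple sequence alignment.

The classic three-step paradigm: (i) all-pairs DP scores, (ii) a
neighbor-joining guide tree over distances derived from those scores,
(iii) guide-tree-ordered group-to-group DP alignment where the match score
of two columns is their counting-form sum-of-pairs.  A gap step inserts an
all-gap column into one group and is charged through the same SP function
with the gap treated as a symbol type, so step (iii) runs the very same DP
as step (i); two singleton groups reduce exactly to pairwise alignment.

Both DP engines are available: ``"reference"`` (sequential signed
integers) and ``"mesh"`` (simulated r-mesh components on unary values).
They follow identical recurrences and tie policies and must produce
identical output.  When the scheme has negative scores the whole pipeline
runs on its scaled-up form so every DP operand is non-negative — the mesh
precondition — and merge scores are reported in scaled units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .components import adder_subtractor, max_switch_nbit
from .dpmesh import align
from .errors import ContractViolation, InputError
from .guidetree import DistanceMatrix, GuideTree, distances_from_scores, nj_build
from .scoring import GAP, ProfileColumn, ScoringScheme, scale_up, sum_of_pair
from .unary import UNDERFLOW, decode, encode, underflow

__all__ = ["AlignedGroup", "MSAResult", "pairwise_all", "group_align", "progressive_msa"]


@dataclass
class AlignedGroup:
    """A set of equal-length gapped sequences with per-column profiles."""

    ids: list
    rows: list  # gapped strings, all the same length

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise InputError("aligned group rows must have equal length")

    @classmethod
    def from_sequence(cls, seq_id: str, seq: str) -> "AlignedGroup":
        return cls([seq_id], [seq])

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def size(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> ProfileColumn:
        return ProfileColumn.from_residues(r[j] for r in self.rows)

    def column_residues(self, j: int) -> list:
        return [r[j] for r in self.rows]

    def degapped(self) -> list:
        return [r.replace(GAP, "") for r in self.rows]


@dataclass
class MSAResult:
    """Final alignment, guide tree, per-merge scores and resource log."""

    alignment: AlignedGroup
    tree: GuideTree
    distances: DistanceMatrix
    pairwise_scores: np.ndarray
    merge_scores: list
    scheme_used: ScoringScheme
    resource_log: dict = field(default_factory=dict)


def pairwise_all(seqs, scheme: ScoringScheme, engine: str = "reference") -> np.ndarray:
    """Symmetric m x m matrix of global DP scores (diagonal = self scores)."""
    m = len(seqs)
    if m < 2:
        raise InputError("need at least 2 sequences")
    S = np.zeros((m, m), dtype=np.int64)
    for i in range(m):
        for j in range(i, m):
            res, _ = align(seqs[i], seqs[j], scheme, "nw", engine=engine)
            S[i, j] = S[j, i] = res.score
    return S


# ---------------------------------------------------------------------------
# group-to-group DP
# ---------------------------------------------------------------------------

def _grid_scores(A: AlignedGroup, B: AlignedGroup, scheme: ScoringScheme):
    """Pre-calculated SP operands: diagonal, up-step and left-step scores."""
    gap_col_A = ProfileColumn.from_residues([GAP] * A.size)
    gap_col_B = ProfileColumn.from_residues([GAP] * B.size)
    cols_A = [A.column(i) for i in range(A.length)]
    cols_B = [B.column(j) for j in range(B.length)]
    diag = np.array(
        [[sum_of_pair(ca, cb, scheme) for cb in cols_B] for ca in cols_A],
        dtype=np.int64,
    ).reshape(A.length, B.length)
    gx = np.array([sum_of_pair(ca, gap_col_B, scheme) for ca in cols_A], dtype=np.int64)
    gy = np.array([sum_of_pair(gap_col_A, cb, scheme) for cb in cols_B], dtype=np.int64)
    return diag, gx, gy


def _grid_dp_reference(diag, gx, gy) -> np.ndarray:
    LA, LB = diag.shape
    c = np.zeros((LA + 1, LB + 1), dtype=np.int64)
    for i in range(1, LA + 1):
        for j in range(1, LB + 1):
            c[i, j] = max(
                c[i - 1, j - 1] + diag[i - 1, j - 1],
                c[i - 1, j] + gx[i - 1],
                c[i, j - 1] + gy[j - 1],
            )
    return c


def _grid_dp_mesh(diag, gx, gy) -> np.ndarray:
    """Same recurrence through the unary mesh components.

    Each cell is three adder/subtractor units plus a max switch, exactly as
    in the pairwise DP mesh but with SP operands pre-loaded.
    """
    LA, LB = diag.shape
    hi = max(int(diag.max(initial=0)), int(gx.max(initial=0)), int(gy.max(initial=0)), 0)
    w = (LA + LB) * hi + 2

    def op(v, delta):
        out, _ = adder_subtractor(
            v, abs(int(delta)), "add" if delta >= 0 else "subtract", w
        )
        return out

    zero = encode(0, w)
    vals = [[zero] * (LB + 1) for _ in range(LA + 1)]
    c = np.zeros((LA + 1, LB + 1), dtype=np.int64)
    for i in range(1, LA + 1):
        for j in range(1, LB + 1):
            cand = [
                op(vals[i - 1][j - 1], diag[i - 1, j - 1]),
                op(vals[i - 1][j], gx[i - 1]),
                op(vals[i][j - 1], gy[j - 1]),
                underflow(w),
            ]
            cell, _ = max_switch_nbit(cand, w)
            vals[i][j] = cell
            dec = decode(cell)
            if dec is UNDERFLOW:
                raise ContractViolation(
                    f"group DP cell ({i},{j}) underflowed; scale the scheme up"
                )
            c[i, j] = dec
    return c


def _grid_traceback(c, diag, gx, gy):
    """Path through the column grid; ties prefer diagonal > up > left."""
    i, j = c.shape[0] - 1, c.shape[1] - 1
    steps = []
    while i > 0 or j > 0:
        if i == 0:
            steps.append("left")
            j -= 1
        elif j == 0:
            steps.append("up")
            i -= 1
        elif c[i, j] == c[i - 1, j - 1] + diag[i - 1, j - 1]:
            steps.append("diag")
            i, j = i - 1, j - 1
        elif c[i, j] == c[i - 1, j] + gx[i - 1]:
            steps.append("up")
            i -= 1
        elif c[i, j] == c[i, j - 1] + gy[j - 1]:
            steps.append("left")
            j -= 1
        else:
            raise ContractViolation(f"no neighbour explains group DP cell ({i},{j})")
    steps.reverse()
    return steps


def group_align(
    A: AlignedGroup,
    B: AlignedGroup,
    scheme: ScoringScheme,
    engine: str = "reference",
):
    """Align two pre-aligned groups column-against-column.

    Returns ``(merged AlignedGroup, DP score)``.  The merged group lists
    A's rows first, then B's; a gap step inserts an all-gap column into the
    other group.  For the mesh engine every SP operand must be
    non-negative (use a scaled scheme).
    """
    if A.length == 0 or B.length == 0:
        # degenerate: concatenate with all-gap padding
        merged_rows = [r + GAP * B.length for r in A.rows] + [
            GAP * A.length + r for r in B.rows
        ]
        return AlignedGroup(A.ids + B.ids, merged_rows), 0
    diag, gx, gy = _grid_scores(A, B, scheme)
    if engine == "mesh":
        c = _grid_dp_mesh(diag, gx, gy)
    elif engine == "reference":
        c = _grid_dp_reference(diag, gx, gy)
    else:
        raise InputError(f"unknown engine {engine!r}")
    steps = _grid_traceback(c, diag, gx, gy)
    new_A = [""] * A.size
    new_B = [""] * B.size
    i = j = 0
    for step in steps:
        if step == "diag":
            for k in range(A.size):
                new_A[k] += A.rows[k][i]
            for k in range(B.size):
                new_B[k] += B.rows[k][j]
            i += 1
            j += 1
        elif step == "up":
            for k in range(A.size):
                new_A[k] += A.rows[k][i]
            for k in range(B.size):
                new_B[k] += GAP
            i += 1
        else:
            for k in range(A.size):
                new_A[k] += GAP
            for k in range(B.size):
                new_B[k] += B.rows[k][j]
            j += 1
    merged = AlignedGroup(A.ids + B.ids, new_A + new_B)
    return merged, int(c[-1, -1])


def progressive_msa(
    seqs,
    scheme: ScoringScheme,
    ids=None,
    engine: str = "reference",
    paper_literal_nj: bool = False,
) -> MSAResult:
    """Steps (i)-(iii): pairwise scores, guide tree, ordered group merges.

    ``m - 1`` merges follow the neighbor-joining join order (children
    before parents; ties resolve to the earliest-created pair).  If the
    scheme has negative scores the pipeline runs on its scaled-up form.
    The output row order equals the input order and de-gapping the rows
    recovers the inputs exactly.
    """
    m = len(seqs)
    if m < 2:
        raise InputError("need at least 2 sequences")
    if ids is None:
        ids = [f"seq{i}" for i in range(m)]
    lo = min(scheme.matrix.min_score(), scheme.gap, scheme.gap_gap)
    if scheme.gap_open is not None:
        lo = min(lo, scheme.gap_open)
    work = scheme if lo >= 0 else scale_up(scheme)

    S = pairwise_all(seqs, work, engine=engine)
    dm = distances_from_scores(S, ids)
    tree = nj_build(dm, paper_literal=paper_literal_nj)

    groups = {}
    for i, (sid, seq) in enumerate(zip(ids, seqs)):
        groups[sid] = AlignedGroup.from_sequence(sid, seq)
    merge_scores = []
    for left, right, new in tree.merge_order:
        gl = groups.pop(left.label)
        gr = groups.pop(right.label)
        merged, score = group_align(gl, gr, work, engine=engine)
        groups[new.label] = merged
        merge_scores.append((new.label, score))
    (final,) = groups.values()

    # restore input row order
    row_of = {sid: r for sid, r in zip(final.ids, final.rows)}
    ordered = AlignedGroup(list(ids), [row_of[sid] for sid in ids])

    from . import resources

    log = resources.msa_resource_log(
        m=m, n=max(len(s) for s in seqs), scheme=work
    )
    return MSAResult(ordered, tree, dm, S, merge_scores, work, log)
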