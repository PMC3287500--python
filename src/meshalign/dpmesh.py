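"""Constant-time dynamic-programming alignment meshes.

Each DP cell ``c[i, j]`` is a composition of mesh components: three
adder/subtractor units apply the symbol-matching score (diagonal path) and
the gap score (vertical and horizontal paths), and a max switch propagates
the largest candidate onward.  Because values only flow down and right, the
assembly is simulated hierarchically — every component is still evaluated
through the port-level broadcast substrate, but cell results are passed
between component meshes by border values instead of wiring one flat
O(n^4)-unit grid.  The first row and column are initialised to zero, so
leading gaps in either sequence are free; the signed sequential oracles use
the same convention and must agree cell-for-cell.

Affine gap costs extend every travelling value by one selector bit (1 =
already gap-penalized).  The modified gap unit charges the full opening
cost to untagged values, while tagged values pass through an on/off switch
and pay the extension cost only; a 2-input max picks the survivor.

Unscaled schemes with non-negative substitution scores and a negative gap
score run directly on the mesh: gap branches subtract the gap magnitude and
carry the all-zero underflow pattern when they go negative, which loses
every max.  Matrices with negative entries must be scaled up first
(:func:`meshalign.scoring.scale_up`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .components import adder_subtractor, max_switch_nbit, on_off_switch
from .errors import CapacityError, ContractViolation, InputError
from .mesh import PortPartition
from .scoring import GAP, ScoringScheme
from .unary import UNDERFLOW, UnaryNumber, decode, encode, underflow

__all__ = [
    "GapTaggedValue",
    "DPMatrix",
    "AlignmentResult",
    "build_dp_mesh",
    "run_dp",
    "mesh_dp",
    "lcs_cell_config",
    "affine_minus_unit",
    "find_max_location",
    "traceback",
    "align",
]

MODES = ("nw", "sw", "lcs")


@dataclass(frozen=True)
class GapTaggedValue:
    """A unary value plus the affine selector bit (1 = gap already open)."""

    value: UnaryNumber
    selector: int = 0


@dataclass
class DPMatrix:
    """Computed DP scores plus everything traceback needs."""

    c: np.ndarray
    mode: str
    x: str
    y: str
    scheme: ScoringScheme
    tags: np.ndarray | None = None  # affine selector bits per cell

    @property
    def floor(self) -> int:
        """SW clamp value: ``beta`` under a scaled scheme, else 0."""
        return self.scheme.beta if self.scheme.scaled else 0


@dataclass
class AlignmentResult:
    """A decoded traceback: gapped sequences, score, and the cell path."""

    x: str
    y: str
    aligned_x: str
    aligned_y: str
    score: int
    path: list
    end: tuple

    def steps(self):
        """Yield ``(kind, i, j)`` per path step, with (i, j) the target cell."""
        for (i0, j0), (i1, j1) in zip(self.path, self.path[1:]):
            if i1 == i0 + 1 and j1 == j0 + 1:
                yield ("diag", i1, j1)
            elif i1 == i0 + 1:
                yield ("up", i1, j1)
            else:
                yield ("left", i1, j1)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass
class DPMeshAssembly:
    """A built (but not yet run) DP mesh for one sequence pair."""

    x: str
    y: str
    scheme: ScoringScheme
    mode: str
    width: int
    simulated_pus: int = 0

    def op(self, v: UnaryNumber, delta: int) -> UnaryNumber:
        """Signed add via the adder/subtractor component."""
        mode = "add" if delta >= 0 else "subtract"
        out, pus = adder_subtractor(v, abs(delta), mode, self.width)
        self.simulated_pus += pus
        return out

    def maxn(self, inputs) -> UnaryNumber:
        out, pus = max_switch_nbit(inputs, self.width)
        self.simulated_pus += pus
        return out


def _width_for(x: str, y: str, scheme: ScoringScheme, mode: str) -> int:
    if mode == "lcs":
        bound = min(len(x), len(y))
    else:
        per_step = max(
            scheme.matrix.max_score(),
            scheme.gap,
            scheme.gap_open or 0,
            scheme.beta if scheme.scaled else 0,
            0,
        )
        bound = (len(x) + len(y)) * per_step
    return bound + 2


def build_dp_mesh(
    x: str,
    y: str,
    scheme: ScoringScheme,
    mode: str = "nw",
    width: int | None = None,
) -> DPMeshAssembly:
    """Size-check the scheme and fix the unary width for one alignment.

    The width defaults to the smallest that holds the maximum attainable
    score plus the underflow slot; an explicit narrower width raises
    :class:`CapacityError` at build time rather than mid-broadcast.
    """
    if mode not in MODES:
        raise InputError(f"mode must be one of {MODES}")
    if mode in ("nw", "sw") and not scheme.is_mesh_safe():
        raise InputError(
            "mesh execution needs non-negative substitution scores; "
            "scale the scheme up first"
        )
    needed = _width_for(x, y, scheme, mode)
    if width is None:
        width = needed
    elif width < needed:
        raise CapacityError(
            f"width {width} cannot hold the maximum attainable score "
            f"(needs {needed})"
        )
    return DPMeshAssembly(x, y, scheme, mode, width)


def lcs_cell_config(symbols_equal: bool) -> PortPartition:
    """Port partition of the routing unit in an LCS cell.

    On a mismatch the unit configures {NS,E,W} so the max of the up/left
    values passes; on a match it configures {N,E,SW} so the diagonal value,
    incremented by one, passes instead.
    """
    return PortPartition.parse("N,E,SW" if symbols_equal else "NS,E,W")


def affine_minus_unit(
    v: GapTaggedValue, scheme: ScoringScheme, width: int, assembly: DPMeshAssembly | None = None
) -> GapTaggedValue:
    """The modified gap unit for affine costs.

    The base unit charges the extension cost.  A value not yet
    gap-penalized (selector 0) is additionally charged ``eps = gap -
    gap_open`` on a side path while the on/off switch blocks the
    extension-only branch; a tagged value (selector 1) keeps the larger,
    extension-only branch.  The output always carries selector 1.
    """
    if not scheme.affine:
        raise InputError("scheme has no affine costs")

    def op(val, delta):
        if assembly is not None:
            return assembly.op(val, delta)
        out, _ = adder_subtractor(val, abs(delta), "add" if delta >= 0 else "subtract", width)
        return out

    extended = op(v.value, scheme.gap)  # base "-" unit: extension charge
    opened = op(extended, -scheme.eps)  # side path: full opening charge
    admitted, _ = on_off_switch(extended, v.selector, width)
    if assembly is not None:
        assembly.simulated_pus += width * (width + 1)
        best = assembly.maxn([opened, admitted, underflow(width)])
    else:
        best, _ = max_switch_nbit([opened, admitted, underflow(width)], width)
    return GapTaggedValue(best, 1)


def run_dp(assembly: DPMeshAssembly) -> DPMatrix:
    """Evaluate every cell through the component meshes.

    Cells are visited in topological (row-major) order of the acyclic
    value-flow graph; each visit assigns operands to component borders,
    broadcasts once per component, and reads the result — functionally
    equivalent to the single-broadcast flat mesh.
    """
    x, y, scheme, mode, w = (
        assembly.x,
        assembly.y,
        assembly.scheme,
        assembly.mode,
        assembly.width,
    )
    n, m = len(x), len(y)
    zero = encode(0, w)
    floor_val = scheme.beta if scheme.scaled else 0
    vals = [[zero] * (m + 1) for _ in range(n + 1)]
    tags = [[0] * (m + 1) for _ in range(n + 1)] if scheme.affine else None
    c = np.zeros((n + 1, m + 1), dtype=np.int64)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d, u, l = vals[i - 1][j - 1], vals[i - 1][j], vals[i][j - 1]
            if mode == "lcs":
                if x[i - 1] == y[j - 1]:
                    cell = assembly.op(d, 1)
                else:
                    cell = assembly.maxn([u, l, underflow(w)])
            elif scheme.affine:
                diag = assembly.op(d, scheme.s(x[i - 1], y[j - 1]))
                gv = affine_minus_unit(
                    GapTaggedValue(u, tags[i - 1][j]), scheme, w, assembly
                )
                gh = affine_minus_unit(
                    GapTaggedValue(l, tags[i][j - 1]), scheme, w, assembly
                )
                cell = assembly.maxn([diag, gv.value, gh.value])
                tags[i][j] = 0 if diag.bits == cell.bits else 1
            else:
                diag = assembly.op(d, scheme.s(x[i - 1], y[j - 1]))
                gv = assembly.op(u, scheme.gap)
                gh = assembly.op(l, scheme.gap)
                inputs = [diag, gv, gh]
                if mode == "sw":
                    inputs.append(encode(floor_val, w))
                else:
                    inputs.append(underflow(w))
                cell = assembly.maxn(inputs)
            vals[i][j] = cell
            dec = decode(cell)
            if dec is UNDERFLOW:
                raise ContractViolation(f"cell ({i},{j}) decoded to underflow")
            c[i, j] = dec

    return DPMatrix(
        c,
        mode,
        x,
        y,
        scheme,
        tags=np.array(tags, dtype=np.int8) if tags is not None else None,
    )


def mesh_dp(x, y, scheme, mode="nw", width=None) -> DPMatrix:
    """Convenience: build and run the DP mesh in one call."""
    return run_dp(build_dp_mesh(x, y, scheme, mode, width))


# ---------------------------------------------------------------------------
# max location (3-D staged rounds) and traceback
# ---------------------------------------------------------------------------

def _max_of_n(values: np.ndarray) -> int:
    """Index of the max of n values via the n x n flag-matrix rounds.

    Builds ``f(i, j) = 1 iff a_i > a_j``; a column whose OR is 0 holds a
    maximum.  The smallest such column index is returned.
    """
    a = np.asarray(values)
    flags = a[:, None] > a[None, :]
    dominated = flags.any(axis=0)
    return int(np.flatnonzero(~dominated)[0])


def find_max_location(matrix: DPMatrix) -> tuple[int, int]:
    """Argmax cell of the DP matrix via the staged 3-D mesh rounds.

    Each matrix row is fanned out to its own 2-D slice, every slice locates
    its max column with the flag-matrix subroutine, the column indices
    return to the first slice, and a final max over the per-row champions
    picks the winner.  Ties resolve to the lexicographically smallest
    (i, j).
    """
    c = matrix.c
    row_champions = np.array([_max_of_n(c[k]) for k in range(c.shape[0])])
    champion_values = c[np.arange(c.shape[0]), row_champions]
    best_row = _max_of_n(champion_values)
    return best_row, int(row_champions[best_row])


def traceback(
    matrix: DPMatrix,
    end: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> AlignmentResult:
    """Decode the alignment path by neighbor-of-max port fusing.

    Starting from the end cell — ``c[n, m]`` for NW/LCS, the max cell for
    SW — each cell fuses toward the neighbour whose value explains its own
    under the recurrence.  Ties prefer diagonal over vertical over
    horizontal (or are drawn from ``rng`` if given).  SW stops at the first
    cell holding the floor value; NW/LCS continue through the free
    boundary to ``c[0, 0]``.
    """
    c, mode, x, y, scheme = matrix.c, matrix.mode, matrix.x, matrix.y, matrix.scheme
    if end is None:
        end = find_max_location(matrix) if mode == "sw" else (len(x), len(y))
    i, j = end
    path = [(i, j)]
    cols: list[tuple[str, str]] = []
    while True:
        if mode == "sw" and c[i, j] == matrix.floor:
            break
        if i == 0 and j == 0:
            break
        if i == 0:
            cols.append((GAP, y[j - 1]))
            j -= 1
        elif j == 0:
            cols.append((x[i - 1], GAP))
            i -= 1
        else:
            moves = []
            here = c[i, j]
            if mode == "lcs":
                if x[i - 1] == y[j - 1]:
                    if here == c[i - 1, j - 1] + 1:
                        moves.append("diag")
                else:
                    if here == c[i - 1, j]:
                        moves.append("up")
                    if here == c[i, j - 1]:
                        moves.append("left")
            elif scheme.affine:
                if here == c[i - 1, j - 1] + scheme.s(x[i - 1], y[j - 1]):
                    moves.append("diag")
                up_charge = scheme.gap if matrix.tags[i - 1, j] else scheme.gap_open
                if here == c[i - 1, j] + up_charge:
                    moves.append("up")
                left_charge = scheme.gap if matrix.tags[i, j - 1] else scheme.gap_open
                if here == c[i, j - 1] + left_charge:
                    moves.append("left")
            else:
                if here == c[i - 1, j - 1] + scheme.s(x[i - 1], y[j - 1]):
                    moves.append("diag")
                if here == c[i - 1, j] + scheme.gap:
                    moves.append("up")
                if here == c[i, j - 1] + scheme.gap:
                    moves.append("left")
            if not moves:
                raise ContractViolation(
                    f"no neighbour explains c[{i},{j}] = {c[i, j]}"
                )
            move = moves[0] if rng is None else moves[rng.integers(len(moves))]
            if move == "diag":
                cols.append((x[i - 1], y[j - 1]))
                i, j = i - 1, j - 1
            elif move == "up":
                cols.append((x[i - 1], GAP))
                i -= 1
            else:
                cols.append((GAP, y[j - 1]))
                j -= 1
        path.append((i, j))
    path.reverse()
    cols.reverse()
    aligned_x = "".join(a for a, _ in cols)
    aligned_y = "".join(b for _, b in cols)
    score = int(c[end])
    return AlignmentResult(x, y, aligned_x, aligned_y, score, path, end)


def align(
    x: str,
    y: str,
    scheme: ScoringScheme,
    mode: str = "nw",
    engine: str = "reference",
    rng: np.random.Generator | None = None,
) -> tuple[AlignmentResult, DPMatrix]:
    """Pairwise alignment through either backend.

    ``engine="mesh"`` runs the simulated r-mesh; ``engine="reference"``
    uses the sequential oracles (same recurrence and conventions, plain
    integers).  Both return the traceback result and the DP matrix.
    """
    if engine == "mesh":
        matrix = mesh_dp(x, y, scheme, mode)
    elif engine == "reference":
        from . import oracles

        if scheme.affine and mode == "nw":
            c, tags, _ = oracles.oracle_affine(x, y, scheme)
            matrix = DPMatrix(c, mode, x, y, scheme, tags=tags)
        else:
            c, _ = oracles.oracle_dp(x, y, scheme, mode)
            matrix = DPMatrix(c, mode, x, y, scheme)
    else:
        raise InputError(f"unknown engine {engine!r}")
    return traceback(matrix, rng=rng), matrix
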