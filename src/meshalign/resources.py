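"""Closed-form processing-unit accounting for every mesh component.

Run-time claims of the parallel design (O(1) broadcasts per component, O(m)
for the full progressive pipeline) are not wall-clock measurable in a
simulator; they are tracked as resource counts instead.  The formulas here
are the flat PU totals of each construction for a given unary width ``n``
(or operand magnitude ``k``, sequence count ``m``); simulated meshes report
their own ``pu_count`` which matches the component formulas exactly.

The per-cell figure for constant scoring schemes books 4n units for the
max switch and 2n for each of the three adder/subtractor units — 10n per
DP cell, hence O(n^3) for the n x n DP mesh and O(m n^3) for the whole
constant-scheme MSA (O(k n^3) per DP mesh and O(m n^4) in general).
"""

from __future__ import annotations

__all__ = [
    "max_switch_2input_1bit",
    "max_switch_4input_1bit",
    "max_switch_2input_nbit",
    "max_switch_4input_nbit",
    "on_off_switch_units",
    "adder_subtractor_units",
    "dp_cell_constant",
    "dp_mesh_constant",
    "dp_mesh_general",
    "backtracking_units",
    "nj_units",
    "sum_of_pair_units",
    "msa_constant_units",
    "msa_general_units",
    "msa_resource_log",
]


def max_switch_2input_1bit() -> int:
    return 1


def max_switch_4input_1bit() -> int:
    return 4


def max_switch_2input_nbit(n: int) -> int:
    return n


def max_switch_4input_nbit(n: int) -> int:
    return 4 * n


def on_off_switch_units(n: int) -> int:
    return n * (n + 1)


def adder_subtractor_units(k: int, n: int) -> int:
    return k * n


def dp_cell_constant(n: int) -> int:
    """10n per cell: a 4n max switch plus three 2n adder/subtractor units."""
    return max_switch_4input_nbit(n) + 3 * 2 * n


def dp_mesh_constant(n: int) -> int:
    """n x n cells of 10n units each — the O(n^3) constant-scheme DP mesh."""
    return n * n * dp_cell_constant(n)


def dp_mesh_general(n: int, k: int) -> int:
    """General scoring: k x n adder meshes per cell — O(k n^3)."""
    return n * n * (max_switch_4input_nbit(n) + 3 * adder_subtractor_units(k, n))


def backtracking_units(n: int) -> int:
    """The 3-D n x n x n max-location mesh."""
    return n ** 3


def nj_units(m: int) -> int:
    """Neighbor joining on an m x m distance matrix — O(m^3)."""
    return m ** 3


def sum_of_pair_units(m: int, n: int) -> int:
    """All n^2 column-pair SP scores on m-unit arrays — m x n^2."""
    return m * n * n


def msa_constant_units(m: int, n: int) -> int:
    """Whole pipeline with a constant scoring scheme — O(m n^3)."""
    return m * dp_mesh_constant(n)


def msa_general_units(m: int, n: int, k: int) -> int:
    """Whole pipeline with a general scheme — O(m n^4) when k ~ n."""
    return m * dp_mesh_general(n, k)


def msa_resource_log(m: int, n: int, scheme) -> dict:
    """Per-stage PU accounting for one progressive MSA run."""
    k = max(
        abs(scheme.gap),
        abs(scheme.matrix.max_score()),
        1,
    )
    constant = scheme.matrix.max_score() <= 1 and abs(scheme.gap) <= 1
    return {
        "m": m,
        "n": n,
        "k": k,
        "dp_cell_units": dp_cell_constant(n) if constant else None,
        "dp_mesh_units": dp_mesh_constant(n) if constant else dp_mesh_general(n, k),
        "backtracking_units": backtracking_units(n),
        "nj_units": nj_units(m),
        "sum_of_pair_units": sum_of_pair_units(m, n),
        "msa_units": msa_constant_units(m, n) if constant else msa_general_units(m, n, k),
        "scheme_constant": constant,
    }
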