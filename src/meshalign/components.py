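"""Reusable r-mesh components built on the broadcast substrate.

Every component here follows the same evaluation contract: build (or fetch a
cached copy of) a :class:`~meshalign.mesh.MeshConfig`, assign operand bits to
border ports, perform exactly one broadcasting step, and read the result off
a border.  The unary (1UN) encoding makes each of them a pure routing
problem:

* **max switches** — on a shared bus a 1 dominates (OR), and the bitwise OR
  of two prefix patterns is the encoding of their maximum;
* **adder/subtractor** — a ``k x w`` grid whose rows each shift the prefix
  boundary by one position: k increments (addition, fed North, read South)
  or k decrements (subtraction, fed South, read North).  A prefix that
  shifts off the low end leaves the all-zero underflow pattern;
* **on/off switch** — a ``w x (w+1)`` grid of L-shaped paths that either
  passes the whole operand to the East border or blocks it, controlled by a
  selector bit.

Mesh geometries are cached per shape; evaluation only rewrites the boundary
drive bits and re-broadcasts, which keeps the simulated-port semantics while
letting the DP meshes evaluate thousands of component instances.
"""

from __future__ import annotations

from functools import lru_cache

from .errors import CapacityError, InputError
from .mesh import BusNetwork, MeshConfig, broadcast, pu_count, resolve_buses
from .unary import UnaryNumber, decode, encode, underflow

__all__ = [
    "build_max_switch_2input",
    "build_max_switch_4input",
    "build_adder_subtractor",
    "build_on_off_switch",
    "max_switch_1bit",
    "max_switch_nbit",
    "adder_subtractor",
    "on_off_switch",
]


# ---------------------------------------------------------------------------
# builders (public: used by the CLI and by resource accounting)
# ---------------------------------------------------------------------------

def build_max_switch_2input() -> MeshConfig:
    """1 PU fused {NSEW}: N and W are inputs, E and S read the OR."""
    m = MeshConfig((1, 1))
    m.add_unit(0, 0, "NSEW", role_tag="max2")
    return m


def build_max_switch_4input() -> MeshConfig:
    """The 4-PU 1-bit 4-input max switch.

    Port configurations {NSW,E}, {NSE,W}, {NE,S,W}, {NSW,E} laid out on a
    2x2 grid wire the four input ports onto a single bus, so the output is
    the OR (= max) of the inputs.
    """
    m = MeshConfig((2, 2))
    m.add_unit(0, 0, "NSW,E", role_tag="max4")
    m.add_unit(0, 1, "NSE,W", role_tag="max4")
    m.add_unit(1, 0, "NE,S,W", role_tag="max4")
    m.add_unit(1, 1, "NSW,E", role_tag="max4")
    return m


def build_adder_subtractor(b: int, w: int) -> MeshConfig:
    """The k x w adder/subtractor for a pre-loaded operand magnitude ``b``.

    The second operand is left-shifted one bit (dropping the bit that
    represents zero) and fed into the West border, so only its ``k = b``
    one-bits need rows; rows for trailing zeros are omitted.  Every kept row
    sees West = 1 and therefore fuses {NE,SW}; a row with West = 0 would
    fuse {NS,E,W} (a pass-through) and is exactly the kind of row the
    reduction removes.
    """
    if b < 0:
        raise InputError("pre-loaded operand must be non-negative")
    if b > w - 1:
        raise CapacityError(f"operand {b} does not fit in width {w}")
    m = MeshConfig((max(b, 1), w))
    for r in range(max(b, 1)):
        west = 1 if r < b else 0
        for c in range(w):
            m.add_unit(r, c, "NE,SW" if west else "NS,E,W", role_tag="addsub")
        m.boundary_inputs[("W", r)] = west
    return m


def build_on_off_switch(w: int, selector: int) -> MeshConfig:
    """The w x (w+1) on/off switch gating a w-bit operand.

    Column ``i`` fuses with row ``w-1-i`` into an L-shaped path from the
    North border to the last column; the last column passes each row's bit
    to the East border when the selector signal is on and blocks it
    otherwise.  The printed construction fuses last-column cells as a signal
    travels through them; under atomic OR-bus semantics that cascade is
    modelled as configure-time switching from the selector bit.
    """
    m = MeshConfig((w, w + 1))
    for r in range(w):
        for c in range(w):
            if r + c == w - 1:
                m.add_unit(r, c, "NE,S,W", role_tag="onoff")
            elif r + c < w - 1:
                m.add_unit(r, c, "NS,E,W", role_tag="onoff")
            else:
                m.add_unit(r, c, "N,S,EW", role_tag="onoff")
        m.add_unit(r, w, "EW,N,S" if selector else "NS,E,W", role_tag="onoff-sel")
    return m


# ---------------------------------------------------------------------------
# cached geometry + network (evaluation fast path)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _max2() -> tuple[MeshConfig, BusNetwork]:
    m = build_max_switch_2input()
    return m, resolve_buses(m)


@lru_cache(maxsize=None)
def _max4() -> tuple[MeshConfig, BusNetwork]:
    m = build_max_switch_4input()
    return m, resolve_buses(m)


@lru_cache(maxsize=256)
def _addsub(b: int, w: int) -> tuple[MeshConfig, BusNetwork]:
    m = build_adder_subtractor(b, w)
    return m, resolve_buses(m)


@lru_cache(maxsize=64)
def _onoff(w: int, selector: int) -> tuple[MeshConfig, BusNetwork]:
    m = build_on_off_switch(w, selector)
    return m, resolve_buses(m)


# ---------------------------------------------------------------------------
# evaluated components
# ---------------------------------------------------------------------------

def max_switch_1bit(inputs) -> tuple[int, int]:
    """Max (= OR) of 2 to 4 bits in one broadcast.

    Returns ``(bit, simulated PU count)``: 1 PU for the 2-input switch, 4
    for the 3- and 4-input forms (a 3-input use feeds a zero into one
    input port).
    """
    bits = tuple(inputs)
    if not 2 <= len(bits) <= 4:
        raise InputError("max switch takes 2 to 4 input bits")
    if any(b not in (0, 1) for b in bits):
        raise InputError("inputs must be bits")
    if len(bits) == 2:
        m, net = _max2()
        m.boundary_inputs = {("N", 0): bits[0], ("W", 0): bits[1]}
        broadcast(m, net)
        return net.read_border("E", 0), pu_count(m)
    padded = bits + (0,) * (4 - len(bits))
    m, net = _max4()
    m.boundary_inputs = {
        ("N", 0): padded[0],
        ("N", 1): padded[1],
        ("W", 0): padded[2],
        ("E", 0): padded[3],
    }
    broadcast(m, net)
    return net.read_border("S", 1), pu_count(m)


def max_switch_nbit(inputs, w: int) -> tuple[UnaryNumber, int]:
    """Max of 3-4 w-bit unary numbers: one 4-input 1-bit switch per plane.

    The all-zero underflow pattern drives nothing and so loses to every
    valid encoding.  Uses ``4w`` simulated PUs.
    """
    ins = list(inputs)
    if not 3 <= len(ins) <= 4:
        raise InputError("n-bit max switch takes 3 or 4 inputs")
    for u in ins:
        if u.width != w:
            raise InputError(f"width mismatch: {u.width} != {w}")
    while len(ins) < 4:
        ins.append(underflow(w))
    out_bits = []
    pus = 0
    for i in range(w):
        bit, p = max_switch_1bit(tuple(u.bits[i] for u in ins))
        out_bits.append(bit)
        pus += p
    return UnaryNumber(w, tuple(out_bits)), pus


def adder_subtractor(a: UnaryNumber, b: int, mode: str, w: int) -> tuple[UnaryNumber, int]:
    """``a + b`` or ``a - b`` on the k x w mesh in one broadcast.

    ``b`` is the pre-loaded (configure-time) operand.  A subtraction that
    would go negative yields the all-zero underflow pattern; an underflow
    input propagates as underflow so that downstream max switches can never
    resurrect a dead branch.
    """
    if mode not in ("add", "subtract"):
        raise InputError(f"mode must be 'add' or 'subtract', got {mode!r}")
    if a.width != w:
        raise InputError(f"width mismatch: {a.width} != {w}")
    if a.is_underflow:
        return underflow(w), b * w
    if mode == "add":
        val = decode(a)
        if val + b > w - 1:
            raise CapacityError(f"{val} + {b} does not fit in width {w}")
    if b == 0:
        return a, 0
    m, net = _addsub(b, w)
    k = b
    if mode == "add":
        m.boundary_inputs = {("W", r): 1 for r in range(k)}
        m.boundary_inputs.update({("N", c): a.bits[c] for c in range(w)})
        broadcast(m, net)
        bits = tuple(net.read_border("S", c) for c in range(w))
    else:
        m.boundary_inputs = {("W", r): 1 for r in range(k)}
        m.boundary_inputs.update({("S", c): a.bits[c] for c in range(w)})
        m.boundary_inputs.update({("E", r): 0 for r in range(k)})
        broadcast(m, net)
        bits = tuple(net.read_border("N", c) for c in range(w))
    return UnaryNumber(w, bits), pu_count(m)


def on_off_switch(value: UnaryNumber, selector: int, w: int) -> tuple[UnaryNumber, int]:
    """Gate a w-bit operand: selector 1 passes it, 0 yields all zeros.

    Uses ``w * (w+1)`` simulated PUs; the operand's bit ``i`` exits on the
    East border at row ``w-1-i``.
    """
    if value.width != w:
        raise InputError(f"width mismatch: {value.width} != {w}")
    if selector not in (0, 1):
        raise InputError("selector must be a bit")
    m, net = _onoff(w, selector)
    m.boundary_inputs = {("N", c): value.bits[c] for c in range(w)}
    broadcast(m, net)
    bits = tuple(net.read_border("E", w - 1 - i) for i in range(w))
    return UnaryNumber(w, bits), pu_count(m)
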