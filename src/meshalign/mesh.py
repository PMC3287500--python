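"""The reconfigurable-mesh (r-mesh) computing substrate.

An r-mesh is a 2-D grid of processing units, each with four ports
(N, S, E, W).  A unit may *fuse* subsets of its ports into groups; fused
ports, together with the fixed wiring between abutting ports of neighbouring
units (E of ``(r, c)`` abuts W of ``(r, c+1)``, S of ``(r, c)`` abuts N of
``(r+1, c)``), form *buses*: maximal connected sets of ports.  In one
broadcasting step every bus carries the logical OR of all bits driven onto
it, and every port on the bus reads that value.  OR resolution of concurrent
writes models a common-collector electrical bus: a 1 anywhere dominates,
which is exactly the property the unary max switches exploit.

Coordinates are 0-based with row 0 at the top.  Large assemblies are
simulated hierarchically (component meshes exchanging border values) rather
than as one flat grid; ``pu_count`` accounting still reports flat totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

__all__ = [
    "PORTS",
    "PortPartition",
    "ProcessingUnit",
    "MeshConfig",
    "BusNetwork",
    "enumerate_port_partitions",
    "resolve_buses",
    "broadcast",
    "pu_count",
]

PORTS = ("N", "S", "E", "W")
_PORT_INDEX = {p: i for i, p in enumerate(PORTS)}

# abutting-port wiring: (row offset, col offset, my port, neighbour port)
_ADJACENT = (
    (0, 1, "E", "W"),
    (1, 0, "S", "N"),
)


@dataclass(frozen=True)
class PortPartition:
    """A partition of the four port labels into disjoint fused groups."""

    groups: tuple[frozenset, ...]

    def __post_init__(self):
        labels = [p for g in self.groups for p in g]
        if sorted(labels) != sorted(PORTS):
            raise ValueError(f"not a partition of {PORTS}: {self.groups}")
        # canonical order: groups sorted by their lowest port index
        canon = tuple(
            sorted(
                (frozenset(g) for g in self.groups),
                key=lambda g: min(_PORT_INDEX[p] for p in g),
            )
        )
        object.__setattr__(self, "groups", canon)

    @classmethod
    def parse(cls, spec: str) -> "PortPartition":
        """Build from a compact string such as ``"NE,SW"`` or ``"NS,E,W"``."""
        return cls(tuple(frozenset(part) for part in spec.split(",")))

    @property
    def is_lr_legal(self) -> bool:
        """Linear r-mesh legality: no fused group of three or more ports."""
        return all(len(g) < 3 for g in self.groups)

    def group_of(self, port: str) -> frozenset:
        for g in self.groups:
            if port in g:
                return g
        raise KeyError(port)

    def __str__(self) -> str:
        return "{" + "},{".join(
            "".join(sorted(g, key=_PORT_INDEX.get)) for g in self.groups
        ) + "}"


def enumerate_port_partitions() -> list[PortPartition]:
    """All distinct partitions of {N, S, E, W} in a stable canonical order.

    There are exactly 15 (the Bell number B(4)); the five containing a fused
    group of three or more ports are the ones a Linear r-mesh forbids.
    """
    parts: list[PortPartition] = []
    seen = set()
    # assign each port a block id; normalise by first-occurrence relabelling
    for assignment in product(range(4), repeat=4):
        blocks: dict[int, set] = {}
        for port, b in zip(PORTS, assignment):
            blocks.setdefault(b, set()).add(port)
        key = frozenset(frozenset(g) for g in blocks.values())
        if key in seen:
            continue
        seen.add(key)
        parts.append(PortPartition(tuple(frozenset(g) for g in blocks.values())))
    # stable order: by number of groups (coarsest first), then lexicographic
    parts.sort(key=lambda p: (len(p.groups), str(p)))
    return parts


#: the fully-defused partition {N},{S},{E},{W}
SINGLETONS = PortPartition.parse("N,S,E,W")


@dataclass
class ProcessingUnit:
    """One grid node: a port partition plus a small local register store."""

    position: tuple
    partition: PortPartition = SINGLETONS
    registers: dict = field(default_factory=dict)
    role_tag: str = ""


@dataclass
class MeshConfig:
    """A configured grid of processing units with boundary drive bits.

    ``boundary_inputs`` maps ``(border, index)`` to a bit driven into that
    border port: ``("N", c)`` drives the North port of unit ``(0, c)``,
    ``("S", c)`` the South port of ``(rows-1, c)``, ``("W", r)`` the West
    port of ``(r, 0)`` and ``("E", r)`` the East port of ``(r, cols-1)``.
    ``drives`` may additionally force a bit onto any ``(position, port)``.
    """

    dims: tuple[int, int]
    units: dict = field(default_factory=dict)
    boundary_inputs: dict = field(default_factory=dict)
    drives: dict = field(default_factory=dict)

    def __post_init__(self):
        rows, cols = self.dims
        for pos in self.units:
            r, c = pos
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"unit position {pos} outside dims {self.dims}")

    def unit(self, r: int, c: int) -> ProcessingUnit:
        return self.units[(r, c)]

    def add_unit(self, r, c, partition, role_tag: str = "") -> ProcessingUnit:
        if isinstance(partition, str):
            partition = PortPartition.parse(partition)
        pu = ProcessingUnit((r, c), partition, role_tag=role_tag)
        self.units[(r, c)] = pu
        return pu

    def border_port(self, border: str, index: int) -> tuple[tuple, str]:
        rows, cols = self.dims
        if border == "N":
            return (0, index), "N"
        if border == "S":
            return (rows - 1, index), "S"
        if border == "W":
            return (index, 0), "W"
        if border == "E":
            return (index, cols - 1), "E"
        raise ValueError(f"unknown border {border!r}")


class _DSU:
    """Array-based union-find with path halving."""

    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


@dataclass
class BusNetwork:
    """Connected components over (unit, port) vertices, with 1-bit values."""

    mesh: MeshConfig
    bus_of: dict  # (position, port) -> bus id
    buses: list  # bus id -> sorted list of (position, port)
    values: list = field(default_factory=list)  # bus id -> bit

    def ports_of(self, bus_id: int) -> list:
        return self.buses[bus_id]

    def read(self, pos: tuple, port: str) -> int:
        return self.values[self.bus_of[(pos, port)]]

    def read_border(self, border: str, index: int) -> int:
        return self.read(*self.mesh.border_port(border, index))


def resolve_buses(mesh: MeshConfig) -> BusNetwork:
    """Compute the bus structure: components of the fusion/adjacency graph.

    Bus ids are deterministic: buses are numbered by their smallest member
    port in (row, col, port-index) order.
    """
    rows, cols = mesh.dims
    positions = mesh.units.keys()

    def pid(pos, port):
        r, c = pos
        return (r * cols + c) * 4 + _PORT_INDEX[port]

    dsu = _DSU(rows * cols * 4)
    for pos, pu in mesh.units.items():
        for group in pu.partition.groups:
            ports = sorted(group, key=_PORT_INDEX.get)
            for other in ports[1:]:
                dsu.union(pid(pos, ports[0]), pid(pos, other))
    for (r, c) in positions:
        for dr, dc, mine, theirs in _ADJACENT:
            nb = (r + dr, c + dc)
            if nb in mesh.units:
                dsu.union(pid((r, c), mine), pid(nb, theirs))

    roots: dict[int, int] = {}
    buses: list[list] = []
    bus_of: dict = {}
    for pos in sorted(positions):
        for port in PORTS:
            root = dsu.find(pid(pos, port))
            if root not in roots:
                roots[root] = len(buses)
                buses.append([])
            b = roots[root]
            bus_of[(pos, port)] = b
            buses[b].append((pos, port))
    return BusNetwork(mesh, bus_of, buses)


def broadcast(mesh: MeshConfig, network: BusNetwork | None = None) -> BusNetwork:
    """One atomic broadcasting step: every bus reads the OR of its drivers.

    Deterministic and idempotent; an undriven bus reads 0.  Returns the bus
    network with ``values`` filled in.
    """
    net = network if network is not None else resolve_buses(mesh)
    values = [0] * len(net.buses)
    for (border, index), bit in mesh.boundary_inputs.items():
        if bit:
            values[net.bus_of[mesh.border_port(border, index)]] = 1
    for key, bit in mesh.drives.items():
        if bit:
            values[net.bus_of[key]] = 1
    net.values = values
    return net


def pu_count(mesh: MeshConfig) -> int:
    """Number of processing units in the configuration (resource accounting)."""
    return len(mesh.units)
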