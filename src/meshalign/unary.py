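"""Unary (1UN) fixed-width number representation.

A non-negative integer ``x`` with ``0 <= x <= w-1`` is stored in ``w`` bits as a
prefix of ``x + 1`` ones followed by zeros, e.g. 3 at width 8 is ``11110000``.
The all-zero pattern is reserved: it marks an underflow (the result of an
arithmetic step that went negative) and decodes to no integer.  This encoding
is what lets the mesh components below compute max by bitwise OR and
add/subtract by shifting the prefix boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CapacityError, RepresentationError

__all__ = ["UnaryNumber", "UNDERFLOW", "encode", "decode", "left_shift_one"]


class _Underflow:
    """Singleton marker returned by :func:`decode` for the all-zero pattern."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - repr only
        return "UNDERFLOW"


#: Decoded value of the reserved all-zero pattern.
UNDERFLOW = _Underflow()


@dataclass(frozen=True)
class UnaryNumber:
    """A fixed-width 1UN bit vector ``b_0 .. b_{w-1}``.

    ``bits`` is stored most-significant-prefix first: ``bits[i]`` is ``b_i``.
    """

    width: int
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.width < 1:
            raise RepresentationError("width must be >= 1")
        if len(self.bits) != self.width:
            raise RepresentationError(
                f"expected {self.width} bits, got {len(self.bits)}"
            )
        if any(b not in (0, 1) for b in self.bits):
            raise RepresentationError("bits must be 0/1")

    # -- predicates --------------------------------------------------------
    @property
    def is_underflow(self) -> bool:
        return not any(self.bits)

    @property
    def is_prefix(self) -> bool:
        """True iff bits are monotone non-increasing (ones then zeros)."""
        seen_zero = False
        for b in self.bits:
            if b == 0:
                seen_zero = True
            elif seen_zero:
                return False
        return True

    def ones(self) -> int:
        return sum(self.bits)

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)


def encode(x: int, w: int) -> UnaryNumber:
    """Encode integer ``x`` at width ``w`` (``x + 1`` leading ones)."""
    if x < 0:
        raise RepresentationError(f"cannot encode negative value {x}")
    if x > w - 1:
        raise CapacityError(f"value {x} does not fit in width {w} (max {w - 1})")
    return UnaryNumber(w, tuple(1 if i <= x else 0 for i in range(w)))


def underflow(w: int) -> UnaryNumber:
    """The reserved all-zero pattern at width ``w``."""
    return UnaryNumber(w, (0,) * w)


def decode(u: UnaryNumber):
    """Inverse of :func:`encode`; the all-zero pattern yields :data:`UNDERFLOW`."""
    if not u.is_prefix:
        raise RepresentationError(f"non-prefix 1UN pattern: {u}")
    n = u.ones()
    return UNDERFLOW if n == 0 else n - 1


def left_shift_one(u: UnaryNumber) -> UnaryNumber:
    """Drop ``b_0`` and append a zero on the right.

    Strips the bit that represents zero, so the shifted pattern of
    ``encode(x)`` has exactly ``x`` ones — the form fed into the adder's
    West border.
    """
    return UnaryNumber(u.width, u.bits[1:] + (0,))
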