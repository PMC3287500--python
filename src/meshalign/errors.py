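"""Exception types shared across the package."""


class MeshAlignError(Exception):
    """Base class for all package errors."""


class CapacityError(MeshAlignError):
    """A value does not fit in the configured unary width."""


class RepresentationError(MeshAlignError):
    """A bit pattern violates the 1UN prefix invariant."""


class InputError(MeshAlignError):
    """Malformed user input (sequences, matrices, configuration)."""


class ContractViolation(MeshAlignError):
    """Internal consistency check failed (e.g. inconsistent DP matrix)."""
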