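"""Exception types shared across the package."""


class ConchToughError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(ConchToughError):
    """A lattice/specimen specification violates its invariants."""


class GeometryError(ConchToughError):
    """A crack or pattern does not fit inside the allowed domain."""


class SolverError(ConchToughError):
    """A linear solve failed or the system is under-constrained."""
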