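"""Exception hierarchy for fiberwalk."""


class FiberWalkError(Exception):
    """Base class for all fiberwalk errors."""


class InvalidConfigurationError(FiberWalkError, ValueError):
    """A simulation configuration is invalid (e.g. dimension < 2)."""


class InvalidEdgeError(FiberWalkError, ValueError):
    """Two positions do not form a lattice edge."""


class InvalidLabelError(FiberWalkError, ValueError):
    """An edge-label entry lies outside {-1, 0, 1}."""


class UnknownVertexError(FiberWalkError, KeyError):
    """A vertex id is not present in the lattice."""


class IllegalStateError(FiberWalkError, RuntimeError):
    """An operation was called on a state that does not admit it."""


class ContractForbiddenError(FiberWalkError, ValueError):
    """A merge was requested across a self-avoiding edge (rule 2)."""


class UnresolvableWalkError(FiberWalkError, RuntimeError):
    """Backtracking exhausted every alternative back to the origin."""


class UnsupportedDimensionError(FiberWalkError, ValueError):
    """The operation is defined in 2D only."""


class DegenerateInputError(FiberWalkError, ValueError):
    """The input is too small to be meaningful (e.g. a zero-length fiber)."""


class InsufficientDataError(FiberWalkError, ValueError):
    """Too few data points for the requested estimate."""


class InvalidModeError(FiberWalkError, ValueError):
    """The walk mode does not admit the requested statistic."""


class InvalidInputError(FiberWalkError, ValueError):
    """Generic invalid input (empty samples, open polylines, ...)."""
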