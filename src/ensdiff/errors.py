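"""Exception hierarchy for ensemble loading and comparison."""


class EnsdiffError(Exception):
    """Base class for all package errors."""


class TopologyError(EnsdiffError):
    """Atom records are inconsistent across files, frames or tables."""


class EmptyInputError(EnsdiffError):
    """An operation received no frames, no atoms or no values."""


class ConfigError(EnsdiffError):
    """Configuration is missing or contradicts the loaded structures."""


class EmptyRegionError(EnsdiffError):
    """A region selects no atoms; usually a config/topology mismatch."""


class UnitError(EnsdiffError):
    """Two series with different units or descriptors were compared."""


class InsufficientDataError(EnsdiffError):
    """Too few frames or values for the requested estimate."""


class InsufficientReplicasError(InsufficientDataError):
    """Replica-level resampling needs at least two replicas per condition."""


class DegenerateRangeError(EnsdiffError):
    """All values identical: the trimmed range r is zero."""


class FitError(EnsdiffError):
    """Least-squares superposition failed (degenerate fit region)."""


class AnnotationError(EnsdiffError):
    """Selections lack donor/acceptor/polar-hydrogen annotations."""
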