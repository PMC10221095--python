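"""Exception hierarchy shared across the package."""


class RampClampError(Exception):
    """Base class for all package errors."""


class ParseError(RampClampError):
    """A file record could not be parsed; message names the line number."""


class EmptyInputError(RampClampError):
    """An input contained no usable records."""


class SelectionError(RampClampError):
    """A selection expression referenced unknown tokens or failed to parse."""


class ShapeError(RampClampError):
    """Array / atom-table shapes are inconsistent."""


class DegenerateGeometryError(RampClampError):
    """Too few or collinear/coincident points for a geometric operation."""


class InsufficientFramesError(RampClampError):
    """An operation needs more trajectory frames than were supplied."""


class PartitionError(RampClampError):
    """Chain sets that must be disjoint share atoms."""


class ModeError(RampClampError):
    """An analysis mode was requested that the inputs cannot support."""


class ParameterizationError(RampClampError):
    """An atom lacks force-field-style parameters."""


class NumericalValidityError(RampClampError):
    """A computed intermediate (e.g. a Born radius) is out of range."""


class ConfigurationError(RampClampError):
    """An engine or pipeline configuration is self-contradictory."""


class StabilityError(RampClampError):
    """Integrator settings are outside the stable regime."""


class GenerationError(RampClampError):
    """A synthetic-data generator could not satisfy its constraints."""


class InsufficientReplicatesError(RampClampError):
    """A statistical comparison needs more replicates."""
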