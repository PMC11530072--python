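"""Exception hierarchy for magbench."""


class MagbenchError(Exception):
    """Base class for all magbench-specific errors."""


class SchemaError(MagbenchError):
    """A tabular input is missing required columns or has malformed values."""


class RosterValidationError(MagbenchError):
    """A species group violates one of the community-composition invariants."""


class RosterStructureError(MagbenchError):
    """Taxonomic triplets cannot be constructed from the roster as given."""


class InfeasibleParameterError(MagbenchError):
    """A requested abundance floor or decay shape has no valid parameterization."""


class MissingGenomeError(MagbenchError):
    """A community species has no usable genome sequence."""


class InsufficientReplicationError(MagbenchError):
    """A factor level has too few observations for a statistical comparison."""
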