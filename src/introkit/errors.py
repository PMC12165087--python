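"""Exception hierarchy shared by all introkit modules."""


class IntrokitError(Exception):
    """Base class for all introkit errors."""


class ConfigurationError(IntrokitError):
    """A configuration object violates one of its invariants."""


class ArgumentError(IntrokitError, ValueError):
    """An operation received an argument outside its contract."""


class FormatError(IntrokitError):
    """An input file violates the expected on-disk format."""


class ContractError(IntrokitError):
    """A data-model invariant was violated at an operation boundary."""


class InsufficientDataError(IntrokitError):
    """Not enough data points to compute the requested statistic."""


class AlignmentError(IntrokitError):
    """Two window sets that must share a grid do not align."""


class MappingError(IntrokitError):
    """A sample is missing from the population map."""
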