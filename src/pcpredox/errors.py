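"""Exception hierarchy shared across the package."""


class PcpRedoxError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PcpRedoxError, ValueError):
    """A model parameter violates its domain (e.g. a, b, k must be > 0)."""


class InsufficientDataError(PcpRedoxError, ValueError):
    """Too few data points for the requested estimation."""


class DegenerateInputError(PcpRedoxError, ValueError):
    """Input carries no usable signal (e.g. a constant series)."""


class DataConsistencyError(PcpRedoxError, ValueError):
    """Observed data contradict a physical constraint beyond tolerance."""


class MassBalanceError(PcpRedoxError, ValueError):
    """Mole or mass conservation violated beyond tolerance."""


class InvalidPositionError(PcpRedoxError, ValueError):
    """Ring position outside {2, 3, 4, 5, 6}."""


class NotADechlorinationStepError(PcpRedoxError, ValueError):
    """Congener pair is not a single chlorine-removal step."""


class UnidentifiableError(PcpRedoxError, ValueError):
    """Observations contain no information about the requested parameters."""


class SchemaError(PcpRedoxError, ValueError):
    """Tabular input does not match the expected column schema."""
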