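"""Exception hierarchy shared across the codec."""


class RCError(Exception):
    """Base class for all codec errors."""


class AlphabetError(RCError, ValueError):
    """Sequence contains characters outside A/C/G/T."""


class LayoutError(RCError, ValueError):
    """Field lengths or strand structure violate the layout."""


class ConfigError(RCError, ValueError):
    """Invalid configuration (shapes, rates, thresholds)."""


class DomainError(RCError, ValueError):
    """Numeric argument outside the model's domain."""


class CapacityError(RCError, ValueError):
    """A counter does not fit its nucleotide field."""


class SearchExhaustedError(RCError, RuntimeError):
    """A seeded search (matrix selection or equilibrium) ran out of space."""


class UndecodableError(RCError, RuntimeError):
    """The surviving strands do not determine the original chunks."""

    def __init__(self, message: str, missing_pivots=None):
        super().__init__(message)
        self.missing_pivots = list(missing_pivots or [])
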