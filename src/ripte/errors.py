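"""Exception types shared across the pipeline stages."""


class RipteError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RipteError, ValueError):
    """A simulation or analysis parameter is outside its valid domain."""


class MissingDataError(RipteError, KeyError):
    """A required measurement (probe value, replicate pair member) is absent."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class MissingReferenceError(MissingDataError):
    """A designated reference gene is absent from a sample."""


class InvalidAnchorError(MissingDataError):
    """The anchor gene for input-abundance rescaling is absent."""


class InsufficientDataError(RipteError, ValueError):
    """Too few observations to compute the requested statistic."""


class DomainError(RipteError, ValueError):
    """A numeric argument violates a mathematical precondition (e.g. ratio <= 0)."""


class InvalidReferenceError(RipteError, ValueError):
    """A tRNA reference does not carry A at its annotated wobble position."""


class InsufficientCoverageError(RipteError, ValueError):
    """An editing comparison was requested on a site that failed coverage."""


class DegenerateTableError(RipteError, ValueError):
    """A contingency table has an all-zero margin."""
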