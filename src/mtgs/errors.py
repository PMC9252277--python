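"""Exception hierarchy for the mtgs package."""


class MtgsError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(MtgsError):
    """Locus (or trait) sets of two objects do not align."""


class DegenerateTraitError(MtgsError):
    """A trait has zero observed range, so normalization bounds are undefined."""


class NormalizationError(MtgsError):
    """A value falls outside the reference bounds used for normalization."""


class CapacityError(MtgsError):
    """The instance exceeds the configured exact-solver capacity."""


class FormatError(MtgsError):
    """A file does not conform to the documented dialect."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
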