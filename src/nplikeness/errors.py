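"""Exception hierarchy for the nplikeness package."""


class NPLikenessError(Exception):
    """Base class for all package errors."""


class InputError(NPLikenessError):
    """A required input is missing or unreadable."""


class EmptyInputError(InputError):
    """An input file yielded no parsable records."""


class OutputError(NPLikenessError):
    """An output location cannot be written."""


class UnsupportedFormatError(InputError):
    """The file uses a dialect this package deliberately does not read (e.g. SDF V3000)."""


class SignatureParseError(NPLikenessError):
    """A signature string violates the documented grammar.

    Carries ``position``, the 0-based character offset at which parsing failed.
    """

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class TrainingError(NPLikenessError):
    """A frequency index cannot be built (e.g. empty corpus)."""


class UndefinedScoreError(NPLikenessError):
    """A fragment score is undefined: pseudo-count 0 with a zero count in the log-ratio."""


class ModelFormatError(NPLikenessError):
    """A persisted scorer model file has the wrong version or is malformed."""
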