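"""Exception hierarchy.

Every error raised by the library derives from :class:`TextKgError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class TextKgError(Exception):
    """Base class for all errors raised by textkg."""


class InvalidInputError(TextKgError):
    """An operation received input that violates its precondition."""


class CapabilityError(TextKgError):
    """An annotation provider cannot serve a requested analysis kind."""

    def __init__(self, kind: str, message: str | None = None):
        self.kind = kind
        super().__init__(message or f"provider cannot serve analysis kind {kind!r}")


class MissingAnnotationError(TextKgError):
    """A replay provider has no stored annotation for a sentence."""

    def __init__(self, sentence: str):
        self.sentence = sentence
        super().__init__(f"no stored annotation for sentence: {sentence!r}")


class FixtureSchemaError(TextKgError):
    """A replay fixture violates the fixture schema; names the first offender."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"fixture entry {key!r}: {message}")


class AmbiguousAbbreviationError(TextKgError):
    """Two abbreviation pairs share a short form with different long forms."""


class ParseMismatchError(TextKgError):
    """A constituency parse does not cover the sentence it was given."""


class InvalidCombinationError(TextKgError):
    """Two link sets targeting different ontologies cannot be combined."""


class InvalidPhraseError(TextKgError):
    """A phrase normalizes to nothing and cannot be minted into a URI."""


class IntermediateFormatError(TextKgError):
    """A human-edited intermediate file could not be parsed."""

    def __init__(self, path, line_no: int, message: str):
        self.path = path
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")
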