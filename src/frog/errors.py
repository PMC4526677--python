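"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`FrogError`
so callers (and the CLI) can distinguish data/validation problems from bugs.
"""


class FrogError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(FrogError):
    """A schema definition could not be parsed or violates its invariants."""


class UnknownLevelError(SchemaError):
    """A level name does not exist in the schema."""

    def __init__(self, name: str, suggestions: list[str] | None = None):
        self.name = name
        self.suggestions = suggestions or []
        hint = f" (did you mean: {', '.join(self.suggestions)}?)" if self.suggestions else ""
        super().__init__(f"unknown level {name!r}{hint}")


class UnknownAttributeError(SchemaError):
    """An attribute name does not exist within its level."""

    def __init__(self, level: str, name: str, suggestions: list[str] | None = None):
        self.level = level
        self.name = name
        self.suggestions = suggestions or []
        hint = f" (did you mean: {', '.join(self.suggestions)}?)" if self.suggestions else ""
        super().__init__(f"unknown attribute {name!r} in level {level!r}{hint}")


class FingerprintError(FrogError):
    """A fingerprint string is malformed or used with the wrong level."""


class MergeConflictError(FingerprintError):
    """Two fingerprints disagree on a determined symbol."""

    def __init__(self, position: int, a: str, b: str):
        self.position = position
        super().__init__(f"merge conflict at position {position}: {a!r} vs {b!r}")


class HgvsParseError(FrogError):
    """A variant description string could not be parsed."""


class AnnotationError(FrogError):
    """A variant annotation references properties absent from the schema."""


class FormatError(FrogError):
    """A TSV/VCF source is malformed; carries a location where possible."""

    def __init__(self, message: str, line: int | None = None, column: str | None = None):
        self.line = line
        self.column = column
        loc = []
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column {column!r}")
        prefix = f"[{', '.join(loc)}] " if loc else ""
        super().__init__(prefix + message)
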