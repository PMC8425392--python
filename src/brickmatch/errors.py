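"""Exception hierarchy.

Two top-level families matter for the CLI exit-code contract: usage errors
(exit 1) and data errors (exit 2). Everything raised by the library derives
from :class:`BrickmatchError`.
"""


class BrickmatchError(Exception):
    """Base class for all errors raised by this package (data errors)."""


class UsageError(BrickmatchError):
    """The caller asked for something unsupported (e.g. matching an AF map)."""


class SbgnParseError(BrickmatchError):
    """Malformed SBGN-ML input; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class UnsupportedClassError(BrickmatchError):
    """A glyph or arc class outside the supported PD vocabulary."""

    def __init__(self, cls: str, kind: str = "glyph"):
        self.cls = cls
        super().__init__(f"unsupported {kind} class: {cls!r}")


class LanguageMismatchError(BrickmatchError):
    """AF/ER-specific content in a document declared as PD (or vice versa)."""


class IntegrityError(BrickmatchError):
    """A reference inside a map or library does not resolve, or an invariant fails."""


class RoleError(BrickmatchError):
    """A glyph id was used in a role its class does not support."""


class PatternSyntaxError(BrickmatchError):
    """Unbalanced or misplaced delimiter in a label pattern."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)


class MissingBindingError(BrickmatchError):
    """A variable required for rendering/instantiation has no binding."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(f"no binding for variable {name!r}")


class LibraryLoadError(BrickmatchError):
    """Brick-library JSON failed structural or consistency validation.

    ``pointer`` is a JSON-pointer-like path to the offending element.
    """

    def __init__(self, message: str, pointer: str = ""):
        self.pointer = pointer
        if pointer:
            message = f"{pointer}: {message}"
        super().__init__(message)
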