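"""Exception hierarchy.

All library errors derive from :class:`TfslError`, so callers can catch one
type at an application boundary.  Decoding/encoding failures carry enough
context (datatype path, character offset or line number) to locate the
offending piece of text or data.
"""

from __future__ import annotations


class TfslError(Exception):
    """Base class for all errors raised by this package."""


class SpecSyntaxError(TfslError):
    """A specification document violates the specification-language syntax.

    Carries the diagnostics produced while validating the definition tree.
    """

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        if self.diagnostics:
            details = "\n".join("  - " + str(d) for d in self.diagnostics)
            return f"{base}\n{details}"
        return base


class DocumentSyntaxError(TfslError):
    """The YAML/JSON document itself could not be parsed."""


class IncludeError(TfslError):
    """A problem while resolving the include section (missing file, bad override)."""


class IncludeCycleError(IncludeError):
    """A file includes itself, directly or through other files."""

    def __init__(self, stack: list[str]):
        self.stack = list(stack)
        super().__init__("include cycle: " + " -> ".join(self.stack))


class UnresolvedReferenceError(TfslError):
    """A datatype definition references a name that is not defined anywhere."""

    def __init__(self, name: str, referrer: str):
        self.name = name
        self.referrer = referrer
        super().__init__(f"datatype {referrer!r} references undefined datatype {name!r}")


class CircularReferenceError(TfslError):
    """The datatype dependency graph contains a cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__("circular reference: " + " -> ".join(self.cycle))


class PatternError(TfslError):
    """A user-supplied regular expression is invalid, or a compiled pattern
    exceeds the configured complexity cap."""


class DecodingError(TfslError):
    """A text does not follow the datatype definition.

    ``path`` locates the failing sub-definition, ``offset`` the first
    character at which no continuation of the match is possible (best
    effort), and ``lineno`` is set for file decoding (1-based).
    """

    def __init__(self, message: str, *, path: str = "", offset: int | None = None,
                 lineno: int | None = None):
        self.path = path
        self.offset = offset
        self.lineno = lineno
        where = []
        if path:
            where.append(f"at {path}")
        if lineno is not None:
            where.append(f"line {lineno}")
        if offset is not None:
            where.append(f"offset {offset}")
        suffix = f" ({', '.join(where)})" if where else ""
        super().__init__(message + suffix)


class EncodingError(TfslError):
    """A data value cannot be represented under the datatype definition."""

    def __init__(self, message: str, *, path: str = ""):
        self.path = path
        suffix = f" (at {path})" if path else ""
        super().__init__(message + suffix)


class ArchiveError(TfslError):
    """Problems with precompiled specification archives."""


class CorruptArchiveError(ArchiveError):
    pass


class VersionMismatchError(ArchiveError):
    pass


class UnsatisfiableExampleError(TfslError):
    """Example generation cannot satisfy the request (e.g. no invalid text
    exists for a definition accepting every string)."""
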