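"""Exception hierarchy with stable machine-readable codes.

Every error raised by this package carries a ``code`` attribute drawn from a
closed set of tokens, so callers (and the CLI) can dispatch on the code rather
than the exception class or message text.
"""

from __future__ import annotations


class MixsSaError(Exception):
    """Base class for all package errors."""

    code: str = "ERROR"

    def __init__(self, message: str, **context: object) -> None:
        super().__init__(message)
        self.context = context

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        return f"[{self.code}] {base}"


# ---------------------------------------------------------------- registry

class RegistryDuplicateIdError(MixsSaError):
    code = "REGISTRY_DUPLICATE_ID"


class RegistryDanglingTermError(MixsSaError):
    code = "REGISTRY_DANGLING_TERM"


class TermNotFoundError(MixsSaError):
    code = "TERM_NOT_FOUND"

    def __init__(self, message: str, suggestions: list[str] | None = None, **ctx: object):
        super().__init__(message, **ctx)
        #: nearest registered names by edit distance; advisory only.
        self.suggestions = suggestions or []


class IdSyntaxError(MixsSaError):
    code = "ID_SYNTAX"


class PackageNotFoundError(MixsSaError):
    code = "PACKAGE_NOT_FOUND"


# ----------------------------------------------------------------- records

class TableFormatError(MixsSaError):
    code = "TABLE_FORMAT"


class DuplicateSampleError(MixsSaError):
    code = "DUPLICATE_SAMPLE"


class DuplicateAttributeError(MixsSaError):
    code = "DUPLICATE_ATTRIBUTE"


class ValueSyntaxError(MixsSaError):
    code = "VALUE_SYNTAX"

    def __init__(self, message: str, term: str | None = None, raw: str | None = None):
        super().__init__(message, term=term, raw=raw)
        self.term = term
        self.raw = raw


# ---------------------------------------------------------------- relgraph

class RelationshipSyntaxError(MixsSaError):
    """Raised for malformed relationship entries; ``code`` set per instance."""

    def __init__(self, code: str, message: str, **ctx: object):
        super().__init__(message, **ctx)
        self.code = code


class SampleNotFoundError(MixsSaError):
    code = "SAMPLE_NOT_FOUND"


class FormatNotSupportedError(MixsSaError):
    code = "FORMAT_NOT_SUPPORTED"


# ---------------------------------------------------------------- fixtures

class ParamsInvalidError(MixsSaError):
    code = "PARAMS_INVALID"


class InjectionImpossibleError(MixsSaError):
    code = "INJECTION_IMPOSSIBLE"
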