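"""Structured exceptions raised across the package.

Every reader and operation either returns a fully validated object or
raises one of these; no function hands back a partially parsed table.
"""


class GenefamError(Exception):
    """Base class for all package errors."""


class SchemaError(GenefamError):
    """Input file does not match the expected column/record schema."""


class DuplicateIdError(GenefamError):
    """The same identifier occurs more than once where ids must be unique."""


class SequenceError(GenefamError):
    """A sequence violates its alphabet or coding constraints."""


class ValidationError(GenefamError):
    """A value violates a documented invariant (coordinates, Cq, thresholds)."""


class ReferenceError_(GenefamError):
    """An id referenced in one table does not resolve in another."""
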