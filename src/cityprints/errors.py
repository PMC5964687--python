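"""Exception hierarchy for cityprints."""


class CityprintsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CityprintsError):
    """A file does not conform to the expected dialect (e.g. missing taxonomy column)."""


class ValidationError(CityprintsError):
    """Data violates an invariant (negative counts, duplicate ids, ...)."""


class PreconditionError(CityprintsError):
    """An operation was called on inputs that do not satisfy its contract."""
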