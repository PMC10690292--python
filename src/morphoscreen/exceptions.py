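"""Exception hierarchy shared across the package."""


class MorphoscreenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MorphoscreenError, ValueError):
    """A table does not conform to the expected column layout."""


class ValidationError(MorphoscreenError, ValueError):
    """An input value or configuration violates a documented constraint."""


class EmptyResultError(MorphoscreenError, ValueError):
    """An operation produced an empty result where data is required."""
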