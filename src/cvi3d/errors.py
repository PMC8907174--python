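"""Exception hierarchy for the CVI pipeline."""


class CviError(Exception):
    """Base class for all pipeline errors."""


class VolumeLoadError(CviError):
    """An image stack could not be loaded (missing, ragged, or unreadable files)."""


class SchemaError(CviError):
    """A metadata record or table is missing required fields or has the wrong shape."""


class ValidationError(CviError):
    """Data violates a domain invariant (e.g. upper boundary below lower boundary)."""


class UndefinedValueError(CviError):
    """A requested quantity is mathematically undefined for the given input."""
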