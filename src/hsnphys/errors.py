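"""Exception hierarchy shared across the package."""


class HsnPhysError(Exception):
    """Base class for all package errors."""


class ParameterError(HsnPhysError, ValueError):
    """A model parameter violates its documented constraints."""


class InputError(HsnPhysError, ValueError):
    """Input data violate a precondition (length, size, domain)."""


class SchemaError(HsnPhysError, ValueError):
    """A CSV file is missing required columns or has a malformed header."""


class PipelineError(HsnPhysError, RuntimeError):
    """A pipeline stage produced an unusable intermediate (e.g. nonpositive baseline)."""
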