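"""Exception hierarchy.

All package errors derive from :class:`DissocsigError` so callers can catch
one type; format/validation/config subclasses also derive from ``ValueError``
for idiomatic use.
"""


class DissocsigError(Exception):
    """Base class for all errors raised by dissocsig."""


class FormatError(DissocsigError, ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(DissocsigError, ValueError):
    """Input data violate a documented invariant or precondition."""


class ConfigError(DissocsigError, ValueError):
    """A configuration document is malformed or inconsistent."""


class PipelineError(DissocsigError, RuntimeError):
    """A pipeline stage failed at run time."""
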