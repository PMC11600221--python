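"""Exception hierarchy.

All package errors derive from :class:`GafSenseError` so callers can catch
one base class. Argument-validation errors also derive from ``ValueError``
to behave well in generic code.
"""


class GafSenseError(Exception):
    """Base class for all gafsense errors."""


class InvalidArgumentError(GafSenseError, ValueError):
    """A function argument violates a documented precondition."""


class SchemaError(GafSenseError):
    """A file parsed, but its columns/shape do not match the expected dialect."""


class ParseError(SchemaError):
    """A recording or manifest file could not be parsed; names row/column."""


class ProtocolError(GafSenseError):
    """A validation protocol cannot run on the given dataset layout."""


class CapabilityError(GafSenseError):
    """An optional capability (e.g. an external vision backbone) is absent."""
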