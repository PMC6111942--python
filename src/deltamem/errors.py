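"""Exception hierarchy.

Split so the CLI can map failure kinds onto distinct exit codes:
usage problems, data/validation problems, everything else.
"""


class DeltamemError(Exception):
    """Base class for all package errors."""


class ParseError(DeltamemError):
    """A file could not be parsed in the named dialect."""


class SchemaError(DeltamemError):
    """Dataset structure contradicts the declared or required schema."""


class ValidationError(DeltamemError):
    """A value violates its attribute schema (names row and attribute)."""


class DimensionMismatchError(DeltamemError):
    """Pattern dimensionality does not match the memory or transform."""


class FingerprintMismatchError(DeltamemError):
    """An operation required the exact fundamental set a model was built from."""
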