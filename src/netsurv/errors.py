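"""Exception hierarchy for netsurv.

All package errors derive from :class:`NetsurvError` so callers can catch one
base class; the subclasses mirror the distinct failure contracts (file format,
value validation, cohort assembly, configuration).
"""


class NetsurvError(Exception):
    """Base class for all netsurv errors."""


class FormatError(NetsurvError):
    """A file could not be parsed (malformed cell, bad header, ...)."""


class ValidationError(NetsurvError):
    """Parsed data violates a domain invariant (negative TPM, duplicate ID, ...)."""


class CohortAssemblyError(NetsurvError):
    """Expression matrix and clinical table cannot be joined."""


class ConfigurationError(NetsurvError):
    """A configuration value is out of its admissible range."""


class EmptyResultError(NetsurvError):
    """An operation removed every row/gene, leaving nothing to work with."""
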