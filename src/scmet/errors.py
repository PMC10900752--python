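"""Exception hierarchy.

All package errors derive from :class:`ScmetError` so callers can catch one
base class; subclasses mark the failure mode (bad file, inconsistent
dimensions, bad parameter, corrupted checkpoint, exhausted candidate pool).
"""


class ScmetError(Exception):
    """Base class for all scmet errors."""


class FormatError(ScmetError):
    """A file is missing or not in the expected on-disk format."""


class ConsistencyError(ScmetError):
    """Dimensions or identifiers disagree between related inputs."""


class ParseError(ScmetError):
    """A table cell could not be interpreted; message carries coordinates."""


class ParameterError(ScmetError, ValueError):
    """A numeric argument is outside its valid range."""


class IntegrityError(ScmetError):
    """A checkpoint blob and its metadata sidecar do not match."""


class VocabularyError(ScmetError, KeyError):
    """A cell-type label is not part of the model's label vocabulary."""


class CapacityError(ScmetError):
    """The candidate pool cannot satisfy a requested per-type allocation."""


class DivergenceError(ScmetError):
    """Training produced a non-finite loss; message names the last stable epoch."""
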