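"""Package exception hierarchy."""

from __future__ import annotations


class SmhatError(Exception):
    """Base class for all package errors."""


class SchemaError(SmhatError):
    """A file does not conform to the documented schema."""


class VocabularyError(SchemaError):
    """A tag or category falls outside the controlled vocabulary."""


class CodebookValidationError(SmhatError):
    """A codebook violates one of its invariants."""


class ConfigurationError(SmhatError):
    """A codebook item is inconsistent with the tag vocabulary."""


class EmptyProvisionError(SmhatError):
    """A menu cycle with neither weeks nor a price list cannot be scored."""


class ReliabilityError(SmhatError):
    """Invalid input to a reliability statistic (e.g. a single coder)."""


class DegenerateMarginalsError(ReliabilityError):
    """Cohen's kappa is undefined: expected agreement is 1 but observed is not."""
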