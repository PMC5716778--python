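"""Exception hierarchy for cdscore.

All package errors derive from :class:`CdScoreError` so callers can catch
one base class; subclasses distinguish parse/validation problems from
statistical-design problems.
"""


class CdScoreError(Exception):
    """Base class for all cdscore errors."""


class ParseError(CdScoreError):
    """A file could not be parsed (malformed header, bad dimensions...)."""


class ValidationError(CdScoreError):
    """Parsed data violates a domain invariant (negative intensity, event
    indicator outside {0,1}...)."""


class SchemaError(CdScoreError):
    """A required column or field is missing."""


class AlignmentError(CdScoreError):
    """Expression and clinical tables share no sample IDs."""


class DesignError(CdScoreError):
    """A statistical design precondition is violated (class with <2
    samples, empty group, constant covariate...)."""


class DegenerateInputError(CdScoreError):
    """Input admits no analysis (constant expression vector, no candidate
    cutpoint inside the search band...)."""


class ConfigurationError(CdScoreError):
    """Invalid generator or pipeline configuration."""


class ModelApplicationError(CdScoreError):
    """A frozen score model cannot be applied to a cohort (missing
    probeset, unset merge map...)."""


class BuildError(CdScoreError):
    """A score model cannot be built (empty replicated gene set...)."""
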