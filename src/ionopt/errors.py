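"""Exception hierarchy for ionopt.

All package-specific failures derive from :class:`IonoptError` so callers
can catch one base class at pipeline boundaries.
"""


class IonoptError(Exception):
    """Base class for all ionopt errors."""


class InvalidValueError(IonoptError, ValueError):
    """A numeric argument is non-finite or outside its admissible range."""


class DesignInfeasibleError(IonoptError):
    """The requested design (resolution, run count, ...) cannot be built."""


class SchemaError(IonoptError):
    """An input table or config references unknown factors/columns."""


class AliasedTermsError(IonoptError):
    """Model matrix is rank deficient because requested terms are confounded.

    Parameters
    ----------
    terms : iterable of str
        Names of the mutually confounded terms.
    """

    def __init__(self, terms, message=None):
        self.terms = sorted(set(terms))
        super().__init__(message or f"aliased terms: {', '.join(self.terms)}")


class NotComputableError(IonoptError):
    """A diagnostic has no defined value on this data (e.g. zero pure-error df)."""


class ConfigurationError(IonoptError):
    """Inconsistent configuration (missing models, analyte mismatch, ...)."""


class DegenerateScanError(IonoptError):
    """A one-factor-at-a-time scan contains no usable signal."""


class InsufficientDataError(IonoptError):
    """Too few calibration levels / runs for the requested fit."""
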