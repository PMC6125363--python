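"""Exception hierarchy.

Every error raised on bad user input derives from :class:`PrognosigError`
(itself a ``ValueError``) so callers can catch one type at pipeline
boundaries while tests can assert the specific condition.
"""


class PrognosigError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(PrognosigError):
    """A simulation or run configuration violates its invariants."""


class ParameterError(PrognosigError):
    """An operation parameter is out of its admissible range."""


class ImputationError(PrognosigError):
    """A sample column has too few observed values to estimate moments."""


class PairingError(PrognosigError):
    """Paired test requested but patients do not match across regions."""


class ZScoreError(PrognosigError):
    """A constant row cannot be z-scored."""


class OverlapError(PrognosigError):
    """Too few shared observations for a pairwise correlation."""


class DegenerateCovariateError(PrognosigError):
    """A constant covariate admits no regression slope."""


class UndefinedRatioError(PrognosigError):
    """Heavy-transition sum is zero; the light/heavy ratio is undefined."""


class QCUndefinedError(PrognosigError):
    """A QC statistic (rdotp) is undefined for an all-zero vector."""


class UnevaluableError(PrognosigError):
    """Both regions of an IHC case are missing; no call can be made."""


class UndefinedKappaError(PrognosigError):
    """All ratings fall in one category; chance agreement is 1."""


class DegenerateTableError(PrognosigError):
    """A contingency table has a zero marginal."""


class StratificationError(PrognosigError):
    """A class is too small to stratify."""


class SmoteError(PrognosigError):
    """Minority class too small for synthetic oversampling."""


class UndefinedAUCError(PrognosigError):
    """ROC AUC is undefined when only one class is present."""


class SchemaError(PrognosigError):
    """An input table is missing required columns or features."""
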