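"""Exception hierarchy for ssbn.

Infinite ratios (e.g. a Bayes factor with a zero denominator but non-zero
numerator) are *not* exceptions: they are reported as ``math.inf`` so that
callers ranking explanations can still order them.
"""


class SSBNError(Exception):
    """Base class for all ssbn errors."""


class DomainError(SSBNError):
    """An unknown variable name or state label was supplied."""


class IncompleteAssignmentError(SSBNError):
    """An operation requiring a full assignment received a partial one."""


class ImpossibleEvidenceError(SSBNError):
    """The supplied evidence has probability zero under the network."""


class IllDefinedComplementError(SSBNError):
    """GBF complement is undefined because P(x) is 0 or 1."""


class UndefinedMeasureError(SSBNError):
    """A normalising quantity (e.g. target entropy) is zero."""


class TooLargeError(SSBNError):
    """An exact enumeration would exceed the configured state-space cap."""


class EstimationError(SSBNError):
    """Parameter estimation is impossible (no effective data, no smoothing)."""


class ConfigurationError(SSBNError):
    """Invalid learner/search configuration or missing required columns."""


class ValidationError(SSBNError):
    """Input data failed validation against its declared metadata."""


class StratificationError(SSBNError):
    """A target class is too small for the requested number of folds."""


class SpecificationError(SSBNError):
    """A synthetic-cohort specification is internally infeasible."""
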