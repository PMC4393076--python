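"""Exception hierarchy.

Every error carries a short machine-greppable ``code`` so that CLI failures
can be matched by scripts without parsing free-form prose.
"""


class CorrankError(Exception):
    """Base class for all package errors."""

    code = "E_CORRANK"


class ValidationError(CorrankError):
    """Inputs violate a documented precondition or invariant."""

    code = "E_VALIDATION"


class InputFormatError(CorrankError):
    """A file could not be parsed (ragged rows, non-numeric cells, ...)."""

    code = "E_INPUT_FORMAT"


class DuplicateGeneError(CorrankError):
    """The same gene identifier occurs more than once."""

    code = "E_DUPLICATE_GENE"


class UnlabeledSampleError(CorrankError):
    """A sample column has no group assignment."""

    code = "E_UNLABELED_SAMPLE"


class ZeroEnergyGeneError(CorrankError):
    """A gene row has zero sum of squares after centering."""

    code = "E_ZERO_ENERGY_GENE"


class FactorizationError(CorrankError):
    """Cholesky factorization failed even after diagonal regularization."""

    code = "E_CHOLESKY"


class NonFiniteResultError(CorrankError):
    """A computation produced NaN or infinite values."""

    code = "E_NONFINITE"


class ConfigError(CorrankError):
    """A configuration file is malformed or holds unknown keys."""

    code = "E_CONFIG"
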