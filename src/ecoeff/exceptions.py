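"""Exception hierarchy shared across the pipeline stages."""


class EcoeffError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EcoeffError, ValueError):
    """A configuration object or file violates its invariants."""


class ValidationError(EcoeffError, ValueError):
    """Input data violate a documented precondition."""


class CoefficientLookupError(EcoeffError, KeyError):
    """A crop or emission source has no coefficient entry."""


class SingularityError(EcoeffError, ValueError):
    """A regression design matrix is rank deficient.

    Carries the names of the offending columns when they can be identified.
    """

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class EstimationError(EcoeffError, RuntimeError):
    """An iterative estimator failed to converge or is unidentified."""


class IntegrityError(EcoeffError, RuntimeError):
    """A pipeline intermediate no longer matches its recorded hash."""
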