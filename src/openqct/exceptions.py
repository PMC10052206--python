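"""Exception hierarchy shared across the package."""


class OpenQCTError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(OpenQCTError, ValueError):
    """A scalar input violates a physical precondition (e.g. Z0 <= 0)."""


class DegeneratePressureError(InvalidInputError):
    """SBP <= DBP: pulse pressure is zero or negative."""


class ConfigurationError(OpenQCTError, ValueError):
    """A configuration value is out of range or refers to an unknown name."""


class InsufficientSamplesError(OpenQCTError, ValueError):
    """Fewer samples than the smallest mesh (M < 4) or window requires."""


class DegenerateVariableError(OpenQCTError):
    """A variable is constant over the window; its rank image is undefined.

    Callers treat the variable as zero-entropy and unstructured.
    """


class InvalidMatrixError(OpenQCTError, ValueError):
    """A matrix handed to the complexity operator is non-symmetric or has NaNs."""


class InsufficientDataError(OpenQCTError, ValueError):
    """The record is shorter than one analysis window."""


class InsufficientBaselineError(OpenQCTError, ValueError):
    """The requested baseline span covers too few trend points or beats."""
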