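"""Exception hierarchy.

Every error raised by this package derives from :class:`NirsconnError`, so
callers (and the CLI) can map failures onto coarse categories: validation
problems, data problems, and numerical problems.
"""


class NirsconnError(Exception):
    """Base class for all package errors."""


class ValidationError(NirsconnError, ValueError):
    """A parameter or configuration value violates its contract."""


class FormatError(NirsconnError, ValueError):
    """An on-disk file does not conform to the expected format."""


class UnsupportedDataError(FormatError):
    """The file is well formed but holds a data type we do not handle
    (e.g. non-continuous-wave SNIRF measurements)."""


class PairingError(NirsconnError, ValueError):
    """A source-detector pair lacks its two-wavelength partner."""


class DataError(NirsconnError, ValueError):
    """Input data are structurally valid but unusable for the requested
    computation (too short, missing a condition, negative intensity...)."""


class SingularDesignError(NirsconnError, ValueError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message: str, collinear_columns=()):
        super().__init__(message)
        self.collinear_columns = tuple(collinear_columns)


class NumericalError(NirsconnError, ArithmeticError):
    """A numerical operation failed (singular extinction matrix, unstable
    simulation, ...)."""
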