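"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes: configuration problems -> 2,
data insufficiency -> 3, signature gene coverage failures -> 4.
"""


class RecurRiskError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RecurRiskError, ValueError):
    """A file or table violates the expected format (duplicates, bad cells, missing columns)."""


class ConfigError(RecurRiskError, ValueError):
    """An invalid or inconsistent configuration value."""


class DataError(RecurRiskError, ValueError):
    """Input data cannot support the requested computation."""


class InsufficientEventsError(DataError):
    """Too few observed events to fit or screen."""


class DegenerateCovariateError(DataError):
    """A covariate is constant (or otherwise uninformative) for the fit."""


class InsufficientSignalError(DataError):
    """Training found no stable prognostic genes for a branch."""


class CoverageError(RecurRiskError, KeyError):
    """Prediction-time expression matrix is missing too many signature genes."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = list(missing)

    def __str__(self):  # KeyError would repr() the message otherwise
        return self.args[0]
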