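"""Exception hierarchy shared across the package."""


class MRBiomeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MRBiomeError):
    """A required column, option or config entry is missing or invalid."""


class SummaryStatParseError(MRBiomeError):
    """A summary-statistics file could not be parsed; message names the line."""


class DomainError(MRBiomeError, ValueError):
    """An argument is outside the mathematical domain of a formula."""


class InsufficientInstrumentsError(MRBiomeError):
    """Too few instruments for the requested estimator."""


class CollinearityError(MRBiomeError):
    """The multivariable exposure matrix is rank deficient."""

    def __init__(self, message, exposures=()):
        super().__init__(message)
        self.exposures = list(exposures)
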