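"""Exception and warning hierarchy shared across the package."""


class PrxKitError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PrxKitError, ValueError):
    """A numeric or structural argument violates its contract."""


class ConfigurationError(PrxKitError):
    """A scheme/run configuration is incomplete or inconsistent."""


class SchemaError(PrxKitError):
    """A table does not conform to its declared column schema."""


class FitFailureError(PrxKitError):
    """No multistart converged; carries diagnostics in args."""


class InsufficientDataError(PrxKitError):
    """Too few points / too little design span for the requested fit."""


class DegenerateDesignError(PrxKitError):
    """Zero variance in the independent variable of a regression."""


class CollinearityError(PrxKitError):
    """Preset rate constants too close to separate their amplitudes."""


class DegenerateControlsError(PrxKitError):
    """Ratiometric controls make the degree-of-oxidation denominator vanish."""


class IdentifiabilityWarning(UserWarning):
    """Two fitted rate constants are within threefold of each other."""


class PseudoFirstOrderWarning(UserWarning):
    """Co-substrate excess below tenfold over enzyme."""


class AssayRangeWarning(UserWarning):
    """Absorbance slope outside the assay's working band."""
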