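"""Exception and warning types shared across the package."""


class DietmortError(Exception):
    """Base class for package errors."""


class ConfigError(DietmortError):
    """A configuration value is invalid; the message names the offending field."""


class DataError(DietmortError):
    """Input data violate a precondition (missing columns, bad values)."""


class MissingComponentError(DataError):
    """A score component cannot be computed because its column is absent."""


class EmptyStratumError(DataError):
    """A stratum required for cut-off derivation or fitting contains no subjects."""


class ConvergenceError(DietmortError):
    """A model fit failed to converge."""


class DegenerateCutoffWarning(UserWarning):
    """A component is constant within a stratum; all subjects share one bin."""
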