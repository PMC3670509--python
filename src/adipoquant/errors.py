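"""Exception hierarchy shared by all adipoquant modules."""


class AdipoquantError(Exception):
    """Base class for all package errors."""


class DomainError(AdipoquantError, ValueError):
    """An input value is outside the domain where a formula is defined."""


class MissingMeasurementError(AdipoquantError, ValueError):
    """A required anthropometric measurement is absent from the record."""


class MissingCovariateError(AdipoquantError, ValueError):
    """A required categorical covariate (race, maturation) is absent."""


class UnsupportedAgeError(AdipoquantError, ValueError):
    """The subject's age falls outside every published branch of an equation."""


class CohortSpecError(AdipoquantError, ValueError):
    """A synthetic-cohort specification is internally infeasible."""


class SchemaError(AdipoquantError, ValueError):
    """A CSV file does not conform to the expected subject schema."""


class ConfigError(AdipoquantError, ValueError):
    """A run configuration violates its invariants."""


class RankDeficientError(AdipoquantError, ValueError):
    """A regression design matrix is rank deficient (collinear columns)."""
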