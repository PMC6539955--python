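"""Exception hierarchy shared across the pipeline stages."""


class FlavopgpError(Exception):
    """Base class for all package-specific errors."""


class ParseError(FlavopgpError):
    """A CSV cell or column could not be parsed; message carries row/column."""


class FixtureIntegrityError(FlavopgpError):
    """A packaged table violates one of its declared invariants."""


class ConsistencyError(FlavopgpError):
    """Cross-table or split inconsistency (e.g. id present in one table only)."""


class DomainError(FlavopgpError):
    """An argument is outside the mathematical domain of an operation."""


class FitError(FlavopgpError):
    """A model fit failed or is undefined for the given data."""


class RangeError(FlavopgpError):
    """A requested quantity lies outside the range covered by the fit/data."""


class UndefinedStatisticError(FlavopgpError):
    """A statistic is undefined (zero variance, constant predictions, ...)."""


class SpecError(FlavopgpError):
    """A synthetic-data or run specification is invalid."""
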