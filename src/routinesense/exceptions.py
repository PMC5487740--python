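"""Exception hierarchy for the routinesense pipeline."""


class RoutinesenseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RoutinesenseError):
    """A file does not conform to the expected CSV dialect (e.g. missing column)."""


class RowError(RoutinesenseError):
    """A single CSV row violates the event schema; carries the row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class CoverageError(RoutinesenseError):
    """An event falls outside the configured timezone-schedule coverage."""


class ConfigError(RoutinesenseError):
    """A configuration value is missing or inconsistent."""


class ColdStartError(RoutinesenseError):
    """Not enough history to build a baseline or historical median."""


class UndefinedStatisticError(RoutinesenseError):
    """A summary statistic is undefined for the given input (e.g. zero days)."""


class SingularDesignError(RoutinesenseError):
    """The regression design matrix is singular (constant/collinear regressors)."""
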