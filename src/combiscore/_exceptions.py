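"""Exception hierarchy shared across the package."""


class CombiscoreError(Exception):
    """Base class for all package errors."""


class ConfigError(CombiscoreError):
    """Invalid configuration (e.g. a required column mapping is missing)."""


class ParseError(CombiscoreError):
    """Malformed input rows; carries the offending row numbers."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class IntegrityError(CombiscoreError):
    """Internally inconsistent data (e.g. conflicting drug names in a block)."""


class DesignError(CombiscoreError):
    """The experimental layout cannot support the requested operation."""


class FitError(CombiscoreError):
    """Curve fitting could not be performed at all (not mere non-convergence)."""
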