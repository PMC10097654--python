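"""Typed exceptions shared across the pipeline stages."""


class CoraltradeError(Exception):
    """Base class for all package errors."""


class SchemaError(CoraltradeError):
    """A required column is missing or a table does not match its schema."""


class ValidationError(CoraltradeError):
    """A row violates a type invariant; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class ConfigError(CoraltradeError):
    """A configuration value is out of range or inconsistent."""


class InsufficientDataError(CoraltradeError):
    """Too few observations for the requested computation."""


class DegenerateFitError(CoraltradeError):
    """A model cannot be fit because a variance is zero or a matrix is singular."""


class GapError(CoraltradeError):
    """A temperature logger series has a gap longer than 24 h."""

    def __init__(self, tank_id: str, dates):
        self.tank_id = tank_id
        self.dates = list(dates)
        super().__init__(f"logger gap > 24 h in tank {tank_id} around: "
                         + ", ".join(str(d) for d in self.dates))
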