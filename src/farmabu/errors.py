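"""Exception hierarchy.

All package errors derive from :class:`FarmAbuError` so callers can catch one
type at pipeline boundaries while the library still raises precise subclasses.
"""


class FarmAbuError(Exception):
    """Base class for all errors raised by farmabu."""


class StrengthFormatError(FarmAbuError):
    """A strength label does not match any supported declaration dialect."""


class UnitCompatibilityError(FarmAbuError):
    """Strength basis and package unit do not combine (e.g. g/kg with a mL vial)."""


class ConfigurationError(FarmAbuError):
    """Missing or inconsistent configuration (IU factor, exchange rate, programme)."""


class CatalogLookupError(FarmAbuError):
    """A product, package or ingredient reference does not resolve in the catalog."""


class RecordValidationError(FarmAbuError):
    """Input rows failed validation; carries the offending row numbers."""

    def __init__(self, message: str, rows: list | None = None):
        super().__init__(message)
        self.rows = rows or []
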