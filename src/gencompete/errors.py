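"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`GencompeteError` so the CLI can
distinguish user-facing input problems from genuine bugs.
"""


class GencompeteError(Exception):
    """Base class for all package errors."""


class InputError(GencompeteError):
    """A required input file is missing or unreadable."""


class SchemaError(GencompeteError):
    """An input table lacks a mandatory column or has an unusable layout."""


class ValidationError(GencompeteError):
    """Row-level content violates a table invariant (duplicates, negatives...)."""


class ConfigError(GencompeteError):
    """A configuration key or value is unknown or inconsistent."""


class FitError(GencompeteError):
    """A model fit failed (non-convergence, separation, no events).

    Carries a ``diagnostics`` dict describing the failure.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
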