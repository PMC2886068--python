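"""Exception hierarchy for the bile-salt analysis pipeline."""


class BileSaltError(Exception):
    """Base class for all package errors."""


class ParseError(BileSaltError, ValueError):
    """A compound name (or a fragment of it) could not be parsed."""

    def __init__(self, name: str, fragment: str | None = None, reason: str = ""):
        self.name = name
        self.fragment = fragment
        msg = f"cannot parse {name!r}"
        if fragment:
            msg += f": offending fragment {fragment!r}"
        if reason:
            msg += f" ({reason})"
        super().__init__(msg)


class ValidationError(BileSaltError, ValueError):
    """A descriptor or input value violates a structural invariant."""


class UnsupportedScaffoldError(BileSaltError, ValueError):
    """Formula arithmetic requested for a scaffold size outside the model."""


class ClassificationError(BileSaltError, ValueError):
    """A species profile cannot be assigned to any profile class."""


class ConfigurationError(BileSaltError, ValueError):
    """A simulation or annotation configuration is invalid or empty."""


class SchemaError(BileSaltError, ValueError):
    """A tabular input is missing required columns or contains duplicates."""


class MissingDataError(BileSaltError, ValueError):
    """A tree tip lacks a character state and no exclusion policy applies."""
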