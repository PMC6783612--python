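"""Exception hierarchy used across the package."""


class ConnectokitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ConnectokitError):
    """A configuration value is invalid; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class FormatError(ConnectokitError):
    """A file does not parse as the expected format."""


class IntegrityError(ConnectokitError):
    """Parsed data violates a structural invariant (symmetry, range, diagonal...)."""


class CohortError(ConnectokitError):
    """A cohort-level precondition is violated (group sizes, node mismatch...)."""


class DegenerateStatisticError(ConnectokitError):
    """A statistic is undefined for the given data (zero variance, constant input)."""
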