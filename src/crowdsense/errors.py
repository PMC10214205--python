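"""Exception taxonomy shared by the library and the CLI.

The CLI maps these onto exit codes: usage/configuration -> 2, data -> 3,
numerical -> 4.
"""


class CrowdSenseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CrowdSenseError):
    """Invalid configuration: unknown keys, inconsistent geometry, bad enums."""


class UsageError(CrowdSenseError):
    """An operation was called in a way its contract forbids."""


class DomainError(CrowdSenseError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class DataError(CrowdSenseError):
    """Malformed, empty, or fully-gated-out input data."""


class EstimationError(CrowdSenseError):
    """A statistical estimate could not be formed from the data provided."""


class NumericalError(CrowdSenseError):
    """Integration or optimisation failure (e.g. bond overextension)."""
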