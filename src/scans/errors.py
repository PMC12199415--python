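"""Exception hierarchy shared across the package.

Each class maps to a distinct process exit code in the command-line
interface (configuration 2, data 3, training 4).
"""

__all__ = [
    "ScansError",
    "ConfigurationError",
    "DataError",
    "ConsistencyError",
    "TrainingError",
    "EvaluationError",
]


class ScansError(Exception):
    """Base class for package errors."""

    exit_code = 1


class ConfigurationError(ScansError):
    """Invalid parameter or configuration value."""

    exit_code = 2


class DataError(ScansError):
    """Malformed or insufficient input data."""

    exit_code = 3


class ConsistencyError(DataError):
    """Two inputs that must agree (e.g. annotation vs sequence) do not."""


class TrainingError(ScansError):
    """Model fitting failed, e.g. no checkpoint satisfies the selection rule."""

    exit_code = 4


class EvaluationError(ScansError):
    """A metric is undefined on the given inputs."""

    exit_code = 3
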