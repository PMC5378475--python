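"""Error classes shared across the package.

Each maps to a nonzero CLI exit code so shell pipelines can distinguish bad
parameters from bad data from configuration mistakes.
"""


class AndrodynError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(AndrodynError):
    """A numeric argument violates its contract (range, sign, consistency)."""

    exit_code = 2


class DataError(AndrodynError):
    """Input records are empty, degenerate, or otherwise unusable."""

    exit_code = 3


class CalibrationError(AndrodynError):
    """A requested calibration target cannot be attained."""

    exit_code = 4


class ConfigError(AndrodynError):
    """A pipeline configuration document is invalid."""

    exit_code = 5
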