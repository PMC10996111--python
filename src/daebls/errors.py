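"""Exception hierarchy mapped to CLI exit codes (config=2, data=3, numeric=4)."""


class DaeBlsError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(DaeBlsError):
    """Invalid configuration or parameter value."""

    exit_code = 2


class DataError(DaeBlsError):
    """Invalid, degenerate or inconsistent input data."""

    exit_code = 3


class SchemaError(DataError):
    """Feature-name / shape mismatch between tables or models."""

    exit_code = 3


class NumericError(DaeBlsError):
    """Non-finite values or numerical breakdown."""

    exit_code = 4
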