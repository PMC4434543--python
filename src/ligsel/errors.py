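"""Exception hierarchy; the CLI maps these onto exit codes."""


class LigselError(Exception):
    """Base class for package errors."""


class ConfigError(LigselError):
    """Invalid parameter or configuration file (CLI exit code 2)."""


class DataError(LigselError):
    """Invalid or missing input data (CLI exit code 3)."""


class SchemaError(DataError):
    """A table is missing required columns or has malformed values."""
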