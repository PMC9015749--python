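"""Exception hierarchy."""


class HomesenseError(Exception):
    """Base class for all package errors."""


class ConfigError(HomesenseError):
    """Invalid configuration; ``field`` names the offending entry."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DataError(HomesenseError):
    """Input data violates a contract (bad value, wrong shape)."""


class FormatError(DataError):
    """Input data cannot be parsed (off-grid timestamp, bad CSV cell)."""
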