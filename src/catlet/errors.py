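"""Exception types shared across the package."""


class CatletError(Exception):
    """Base class for package errors."""


class ValidationError(CatletError, ValueError):
    """Invalid input data (bad field value, malformed record, bad config)."""


class ConfigurationError(CatletError, KeyError):
    """Inconsistent configuration, e.g. a segment missing from a weight table."""

    def __str__(self) -> str:  # KeyError quotes its args; keep plain message
        return ", ".join(str(a) for a in self.args)
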