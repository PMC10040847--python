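"""Exception types raised across the pipeline."""


class ExomarkError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ExomarkError, ValueError):
    """Invalid configuration: unknown keys or violated invariants."""


class ParseError(ExomarkError, ValueError):
    """A standard-format input file could not be parsed."""


class DomainError(ExomarkError, ValueError):
    """An operation was called outside its mathematical domain."""
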