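"""Exception hierarchy for loomcd."""


class LoomcdError(Exception):
    """Base class for all loomcd errors."""


class InputError(LoomcdError):
    """Unreadable, empty or malformed input data."""


class ConfigError(LoomcdError):
    """Inconsistent or impossible run configuration."""
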