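"""Exception hierarchy shared across the toolkit."""


class PagkitError(Exception):
    """Base class for all toolkit errors."""


class InputError(PagkitError, ValueError):
    """Malformed or inconsistent input data (bad file contents, bad tables)."""


class ConfigError(PagkitError, ValueError):
    """Bad run configuration (missing columns, invalid thresholds)."""


class ArgumentError(PagkitError, ValueError):
    """Invalid arguments passed to an analysis operation."""
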