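"""Exception hierarchy.

``GascaError`` is the base for all data/usage errors raised by this package,
so callers (and the CLI) can distinguish them from programming errors.
"""


class GascaError(Exception):
    """Base class for all errors raised by gasca."""


class DesignError(GascaError):
    """The experimental design is invalid (unbalanced, unknown factor, ...)."""


class DataError(GascaError):
    """The feature table is invalid (missing values, non-numeric cells, ...)."""


class ConfigError(GascaError):
    """A model configuration is inconsistent or incomplete."""
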