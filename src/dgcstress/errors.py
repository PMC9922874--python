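"""Exception types shared across the pipeline.

Every stage raises a distinct subclass of :class:`DGCStressError` so the CLI
can abort with a stage-named message and a nonzero exit status.
"""


class DGCStressError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(DGCStressError, ValueError):
    """Invalid configuration (simulation or run config)."""


class FormatError(DGCStressError, ValueError):
    """Malformed tabular input; the message names the offending row/column."""


class DesignError(DGCStressError, ValueError):
    """Study design does not support the requested operation."""


class NormalizationError(DGCStressError, ValueError):
    """Size-factor estimation impossible (no reference gene)."""


class UndefinedPercentageError(DGCStressError, ZeroDivisionError):
    """A percentage was requested over an empty denominator."""


class GeneLookupError(DGCStressError, KeyError):
    """A requested gene is absent from a results table."""
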