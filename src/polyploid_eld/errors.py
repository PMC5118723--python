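"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PipelineError`, so callers (and the
CLI) can distinguish user-input problems from bugs.
"""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PipelineError, ValueError):
    """Invalid configuration value (proportions, thresholds, library sizes...)."""


class FormatError(PipelineError, ValueError):
    """Malformed input file: wrong columns, duplicate ids, bad values."""


class DomainError(PipelineError, ValueError):
    """Numeric argument outside the operation's documented domain."""


class AlignmentError(PipelineError, ValueError):
    """Feature universes of two tables that must match do not."""


class ConsistencyError(PipelineError, ValueError):
    """Cross-stage invariant violated (e.g. missing flag for a network gene)."""
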