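"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PipelineError` so the CLI can abort
with the stage name and the offending identifiers.
"""


class PipelineError(Exception):
    """Base class for all pipeline failures."""


class ConfigError(PipelineError):
    """Invalid configuration value or missing required metadata."""


class FormatError(PipelineError):
    """Malformed input table (duplicate ids, bad cells, missing columns)."""


class DesignError(PipelineError):
    """Statistical design cannot be fit (empty contrast side, zero df, ...)."""


class ImputationError(PipelineError):
    """A row cannot be imputed (no observed overlap with any other row)."""
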