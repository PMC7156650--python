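"""Exception hierarchy used across the pipeline.

All pipeline-specific failures derive from :class:`PipelineError` so callers
can catch one base class; subclasses distinguish bad parameters, malformed
files, schema problems in tables, and analysis windows that cannot be
evaluated on the data at hand.
"""


class PipelineError(Exception):
    """Base class for all endoescape errors."""


class ParameterError(PipelineError, ValueError):
    """A parameter value violates its documented constraints."""


class FormatError(PipelineError, ValueError):
    """An input file exists but its content is not in the expected format."""


class SchemaError(PipelineError, ValueError):
    """A tabular input is missing required columns."""


class InputValidationError(PipelineError, ValueError):
    """Input values (coordinates, shapes) are inconsistent with the data."""


class CalibrationError(PipelineError, ValueError):
    """Physical calibration is missing and no override was supplied."""


class CoverageError(PipelineError, ValueError):
    """A requested time window or offset is not covered by the trace/track."""


class NormalizationError(PipelineError, ValueError):
    """A normalization reference is zero, negative, or otherwise unusable."""


class ConfigError(PipelineError, ValueError):
    """A configuration file contains unknown or invalid keys."""
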