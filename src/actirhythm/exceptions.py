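"""Exception hierarchy for the actirhythm pipeline."""


class ActirhythmError(Exception):
    """Base class for all actirhythm errors."""


class ValidationError(ActirhythmError, ValueError):
    """Invalid input data or parameters."""


class InsufficientDaysError(ActirhythmError):
    """Recording shorter than the configured minimum number of whole days."""


class InsufficientGroupSizeError(ActirhythmError):
    """A comparison group has fewer than two members."""


class ConstantSeriesError(ActirhythmError):
    """A statistic is undefined because the input has zero variance."""


class CsvFormatError(ActirhythmError):
    """Malformed row in a CSV input; message names the offending line."""


class PipelineError(ActirhythmError):
    """A pipeline stage failed; message names the stage (and participant)."""
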