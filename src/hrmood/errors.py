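"""Exception hierarchy for the hrmood pipeline.

Every contract violation raises a subclass of :class:`HRMoodError`, so callers
(and the CLI) can distinguish pipeline errors from programming errors.
"""


class HRMoodError(Exception):
    """Base class for all hrmood errors."""


class FormatError(HRMoodError):
    """A file does not follow the expected on-disk dialect."""


class VocabularyError(FormatError):
    """A categorical field holds a value outside its allowed vocabulary."""


class DuplicateRecordError(FormatError):
    """A manifest contains more than one record for a (subject, emotion) pair."""


class InsufficientDataError(HRMoodError):
    """A series or segment is too short for the requested computation."""


class ShapeError(HRMoodError):
    """A feature row or matrix has the wrong dimensions."""


class ParameterError(HRMoodError):
    """A configuration value is out of its documented range or unknown."""


class DegenerateLabelError(HRMoodError):
    """A labelled dataset holds fewer than two classes."""


class DegenerateFoldError(HRMoodError):
    """A cross-validation training fold lost one of the task's classes."""
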